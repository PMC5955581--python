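"""Responsiveness, orientation/direction tuning tests and tuning-curve fits.

A neuron is *responsive* when its mean response to at least one grating
direction significantly exceeds the pooled grey-screen response under a
one-sided many-to-one (Dunnett-type) comparison at familywise alpha.  The
familywise correction uses a seeded Monte-Carlo null of the maximum
many-to-one t statistic, which converges to tabulated Dunnett critical values
as the draw count grows.

Responsive neurons are then tested for direction and orientation tuning with
a permutation test on the magnitude of the mean trial vector: each grating
trial contributes a vector of length equal to its response at angle theta
(direction space) or 2*theta (orientation space); shuffling direction labels
across trials builds the null.  Significantly tuned neurons are fitted with
an asymmetric circular Gaussian (baseline, two amplitudes 180 deg apart,
shared width, preferred direction) by repeated randomized least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .preprocessing import TrialResponses
from .synthetic import asymmetric_circular_gaussian

__all__ = [
    "TuningFit",
    "TuningResult",
    "classify_responsive",
    "tuning_significance",
    "fit_tuning_curve",
    "tuning_variance_explained",
    "tuning_vector",
    "cosine_similarity",
    "analyze_tuning",
]

DIRECTION = "direction"
ORIENTATION = "orientation"
UNTUNED = "untuned"


@dataclass
class TuningFit:
    baseline: float
    amp1: float
    amp2: float
    sigma_deg: float
    theta_pref_deg: float  # NaN when undefined (flat data / failed fit)
    r_squared: float
    converged: bool


@dataclass
class TuningResult:
    responsive: bool
    tuning_class: str  # direction | orientation | untuned
    p_dir: float
    p_ori: float
    fit: Optional[TuningFit]  # None when untuned
    tuning_vector: Optional[np.ndarray]  # 2-vector in the neuron's tuning space


# ---------------------------------------------------------------------------
# responsiveness (many-to-one comparisons against pooled grey)


@lru_cache(maxsize=64)
def _dunnett_max_t_null(group_sizes: tuple, n_control: int, n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo sample of max_k t_k under H0 for many-to-one comparisons.

    t_k = (mean_k - mean_0) / (s_p sqrt(1/n_k + 1/n_0)) with a pooled
    variance estimate; all groups share the control, which correlates the
    statistics - the reason a max-statistic null is needed.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(group_sizes)
    df = int(sizes.sum() + n_control - sizes.size - 1)
    z_groups = rng.standard_normal((n_draws, sizes.size)) / np.sqrt(sizes)
    z_ctrl = rng.standard_normal((n_draws, 1)) / np.sqrt(n_control)
    s_pooled = np.sqrt(rng.chisquare(df, size=(n_draws, 1)) / df)
    t = (z_groups - z_ctrl) / (s_pooled * np.sqrt(1.0 / sizes + 1.0 / n_control))
    return np.sort(t.max(axis=1))


def _many_to_one_t(groups: list[np.ndarray], control: np.ndarray) -> np.ndarray:
    sizes = np.array([g.size for g in groups])
    n0 = control.size
    df = sizes.sum() + n0 - sizes.size - 1
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    sse += ((control - control.mean()) ** 2).sum()
    s2 = sse / df
    if s2 == 0:
        return np.zeros(len(groups))
    means = np.array([g.mean() for g in groups])
    return (means - control.mean()) / np.sqrt(s2 * (1.0 / sizes + 1.0 / n0))


def classify_responsive(
    tr: TrialResponses,
    alpha: float = 0.01,
    seed: int = 0,
    n_draws: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron responsiveness and per-direction adjusted decisions.

    Each direction's trial means are compared one-sidedly against the pooled
    grey responses; the familywise threshold is the 1-alpha quantile of the
    Monte-Carlo max-t null.  A neuron is responsive iff any direction clears
    it.  Returns ``(responsive (n,), decisions (n, n_directions))``.
    """
    from .synthetic import GRATING

    meta = tr.trial_meta
    grating = tr.condition(GRATING)
    grey = tr.condition("grey")
    dirs_per_trial = tr.grating_directions()
    directions = np.unique(dirs_per_trial)
    groups_idx = [np.flatnonzero(dirs_per_trial == d) for d in directions]
    sizes = tuple(len(g) for g in groups_idx)
    if min(sizes) < 2 or grey.shape[1] < 2:
        raise ValueError("need at least 2 trials per direction and 2 grey trials")

    null = _dunnett_max_t_null(sizes, grey.shape[1], n_draws, seed)
    crit = np.quantile(null, 1.0 - alpha)

    n = tr.n_neurons
    decisions = np.zeros((n, directions.size), dtype=bool)
    for i in range(n):
        t = _many_to_one_t([grating[i, g] for g in groups_idx], grey[i])
        decisions[i] = t > crit
    return decisions.any(axis=1), decisions


# ---------------------------------------------------------------------------
# trial-vector tuning tests


def _trial_vector_stats(responses: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """|mean resultant| of response-weighted unit vectors; responses (..., k)."""
    c = responses @ np.cos(angles_rad)
    s = responses @ np.sin(angles_rad)
    return np.hypot(c, s) / responses.shape[-1]


def tuning_significance(
    tr: TrialResponses,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for direction and orientation tuning, per neuron."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    from .synthetic import GRATING

    resp = tr.condition(GRATING)
    theta = np.deg2rad(tr.grating_directions())
    if np.unique(theta).size < 2:
        raise ValueError("all grating directions must be represented")
    rng = np.random.default_rng(seed)
    n, k = resp.shape

    p = np.empty((2, n))
    cols = np.broadcast_to(np.arange(k), (n, k))
    for space, ang in enumerate((theta, 2.0 * theta)):
        obs = _trial_vector_stats(resp, ang)
        # permuting angle labels == permuting responses across trials;
        # permutations are drawn independently per neuron so that p-values
        # are independent across neurons (not just marginally uniform)
        count = np.zeros(n)
        rows = np.arange(n)[:, None]
        for _ in range(n_perm):
            perm = rng.permuted(cols, axis=1)
            count += _trial_vector_stats(resp[rows, perm], ang) >= obs
        p[space] = (1.0 + count) / (1.0 + n_perm)
    return p[0], p[1]


# ---------------------------------------------------------------------------
# asymmetric circular Gaussian fits


def fit_tuning_curve(
    direction_means: np.ndarray,
    directions_deg: np.ndarray | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> TuningFit:
    """Best-of-``n_restarts`` least-squares fit of the double circular Gaussian.

    Restarts draw the preferred direction and width at random; the parameter
    set with the smallest SSE wins.  Flat data yield near-zero amplitudes and
    an undefined (NaN) preferred direction.
    """
    y = np.asarray(direction_means, dtype=float)
    if directions_deg is None:
        directions_deg = np.arange(y.size) * (360.0 / y.size)
    th = np.asarray(directions_deg, dtype=float)
    if np.unique(th).size < 5:
        raise ValueError("need at least 5 distinct directions")

    rng = np.random.default_rng(seed)
    sst = ((y - y.mean()) ** 2).sum()
    scale = max(np.ptp(y), 1e-12)

    def resid(p):
        return asymmetric_circular_gaussian(th, *p) - y

    best = None
    best_sse = np.inf
    lower = [-np.inf, 0.0, 0.0, 5.0, -360.0]
    upper = [np.inf, np.inf, np.inf, 180.0, 720.0]
    for _ in range(n_restarts):
        p0 = [
            y.min(),
            max(scale * rng.uniform(0.5, 1.5), 1e-9),
            max(scale * rng.uniform(0.0, 0.8), 1e-9),
            rng.uniform(10.0, 60.0),
            rng.uniform(0.0, 360.0),
        ]
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper), max_nfev=2000)
        except Exception:
            continue
        sse = 2.0 * sol.cost
        if sol.success and sse < best_sse:
            best_sse = sse
            best = sol.x
    if best is None:
        return TuningFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)

    b, a1, a2, sigma, theta_p = best
    if a2 > a1:  # canonical form: primary peak is the larger one
        a1, a2 = a2, a1
        theta_p += 180.0
    theta_p = float(np.mod(theta_p, 360.0))
    r2 = 1.0 - best_sse / sst if sst > 0 else np.nan
    if max(a1, a2) <= 1e-8 * max(abs(b), 1.0) + 1e-12:
        theta_p = np.nan  # flat: preferred direction undefined
    return TuningFit(float(b), float(a1), float(a2), float(sigma), theta_p, float(r2), True)


def tuning_variance_explained(tr: TrialResponses) -> np.ndarray:
    """Fraction of cross-trial variance captured by per-direction mean responses.

    ``VE_i = 1 - sum_t (r_it - mean_{dir(t)})^2 / sum_t (r_it - mean)^2`` over
    grating trials; NaN where the total variance is zero.
    """
    from .synthetic import GRATING

    resp = tr.condition(GRATING)
    dirs = tr.grating_directions()
    resid = resp.copy()
    for d in np.unique(dirs):
        cols = dirs == d
        resid[:, cols] -= resp[:, cols].mean(axis=1, keepdims=True)
    sse = (resid**2).sum(axis=1)
    sst = ((resp - resp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ve = 1.0 - sse / sst
    ve[sst == 0] = np.nan
    return ve


def tuning_vector(
    direction_means: np.ndarray, space: str, directions_deg: np.ndarray | None = None
) -> np.ndarray:
    """Sum of direction-mean-weighted unit vectors in direction/orientation space."""
    y = np.asarray(direction_means, dtype=float)
    if directions_deg is None:
        directions_deg = np.arange(y.size) * (360.0 / y.size)
    phi = np.deg2rad(directions_deg)
    if space == ORIENTATION:
        phi = 2.0 * phi
    elif space != DIRECTION:
        raise ValueError(f"unknown space {space!r}")
    v = np.array([y @ np.cos(phi), y @ np.sin(phi)])
    # a resultant negligible relative to the total response mass is zero
    # (uniform responses cancel exactly up to floating-point residue)
    if np.linalg.norm(v) < 1e-9 * max(np.abs(y).sum(), 1e-300):
        v = np.zeros(2)
    return v


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / |u||v|; NaN for a zero-magnitude vector."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# orchestration


def direction_mean_responses(tr: TrialResponses) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged grating response per direction: (means (n, D), directions)."""
    from .synthetic import GRATING

    resp = tr.condition(GRATING)
    dirs = tr.grating_directions()
    directions = np.unique(dirs)
    means = np.column_stack([resp[:, dirs == d].mean(axis=1) for d in directions])
    return means, directions


def analyze_tuning(
    tr: TrialResponses,
    alpha_responsive: float = 0.01,
    alpha_tuning: float = 0.05,
    n_perm: int = 1000,
    n_restarts: int = 20,
    seed: int = 0,
) -> list[TuningResult]:
    """Full per-neuron classification: responsive -> tuned (dir/ori) -> fit.

    Class precedence follows the pooling used throughout the analysis:
    direction-tuned if p_dir < alpha, else orientation-tuned if p_ori < alpha,
    else untuned (responsive-but-untuned neurons are pooled with untuned).
    """
    responsive, _ = classify_responsive(tr, alpha=alpha_responsive, seed=seed)
    p_dir, p_ori = tuning_significance(tr, n_perm=n_perm, alpha=alpha_tuning, seed=seed + 1)
    means, directions = direction_mean_responses(tr)

    results = []
    for i in range(tr.n_neurons):
        if not responsive[i]:
            results.append(TuningResult(False, UNTUNED, p_dir[i], p_ori[i], None, None))
            continue
        if p_dir[i] < alpha_tuning:
            cls = DIRECTION
        elif p_ori[i] < alpha_tuning:
            cls = ORIENTATION
        else:
            cls = UNTUNED
        if cls == UNTUNED:
            results.append(TuningResult(True, UNTUNED, p_dir[i], p_ori[i], None, None))
            continue
        fit = fit_tuning_curve(means[i], directions, n_restarts=n_restarts, seed=seed + 2 + i)
        vec = tuning_vector(means[i], cls, directions)
        results.append(TuningResult(True, cls, p_dir[i], p_ori[i], fit, vec))
    return results


def class_labels(results: list[TuningResult]) -> np.ndarray:
    """Two-class labels used by the network analyses: 'tuned' vs 'untuned'."""
    return np.array(
        ["tuned" if r.tuning_class in (DIRECTION, ORIENTATION) else "untuned" for r in results]
    )


def results_table(results: list[TuningResult]):
    """One-row-per-neuron export of tuning classification and fits."""
    import pandas as pd

    rows = []
    for i, r in enumerate(results):
        row = {
            "neuron": i,
            "responsive": r.responsive,
            "tuning_class": r.tuning_class,
            "p_dir": r.p_dir,
            "p_ori": r.p_ori,
        }
        if r.fit is not None:
            row.update(
                baseline=r.fit.baseline,
                amp1=r.fit.amp1,
                amp2=r.fit.amp2,
                sigma_deg=r.fit.sigma_deg,
                theta_pref_deg=r.fit.theta_pref_deg,
                r_squared=r.fit.r_squared,
            )
        rows.append(row)
    return pd.DataFrame(rows)
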