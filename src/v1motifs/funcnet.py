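"""Directed functional networks from blocked three-control partial correlations.

For every neuron pair (i, j) and every stimulus block b, the partial
correlation between the two block-b traces is computed while controlling for
three variables: the frame-wise mean of i's trace over all *other* blocks,
the same for j (both capture stimulus-locked response, valid because the
grating order repeats across blocks), and the within-block mean trace of all
remaining neurons (population-wide co-fluctuation, e.g. running).  The
first-order partialing identity

    r_xy|z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

is iterated over the three controls; the mean over blocks is the edge weight.

Directionality comes from the block-averaged cross-correlogram of the raw
pair: the global-peak lag t_max orients the edge from the leading to the
lagging neuron, a zero-lag peak makes it bidirectional, and peaks beyond the
lag cutoff (500 ms) remove the edge entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .preprocessing import DffTraces, TrialResponses
from .synthetic import GRATING, GREY, StimulusSchedule

__all__ = [
    "PairwiseCorrelations",
    "FunctionalGraph",
    "partial_corr",
    "block_partial_matrix",
    "cross_correlograms",
    "lag_decisions",
    "edge_lag",
    "build_graph",
    "build_functional_graph",
    "condition_correlations",
    "graph_stats",
]

_EPS = 1e-12


class DegenerateInputError(ValueError):
    """A control is (anti)perfectly correlated with a variable being partialed."""


@dataclass
class PairwiseCorrelations:
    grating_r: np.ndarray  # (n, n) symmetric
    grey_r: np.ndarray
    classes: Optional[np.ndarray] = None


@dataclass
class FunctionalGraph:
    """Directed, signed functional network. ``W[i, j]`` is the weight of i -> j."""

    W: np.ndarray  # (n, n) signed, 0 = no edge
    lag_frames: np.ndarray  # (n, n) int, lag of i -> j (0 for bidirectional)
    frame_rate_hz: float
    positions_um: Optional[np.ndarray] = None
    classes: Optional[np.ndarray] = None
    condition: str = "all"

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]

    def in_weights(self, j: int) -> np.ndarray:
        return self.W[:, j]

    def bidirectional_mask(self) -> np.ndarray:
        """Upper-triangle boolean mask of bidirectional (zero-lag) pairs."""
        both = (self.W != 0) & (self.W.T != 0)
        return np.triu(both, k=1)

    def edge_table(self) -> pd.DataFrame:
        src, dst = np.nonzero(self.W)
        bidir = self.W[dst, src] != 0
        return pd.DataFrame(
            {
                "source": src,
                "target": dst,
                "weight": self.W[src, dst],
                "lag_frames": self.lag_frames[src, dst],
                "bidirectional": bidir,
            }
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.W, create_using=nx.DiGraph)
        for i, j in g.edges:
            g.edges[i, j]["lag_frames"] = int(self.lag_frames[i, j])
        return g


# ---------------------------------------------------------------------------
# partial correlation


def _first_order_partial(r_xy, r_xz, r_yz):
    den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (r_xy - r_xz * r_yz) / np.sqrt(den)


def partial_corr(x: np.ndarray, y: np.ndarray, controls) -> float:
    """Correlation of ``x`` and ``y`` after iterated first-order partialing.

    ``controls`` is a sequence of control traces (the analysis uses three).
    Raises :class:`DegenerateInputError` when any intermediate correlation
    with a control is +/-1 (the denominator vanishes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    controls = [np.asarray(c, dtype=float) for c in controls]
    if any(c.shape != x.shape for c in [y] + controls):
        raise ValueError("all traces must share one length")
    if x.size < 10:
        raise ValueError("traces must have length >= 10")
    data = np.vstack([x, y] + controls)
    if np.any(data.std(axis=1) == 0):
        raise ValueError("zero-variance input trace")

    R = np.corrcoef(data)
    active = list(range(data.shape[0]))
    for z in range(2, data.shape[0]):
        active.remove(z)
        if any(abs(R[a, z]) >= 1 - _EPS for a in active):
            raise DegenerateInputError("control perfectly correlated with a variable")
        Rnew = R.copy()
        for a in active:
            for b in active:
                if a != b:
                    Rnew[a, b] = _first_order_partial(R[a, b], R[a, z], R[b, z])
        R = Rnew
    out = float(R[0, 1])
    if not np.isfinite(out):
        raise DegenerateInputError("partial correlation undefined (degenerate controls)")
    return float(np.clip(out, -1.0, 1.0))


def _blocked_traces(
    dff: DffTraces, schedule: StimulusSchedule, frame_filter: str = "all"
) -> list[np.ndarray]:
    """Per-block (n, F) trace matrices, restricted to the chosen frame filter."""
    mask = schedule.frame_mask(frame_filter)
    out = []
    for sl in schedule.block_slices():
        out.append(dff.dff[:, sl][:, mask[sl]])
    lengths = {x.shape[1] for x in out}
    if len(lengths) != 1:
        raise ValueError("blocks are not frame-aligned under this filter")
    return out


def block_partial_matrix(
    dff: DffTraces,
    schedule: StimulusSchedule,
    frame_filter: str = "all",
    blocks: Optional[list[int]] = None,
) -> np.ndarray:
    """Mean-over-blocks three-control partial-correlation matrix (symmetric).

    ``blocks`` restricts both the blocks averaged over and the blocks the
    stimulus-locked controls are built from (used by cross-validation).  The
    computation is vectorized through cross-block covariance algebra; it is
    numerically identical to calling :func:`partial_corr` per pair.
    """
    X = _blocked_traces(dff, schedule, frame_filter)
    if blocks is None:
        blocks = list(range(len(X)))
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks")
    n = dff.n_neurons
    if n < 3:
        raise ValueError("need at least 3 neurons for the population control")
    F = X[0].shape[1]

    Xc = {b: X[b] - X[b].mean(axis=1, keepdims=True) for b in blocks}
    G = {
        (b, b2): (Xc[b] @ Xc[b2].T) / (F - 1) for b in blocks for b2 in blocks
    }

    P = np.zeros((n, n))
    counts = np.zeros((n, n))
    for b in blocks:
        others = [b2 for b2 in blocks if b2 != b]
        A = G[(b, b)]
        Mx = np.mean([G[(b, b2)] for b2 in others], axis=0)
        Mm = np.mean([G[(b1, b2)] for b1 in others for b2 in others], axis=0)

        va = np.diag(A).copy()
        dmx = np.diag(Mx).copy()
        vm = np.diag(Mm).copy()
        a_S = A.sum(axis=1)
        m_S = Mx.sum(axis=0)
        S_S = A.sum()
        k = n - 2

        c = {}
        c["xy"] = A
        c["xz1"] = np.broadcast_to(dmx[:, None], (n, n))
        c["yz1"] = Mx.T
        c["xz2"] = Mx
        c["yz2"] = np.broadcast_to(dmx[None, :], (n, n))
        c["z1z2"] = Mm
        c["xz3"] = (a_S[:, None] - va[:, None] - A) / k
        c["yz3"] = (a_S[None, :] - va[None, :] - A) / k
        c["z1z3"] = (m_S[:, None] - dmx[:, None] - Mx.T) / k
        c["z2z3"] = (m_S[None, :] - Mx - dmx[None, :]) / k
        v = {
            "x": np.broadcast_to(va[:, None], (n, n)),
            "y": np.broadcast_to(va[None, :], (n, n)),
            "z1": np.broadcast_to(vm[:, None], (n, n)),
            "z2": np.broadcast_to(vm[None, :], (n, n)),
            "z3": (S_S - 2 * a_S[:, None] - 2 * a_S[None, :] + va[:, None] + va[None, :] + 2 * A)
            / k**2,
        }
        with np.errstate(invalid="ignore", divide="ignore"):
            r = {}
            for key, names in {
                "xy": ("x", "y"),
                "xz1": ("x", "z1"),
                "yz1": ("y", "z1"),
                "xz2": ("x", "z2"),
                "yz2": ("y", "z2"),
                "z1z2": ("z1", "z2"),
                "xz3": ("x", "z3"),
                "yz3": ("y", "z3"),
                "z1z3": ("z1", "z3"),
                "z2z3": ("z2", "z3"),
            }.items():
                r[key] = c[key] / np.sqrt(v[names[0]] * v[names[1]])

            # partial out z1 from all pairs among {x, y, z2, z3}
            r1 = {
                "xy": _first_order_partial(r["xy"], r["xz1"], r["yz1"]),
                "xz2": _first_order_partial(r["xz2"], r["xz1"], r["z1z2"]),
                "yz2": _first_order_partial(r["yz2"], r["yz1"], r["z1z2"]),
                "xz3": _first_order_partial(r["xz3"], r["xz1"], r["z1z3"]),
                "yz3": _first_order_partial(r["yz3"], r["yz1"], r["z1z3"]),
                "z2z3": _first_order_partial(r["z2z3"], r["z1z2"], r["z1z3"]),
            }
            # partial out z2 from pairs among {x, y, z3}
            r2 = {
                "xy": _first_order_partial(r1["xy"], r1["xz2"], r1["yz2"]),
                "xz3": _first_order_partial(r1["xz3"], r1["xz2"], r1["z2z3"]),
                "yz3": _first_order_partial(r1["yz3"], r1["yz2"], r1["z2z3"]),
            }
            # partial out z3
            pb = _first_order_partial(r2["xy"], r2["xz3"], r2["yz3"])

        valid = np.isfinite(pb)
        P[valid] += pb[valid]
        counts += valid

    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(counts == len(blocks), P / np.maximum(counts, 1), np.nan)
    P = np.clip(P, -1.0, 1.0)
    np.fill_diagonal(P, 0.0)
    return P


# ---------------------------------------------------------------------------
# cross-correlogram directionality


def cross_correlograms(
    dff: DffTraces,
    schedule: StimulusSchedule,
    max_search_lag_s: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block normalized cross-correlograms for all pairs at lags 0..L.

    Returns ``(stack, valid)`` where ``stack[b, tau, i, j]`` approximates
    ``corr(x_i(t), x_j(t + tau))`` within block b (traces standardized per
    block) and ``valid[b, i]`` flags non-degenerate block traces.  Negative
    lags follow from ``c_ij(-tau) = c_ji(tau)``.
    """
    L = int(np.floor(max_search_lag_s * dff.frame_rate_hz))
    X = _blocked_traces(dff, schedule, "all")
    B = len(X)
    n = dff.n_neurons
    F = X[0].shape[1]
    if F <= L:
        raise ValueError("block shorter than the lag search window")
    stack = np.zeros((B, L + 1, n, n), dtype=np.float32)
    valid = np.zeros((B, n), dtype=bool)
    for b, Xb in enumerate(X):
        mu = Xb.mean(axis=1, keepdims=True)
        sd = Xb.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        valid[b] = ok
        Z = np.where(ok[:, None], (Xb - mu) / np.where(sd > 0, sd, 1.0), 0.0).astype(np.float32)
        for tau in range(L + 1):
            seg = F - tau
            stack[b, tau] = (Z[:, :seg] @ Z[:, tau:].T) / seg
    return stack, valid


def lag_decisions(
    stack: np.ndarray,
    valid: np.ndarray,
    frame_rate_hz: float,
    cutoff_s: float = 0.5,
    blocks: Optional[list[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak lag and edge admissibility for every pair from block-mean correlograms.

    Returns ``(t_max, has_edge)``: ``t_max[i, j] > 0`` means i leads j (edge
    i -> j), 0 means bidirectional; ``has_edge`` is False where the peak lag
    exceeds the cutoff or no block was usable.  Ties go to the smaller |lag|,
    then to the positive lag (candidates ordered 0, +1, -1, +2, -2, ...).
    """
    B, L1, n, _ = stack.shape
    L = L1 - 1
    if blocks is None:
        blocks = list(range(B))
    pair_counts = np.zeros((n, n))
    mean = np.zeros((L + 1, n, n), dtype=np.float64)
    for b in blocks:
        w = np.outer(valid[b], valid[b]).astype(float)
        pair_counts += w
        mean += stack[b] * w
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = mean / pair_counts
    usable = pair_counts > 0

    # candidate order implements the tie-break
    cand_lags = [0]
    for k in range(1, L + 1):
        cand_lags += [k, -k]
    vals = np.empty((len(cand_lags), n, n), dtype=np.float64)
    for idx, lag in enumerate(cand_lags):
        vals[idx] = mean[lag] if lag >= 0 else mean[-lag].transpose(1, 0)
    vals = np.nan_to_num(vals, nan=-np.inf)
    best = np.argmax(vals, axis=0)
    t_max = np.asarray(cand_lags)[best]

    cutoff = int(np.floor(cutoff_s * frame_rate_hz))
    has_edge = usable & (np.abs(t_max) <= cutoff)
    np.fill_diagonal(has_edge, False)
    np.fill_diagonal(t_max, 0)
    return t_max, has_edge


def edge_lag(
    x_blocks,
    y_blocks,
    frame_rate_hz: float,
    max_search_lag_s: float = 1.5,
    cutoff_s: float = 0.5,
) -> tuple[int, str]:
    """Cross-correlogram peak lag and direction for a single neuron pair.

    ``x_blocks``/``y_blocks`` are per-block traces.  Returns ``(t_max,
    direction)`` with direction in {"x->y", "y->x", "bidirectional", "none"};
    ``t_max > 0`` means x leads y.  Zero-variance blocks are excluded; if all
    blocks are excluded the result is ``(0, "none")``.
    """
    L = int(np.floor(max_search_lag_s * frame_rate_hz))
    cutoff = int(np.floor(cutoff_s * frame_rate_hz))
    if L < cutoff:
        raise ValueError("search window must cover the lag cutoff")
    curves = []
    for x, y in zip(x_blocks, y_blocks):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        F = x.size
        c = np.empty(2 * L + 1)
        for tau in range(L + 1):
            seg = F - tau
            c[L + tau] = (zx[:seg] @ zy[tau:]) / seg
            c[L - tau] = (zx[tau:] @ zy[:seg]) / seg
        curves.append(c)
    if not curves:
        return 0, "none"
    mean = np.mean(curves, axis=0)

    order = [0] + [s * k for k in range(1, L + 1) for s in (1, -1)]
    t_max = order[int(np.argmax([mean[L + lag] for lag in order]))]
    if abs(t_max) > cutoff:
        return int(t_max), "none"
    if t_max == 0:
        return 0, "bidirectional"
    return int(t_max), ("x->y" if t_max > 0 else "y->x")


# ---------------------------------------------------------------------------
# graph assembly and statistics


def build_graph(
    partial_matrix: np.ndarray,
    t_max: np.ndarray,
    has_edge: np.ndarray,
    frame_rate_hz: float,
    positions_um: Optional[np.ndarray] = None,
    classes: Optional[np.ndarray] = None,
    weight_floor: float = 0.0,
    condition: str = "all",
) -> FunctionalGraph:
    """Assemble the directed weight matrix from partial correlations and lags."""
    P = np.asarray(partial_matrix, dtype=float)
    n = P.shape[0]
    if t_max.shape != P.shape or has_edge.shape != P.shape:
        raise ValueError("matrix shapes must agree")
    W = np.zeros_like(P)
    lag = np.zeros((n, n), dtype=int)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        w = P[i, j]
        if not has_edge[i, j] or not np.isfinite(w) or abs(w) <= weight_floor:
            continue
        t = t_max[i, j]
        if t == 0:
            W[i, j] = W[j, i] = w
        elif t > 0:
            W[i, j] = w
            lag[i, j] = t
        else:
            W[j, i] = w
            lag[j, i] = -t
    return FunctionalGraph(
        W=W,
        lag_frames=lag,
        frame_rate_hz=frame_rate_hz,
        positions_um=positions_um,
        classes=classes,
        condition=condition,
    )


def build_functional_graph(
    dff: DffTraces,
    schedule: StimulusSchedule,
    frame_filter: str = "all",
    positions_um: Optional[np.ndarray] = None,
    classes: Optional[np.ndarray] = None,
    max_search_lag_s: float = 1.5,
    cutoff_s: float = 0.5,
    weight_floor: float = 0.0,
    blocks: Optional[list[int]] = None,
    correlograms: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> FunctionalGraph:
    """End-to-end graph build: partial matrix + correlogram lags + assembly.

    ``correlograms`` may carry a precomputed :func:`cross_correlograms` result
    so repeated builds (cross-validation folds) do not recompute it.
    """
    P = block_partial_matrix(dff, schedule, frame_filter, blocks=blocks)
    if correlograms is None:
        correlograms = cross_correlograms(dff, schedule, max_search_lag_s)
    stack, valid = correlograms
    t_max, has_edge = lag_decisions(stack, valid, dff.frame_rate_hz, cutoff_s, blocks=blocks)
    return build_graph(
        P,
        t_max,
        has_edge,
        dff.frame_rate_hz,
        positions_um=positions_um,
        classes=classes,
        weight_floor=weight_floor,
        condition=frame_filter,
    )


def condition_correlations(
    tr: TrialResponses,
    classes: Optional[np.ndarray] = None,
    theta_pref_deg: Optional[np.ndarray] = None,
    dpref_bin_deg: float = 30.0,
) -> tuple[PairwiseCorrelations, dict]:
    """Pairwise trial-response correlations per condition plus class summaries.

    Correlates each pair's per-trial mean-response vectors within grating and
    grey trials separately (signal+noise mixture; nothing is shuffled).  The
    summary reports mean r within-tuned / within-untuned / between pairs per
    condition and, when preferred directions are given, mean r of tuned pairs
    against their preferred-direction difference.
    """
    out = {}
    mats = {}
    for cond in (GRATING, GREY):
        resp = tr.condition(cond)
        if resp.shape[1] < 10:
            raise ValueError("need at least 10 trials per condition")
        sd = resp.std(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(resp)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        np.fill_diagonal(r, 1.0)
        mats[cond] = r

    pc = PairwiseCorrelations(grating_r=mats[GRATING], grey_r=mats[GREY], classes=classes)

    if classes is not None:
        classes = np.asarray(classes)
        tuned = classes == "tuned"
        iu, ju = np.triu_indices(len(classes), k=1)
        pair_kind = np.where(
            tuned[iu] & tuned[ju], "within_tuned", np.where(~tuned[iu] & ~tuned[ju], "within_untuned", "between")
        )
        for cond in (GRATING, GREY):
            vals = mats[cond][iu, ju]
            out[cond] = {}
            for k in ("within_tuned", "within_untuned", "between"):
                sel = vals[pair_kind == k]
                out[cond][k] = (
                    float(np.nanmean(sel)) if np.isfinite(sel).any() else np.nan
                )
        if theta_pref_deg is not None:
            dp = np.abs((theta_pref_deg[iu] - theta_pref_deg[ju] + 180.0) % 360.0 - 180.0)
            sel = tuned[iu] & tuned[ju] & np.isfinite(dp)
            edges = np.arange(0.0, 180.0 + dpref_bin_deg, dpref_bin_deg)
            curves = {}
            for cond in (GRATING, GREY):
                vals = mats[cond][iu, ju]
                means = []
                for lo, hi in zip(edges[:-1], edges[1:]):
                    m = sel & (dp >= lo) & (dp < hi + (hi == 180.0))
                    means.append(float(np.nanmean(vals[m])) if m.any() else np.nan)
                curves[cond] = np.array(means)
            out["delta_pref_bins_deg"] = 0.5 * (edges[:-1] + edges[1:])
            out["delta_pref_mean_r"] = curves
    return pc, out


def graph_stats(
    g: FunctionalGraph,
    thresholds: Optional[np.ndarray] = None,
    n_dist_bins: int = 8,
) -> dict:
    """Edge density, spatial structure and bidirectionality of the graph.

    ``lag_speed_mm_s`` is 1/slope of the least-squares line of binned mean
    lag (s) against distance (mm); the bidirectionality ratio divides the
    observed bidirectional-pair fraction by q^2 (q = ordered-pair directed
    edge density), the independent-placement expectation.
    """
    if thresholds is None:
        thresholds = np.array([0.0, 0.025, 0.05, 0.075, 0.1, 0.15, 0.2])
    n = g.n_neurons
    absW = np.abs(g.W)
    iu, ju = np.triu_indices(n, k=1)
    out: dict = {"thresholds": thresholds}

    classes = g.classes
    if classes is not None:
        tuned = np.asarray(classes) == "tuned"
        pair_kind = np.where(
            tuned[iu] & tuned[ju], "within_tuned", np.where(~tuned[iu] & ~tuned[ju], "within_untuned", "between")
        )
    else:
        pair_kind = np.full(iu.size, "all")

    density = []
    bidir_ratio = []
    by_class: dict = {k: [] for k in np.unique(pair_kind)}
    for th in thresholds:
        Wt = np.where(absW > th, g.W, 0.0)
        connected = (Wt[iu, ju] != 0) | (Wt[ju, iu] != 0)
        density.append(connected.mean())
        for k in by_class:
            by_class[k].append(connected[pair_kind == k].mean())
        q = (Wt != 0).sum() / (n * (n - 1))  # ordered-pair directed density
        bi_frac = ((Wt[iu, ju] != 0) & (Wt[ju, iu] != 0)).mean()
        bidir_ratio.append(bi_frac / q**2 if q > 0 else np.nan)
    out["connection_probability"] = np.asarray(density)
    out["connection_probability_by_class"] = {k: np.asarray(v) for k, v in by_class.items()}
    out["bidirectional_ratio"] = np.asarray(bidir_ratio)

    if g.positions_um is not None:
        d = np.linalg.norm(g.positions_um[iu] - g.positions_um[ju], axis=1)
        edges = np.linspace(0.0, d.max() + _EPS, n_dist_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        connected = (g.W[iu, ju] != 0) | (g.W[ju, iu] != 0)
        pair_lag = np.maximum(g.lag_frames[iu, ju], g.lag_frames[ju, iu])  # one side holds it
        p_conn, mean_lag, mean_dist = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (d >= lo) & (d < hi)
            p_conn.append(connected[m].mean() if m.any() else np.nan)
            me = m & connected
            mean_lag.append(np.abs(pair_lag[me]).mean() / g.frame_rate_hz if me.any() else np.nan)
            mean_dist.append(d[me].mean() if me.any() else np.nan)
        out["distance_bins_um"] = centers
        out["connection_probability_by_distance"] = np.asarray(p_conn)
        out["mean_lag_s_by_distance"] = np.asarray(mean_lag)
        ok = np.isfinite(out["mean_lag_s_by_distance"])
        if ok.sum() >= 2:
            # regress against the mean connected-pair distance per bin, not
            # the bin center, so skewed within-bin occupancy does not tilt
            # the slope
            x_mm = np.asarray(mean_dist)[ok] / 1000.0
            slope, _ = np.polyfit(x_mm, out["mean_lag_s_by_distance"][ok], 1)
            out["lag_speed_mm_s"] = float(1.0 / slope) if slope != 0 else np.nan
        else:
            out["lag_speed_mm_s"] = np.nan
    return out
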