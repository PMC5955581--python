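"""Linear peer-prediction of single-trial fluorescence from graph in-neighbors.

Each neuron's trace is modeled as a gain/offset-rescaled weighted sum of its
in-neighbors' traces, with the partial-correlation edge weights as the fixed
linear weights:

    y_hat_j(t) = g_j * sum_i W[i -> j] x_i(t) + b_j

The gain and offset are the closed-form least-squares fit of the raw weighted
sum to the true trace; they are deliberately *not* refit when inputs are
ablated, so edge-removal curves isolate the contribution of the edges
themselves.  Performance is summarized as variance explained,

    VE = 1 - sum_t (y - y_hat)^2 / sum_t y^2

(note the raw, uncentered denominator), per neuron and pooled over the
population.  The benchmark upper bound replaces the fixed weights with
LASSO-optimal weights chosen by 5-fold cross-validation and the
one-standard-error rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import lasso_path

from .funcnet import FunctionalGraph, build_functional_graph, cross_correlograms
from .preprocessing import DffTraces, trial_means
from .synthetic import StimulusSchedule
from .tuning import DIRECTION, ORIENTATION, TuningResult, cosine_similarity, tuning_vector

__all__ = [
    "NeuronPrediction",
    "ReconstructionResult",
    "LassoFit",
    "predict_neuron",
    "variance_explained",
    "population_ve",
    "reconstruct_population",
    "crossval_reconstruction",
    "edge_removal_curves",
    "subpopulation_ablation",
    "lasso_weights",
    "lasso_at",
    "one_se_lambda",
    "model_tuning_similarity",
    "ve_vs_population_size",
]


@dataclass
class NeuronPrediction:
    neuron: int
    gain: float
    offset: float
    prediction: np.ndarray
    mse: float
    variance_explained: float
    n_inputs: int
    constant_only: bool  # zero in-degree fallback


@dataclass
class ReconstructionResult:
    per_neuron: list[NeuronPrediction]
    population_variance_explained: float

    def ve_array(self) -> np.ndarray:
        return np.array([p.variance_explained for p in self.per_neuron])

    def mse_array(self) -> np.ndarray:
        return np.array([p.mse for p in self.per_neuron])


@dataclass
class LassoFit:
    weights: np.ndarray
    intercept: float
    lambdas: np.ndarray
    chosen_lambda: float
    cv_mse: np.ndarray
    cv_se: np.ndarray
    n_folds: int
    coef_path: Optional[np.ndarray] = None  # (p, n_lambdas), full-data path


def lasso_at(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Single LASSO solution ``min (1/2N)||y - b0 - Xb||^2 + lam ||b||_1``.

    ``lam = 0`` reduces to ordinary least squares (solved directly).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = X.mean(axis=0), y.mean()
    if lam == 0:
        beta, *_ = np.linalg.lstsq(X - xm, y - ym, rcond=None)
    else:
        from sklearn.linear_model import Lasso

        model = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000, tol=1e-10)
        model.fit(X - xm, y - ym)
        beta = model.coef_
    return beta, float(ym - xm @ beta)


def one_se_lambda(lambdas: np.ndarray, cv_mse: np.ndarray, cv_se: np.ndarray) -> int:
    """Index of the largest lambda with CV MSE within one SE of the minimum.

    ``lambdas`` must be in descending order (as produced by the path).
    """
    best = int(np.argmin(cv_mse))
    threshold = cv_mse[best] + cv_se[best]
    return int(np.flatnonzero(cv_mse <= threshold)[0])


def variance_explained(y: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - SSE / sum(y^2); NaN for an all-zero target."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("traces must have equal length")
    denom = float(np.sum(y**2))
    if denom == 0:
        return np.nan
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / denom


def population_ve(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """1 - total squared residual over total squared fluorescence, all neurons."""
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    denom = float(np.sum(Y**2))
    if denom == 0:
        return np.nan
    return 1.0 - float(np.sum((Y - Y_hat) ** 2)) / denom


def _fit_gain_offset(y: np.ndarray, raw: np.ndarray) -> tuple[float, float]:
    """Closed-form least squares of y on (raw, 1)."""
    var = raw.var()
    if var == 0:
        return 0.0, float(y.mean())
    g = float(np.cov(raw, y, bias=True)[0, 1] / var)
    b = float(y.mean() - g * raw.mean())
    return g, b


def predict_neuron(
    g: FunctionalGraph,
    dff: DffTraces,
    j: int,
    fit_frames: Optional[np.ndarray] = None,
) -> NeuronPrediction:
    """Predict neuron ``j`` from its in-neighbors; gain/offset fit by least squares.

    ``fit_frames`` optionally restricts the gain/offset fit (and the reported
    MSE/VE) to a frame subset — cross-validation fits on training frames only.
    A neuron with zero in-degree falls back to its best constant, flagged.
    """
    w = g.in_weights(j)
    y_full = dff.dff[j]
    raw_full = w @ dff.dff
    sel = slice(None) if fit_frames is None else fit_frames
    y = y_full[sel]
    n_inputs = int(np.count_nonzero(w))
    if n_inputs == 0:
        gain, offset = 0.0, float(y.mean())
        pred_full = np.full_like(y_full, offset)
        constant = True
    else:
        gain, offset = _fit_gain_offset(y, raw_full[sel])
        pred_full = gain * raw_full + offset
        constant = False
    resid = y - pred_full[sel]
    mse = float(np.mean(resid**2))
    return NeuronPrediction(
        neuron=j,
        gain=gain,
        offset=offset,
        prediction=pred_full,
        mse=mse,
        variance_explained=variance_explained(y, pred_full[sel]),
        n_inputs=n_inputs,
        constant_only=constant,
    )


def reconstruct_population(
    g: FunctionalGraph, dff: DffTraces, fit_frames: Optional[np.ndarray] = None
) -> ReconstructionResult:
    """Predict every neuron and pool population variance explained."""
    preds = [predict_neuron(g, dff, j, fit_frames) for j in range(dff.n_neurons)]
    sel = slice(None) if fit_frames is None else fit_frames
    Y = dff.dff[:, sel]
    Y_hat = np.vstack([p.prediction[sel] for p in preds])
    return ReconstructionResult(preds, population_ve(Y, Y_hat))


def crossval_reconstruction(
    dff: DffTraces,
    schedule: StimulusSchedule,
    frame_filter: str = "all",
    weight_floor: float = 0.0,
    cutoff_s: float = 0.5,
) -> dict:
    """Leave-one-block-out reconstruction: graph and rescaling from training
    blocks, variance explained evaluated on the held-out block.

    Returns per-neuron mean held-out VE across folds, per-fold values, and
    the held-out population VE per fold.
    """
    B = schedule.n_blocks
    if B < 3:
        raise ValueError("need at least 3 blocks for leave-one-out")
    correlograms = cross_correlograms(dff, schedule)
    fold_ve = np.empty((B, dff.n_neurons))
    fold_pop = np.empty(B)
    slices = schedule.block_slices()
    all_frames = np.arange(dff.n_frames)
    for held in range(B):
        train_blocks = [b for b in range(B) if b != held]
        graph = build_functional_graph(
            dff,
            schedule,
            frame_filter=frame_filter,
            weight_floor=weight_floor,
            cutoff_s=cutoff_s,
            blocks=train_blocks,
            correlograms=correlograms,
        )
        test_mask = np.zeros(dff.n_frames, dtype=bool)
        test_mask[slices[held]] = True
        train_frames = all_frames[~test_mask]
        test_frames = all_frames[test_mask]
        Y_hat = np.empty((dff.n_neurons, test_frames.size))
        for j in range(dff.n_neurons):
            p = predict_neuron(graph, dff, j, fit_frames=train_frames)
            pred_test = p.prediction[test_frames]
            Y_hat[j] = pred_test
            fold_ve[held, j] = variance_explained(dff.dff[j, test_frames], pred_test)
        fold_pop[held] = population_ve(dff.dff[:, test_frames], Y_hat)
    return {
        "per_neuron_ve": np.nanmean(fold_ve, axis=0),
        "fold_ve": fold_ve,
        "fold_population_ve": fold_pop,
        "population_ve": float(np.nanmean(fold_pop)),
    }


def edge_removal_curves(
    g: FunctionalGraph,
    dff: DffTraces,
    j: int,
    order: str = "strongest_first",
    seed: int = 0,
    n_random_draws: int = 20,
) -> dict:
    """Increase in MSE as in-edges of ``j`` are removed one at a time.

    Gain and offset stay frozen at their full-model values.  Returns the
    MSE increase normalized by the neuron's mean squared fluorescence, both
    per removal count and per cumulative |weight| removed.  ``order`` is
    ``strongest_first``, ``weakest_first`` or ``random`` (averaged over
    ``n_random_draws`` seeded draws).
    """
    base = predict_neuron(g, dff, j)
    w = g.in_weights(j).copy()
    inputs = np.flatnonzero(w)
    y = dff.dff[j]
    norm = float(np.mean(y**2))
    k = inputs.size
    if k == 0:
        return {"n_removed": np.array([0]), "delta_mse": np.array([0.0]),
                "cum_weight_removed": np.array([0.0])}

    strengths = np.abs(w[inputs])
    if order == "strongest_first":
        orders = [inputs[np.argsort(-strengths, kind="stable")]]
    elif order == "weakest_first":
        orders = [inputs[np.argsort(strengths, kind="stable")]]
    elif order == "random":
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(inputs) for _ in range(n_random_draws)]
    else:
        raise ValueError(f"unknown order {order!r}")

    total_w = strengths.sum()
    dmse = np.zeros((len(orders), k + 1))
    cumw = np.zeros((len(orders), k + 1))
    for o, seq in enumerate(orders):
        raw = w @ dff.dff
        removed = 0.0
        for step, i in enumerate(seq, start=1):
            raw = raw - w[i] * dff.dff[i]
            removed += abs(w[i])
            pred = base.gain * raw + base.offset  # frozen rescaling
            dmse[o, step] = np.mean((y - pred) ** 2) - base.mse
            cumw[o, step] = removed / total_w
    return {
        "n_removed": np.arange(k + 1),
        "delta_mse": dmse.mean(axis=0) / norm,
        "cum_weight_removed": cumw.mean(axis=0),
    }


def subpopulation_ablation(
    g: FunctionalGraph, dff: DffTraces, classes: np.ndarray
) -> dict:
    """MSE increase from removing within-class vs between-class in-edges.

    Gain/offset are frozen from the full model.  Returns (n,) arrays of
    normalized delta-MSE for each ablation plus the class label per neuron.
    """
    classes = np.asarray(classes)
    n = dff.n_neurons
    out = {"within": np.zeros(n), "between": np.zeros(n), "classes": classes}
    for j in range(n):
        base = predict_neuron(g, dff, j)
        w = g.in_weights(j)
        y = dff.dff[j]
        norm = float(np.mean(y**2))
        same = classes == classes[j]
        for key, keep_mask in (("within", ~same), ("between", same)):
            w_abl = np.where(keep_mask, w, 0.0)
            pred = base.gain * (w_abl @ dff.dff) + base.offset
            out[key][j] = (np.mean((y - pred) ** 2) - base.mse) / norm
    return out


def lasso_weights(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    n_lambdas: int = 100,
    seed: int = 0,
    shuffle_frames: bool = True,
) -> LassoFit:
    """LASSO path with cross-validated lambda chosen by the one-SE rule.

    Solves ``min (1/2N) ||y - b0 - X b||^2 + lambda ||b||_1`` over a geometric
    grid from lambda_max (the smallest lambda with an all-zero solution) down
    to 1e-4 lambda_max.  Folds are seeded random frame partitions by default
    (matching the cross-validation convention of standard LASSO tooling);
    ``shuffle_frames=False`` switches to contiguous time chunks, which is the
    conservative choice under strong temporal autocorrelation but inflates
    the fold-to-fold error spread when slow shared fluctuations dominate.
    The chosen lambda is the largest whose CV MSE is within one standard
    error of the minimum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(y).size:
        X = X.T  # accept (p, T) inputs
    y = np.asarray(y, dtype=float)
    T, p = X.shape
    if p < 1:
        raise ValueError("need at least one input")
    if T <= p:
        warnings.warn("fewer frames than inputs; LASSO fit may be unstable")
    if np.all(X.std(axis=0) == 0):
        return LassoFit(np.zeros(p), float(y.mean()), np.array([]), np.nan,
                        np.array([]), np.array([]), n_folds)

    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / T
    if lam_max == 0:
        return LassoFit(np.zeros(p), float(y.mean()), np.array([]), 0.0,
                        np.array([]), np.array([]), n_folds)
    lambdas = np.geomspace(lam_max, 1e-4 * lam_max, n_lambdas)

    idx = np.arange(T)
    if shuffle_frames:
        np.random.default_rng(seed).shuffle(idx)
    folds = np.array_split(idx, n_folds)

    mse = np.empty((n_folds, n_lambdas))
    for f, test in enumerate(folds):
        train = np.setdiff1d(idx, test, assume_unique=False)
        Xt, yt = X[train], y[train]
        xm, ym = Xt.mean(axis=0), yt.mean()
        _, coefs, _ = lasso_path(Xt - xm, yt - ym, alphas=lambdas, precompute=True)
        pred = (X[test] - xm) @ coefs + ym
        mse[f] = np.mean((y[test][:, None] - pred) ** 2, axis=0)
    cv_mse = mse.mean(axis=0)
    cv_se = mse.std(axis=0, ddof=1) / np.sqrt(n_folds)

    chosen = one_se_lambda(lambdas, cv_mse, cv_se)
    lam = float(lambdas[chosen])

    xm, ym = X.mean(axis=0), y.mean()
    _, coefs, _ = lasso_path(X - xm, y - ym, alphas=lambdas, precompute=True)
    beta = coefs[:, chosen]
    intercept = float(ym - xm @ beta)
    return LassoFit(beta, intercept, lambdas, lam, cv_mse, cv_se, n_folds, coef_path=coefs)


def lasso_reconstruction(
    g: FunctionalGraph, dff: DffTraces, n_folds: int = 5, seed: int = 0
) -> ReconstructionResult:
    """Benchmark reconstruction with LASSO-optimal in-neighbor weights."""
    preds = []
    Y_hat = np.empty_like(dff.dff)
    for j in range(dff.n_neurons):
        w = g.in_weights(j)
        inputs = np.flatnonzero(w)
        y = dff.dff[j]
        if inputs.size == 0:
            pred = np.full_like(y, y.mean())
            fitted = NeuronPrediction(j, 0.0, float(y.mean()), pred,
                                      float(np.mean((y - pred) ** 2)),
                                      variance_explained(y, pred), 0, True)
        else:
            fit = lasso_weights(dff.dff[inputs].T, y, n_folds=n_folds, seed=seed + j)
            pred = dff.dff[inputs].T @ fit.weights + fit.intercept
            fitted = NeuronPrediction(j, 1.0, fit.intercept, pred,
                                      float(np.mean((y - pred) ** 2)),
                                      variance_explained(y, pred),
                                      int(np.count_nonzero(fit.weights)), False)
        preds.append(fitted)
        Y_hat[j] = pred
    return ReconstructionResult(preds, population_ve(dff.dff, Y_hat))


def model_tuning_similarity(
    result: ReconstructionResult,
    dff: DffTraces,
    schedule: StimulusSchedule,
    tuning: list[TuningResult],
) -> np.ndarray:
    """Cosine similarity of data vs model tuning vectors for tuned neurons.

    The model tuning vector is built exactly like the data one — trial means
    of the predicted trace, averaged per direction, summed as vectors — in
    direction or orientation space according to each neuron's tuning class.
    NaN for neurons that are not tuned or whose model vector is zero.
    """
    from .tuning import direction_mean_responses

    pred_traces = np.vstack([p.prediction for p in result.per_neuron])
    pred_dff = DffTraces(pred_traces, np.ones_like(pred_traces), dff.frame_rate_hz)
    tr_pred = trial_means(pred_dff, schedule)
    means_pred, directions = direction_mean_responses(tr_pred)

    out = np.full(dff.n_neurons, np.nan)
    for j, t in enumerate(tuning):
        if t.tuning_class not in (DIRECTION, ORIENTATION) or t.tuning_vector is None:
            continue
        v_model = tuning_vector(means_pred[j], t.tuning_class, directions)
        out[j] = cosine_similarity(t.tuning_vector, v_model)
    return out


def ve_vs_population_size(
    dff: DffTraces,
    schedule: StimulusSchedule,
    sizes,
    n_rep: int = 2,
    seed: int = 0,
    weight_floor: float = 0.0,
) -> dict:
    """Population VE of the full pipeline on random neuron subsamples.

    For each size, ``n_rep`` seeded subsamples are drawn; the functional
    graph and reconstruction are recomputed from scratch on the subsample.
    Reports mean population VE per size and the Spearman correlation of VE
    with size across all subsamples.
    """
    sizes = list(sizes)
    if max(sizes) > dff.n_neurons:
        raise ValueError("subsample size exceeds population")
    rng = np.random.default_rng(seed)
    stack, valid = cross_correlograms(dff, schedule)
    ve = np.empty((len(sizes), n_rep))
    for s_idx, size in enumerate(sizes):
        for rep in range(n_rep):
            sub = np.sort(rng.choice(dff.n_neurons, size=size, replace=False))
            sub_dff = DffTraces(dff.dff[sub], dff.baseline_f0[sub], dff.frame_rate_hz)
            if size < 3:
                res = ReconstructionResult(
                    [predict_neuron(
                        FunctionalGraph(np.zeros((size, size)), np.zeros((size, size), int),
                                        dff.frame_rate_hz),
                        sub_dff, j) for j in range(size)],
                    np.nan,
                )
                Y_hat = np.vstack([p.prediction for p in res.per_neuron])
                ve[s_idx, rep] = population_ve(sub_dff.dff, Y_hat)
                continue
            sub_stack = np.ascontiguousarray(stack[:, :, sub][:, :, :, sub])
            graph = build_functional_graph(
                sub_dff,
                schedule,
                weight_floor=weight_floor,
                correlograms=(sub_stack, valid[:, sub]),
            )
            ve[s_idx, rep] = reconstruct_population(graph, sub_dff).population_variance_explained
    flat_sizes = np.repeat(sizes, n_rep)
    rho, _ = spearmanr(flat_sizes, ve.ravel())
    return {"sizes": np.asarray(sizes), "ve": ve, "mean_ve": ve.mean(axis=1),
            "spearman_rho": float(rho)}
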