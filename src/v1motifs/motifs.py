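"""Directed triplet-motif clustering coefficients and Erdős–Rényi nulls.

On the binarized graph (any nonzero weight -> 1), each node's participation
in the four directed triangle classes — cycle, middleman, fan-in, fan-out —
plus total clustering is normalized by the number of such triangles its
degrees allow.  With A the binary adjacency (A[i, j] = 1 for edge i -> j),
d_in/d_out its column/row degrees, d_tot = d_in + d_out and d_bi = (A^2)_ii
the reciprocal-pair count:

    cycle_i     = (A^3)_ii            / (d_in d_out - d_bi)
    middleman_i = (A A^T A)_ii        / (d_in d_out - d_bi)
    fan_in_i    = (A^T A^2)_ii        / (d_in (d_in - 1))
    fan_out_i   = (A^2 A^T)_ii        / (d_out (d_out - 1))
    total_i     = ((A + A^T)^3)_ii    / (2 (d_tot (d_tot - 1) - 2 d_bi))

Coefficients whose denominator is zero are undefined (NaN) and excluded from
all means rather than set to zero, which would bias sparse-degree nodes.
Data graphs are compared against ensembles of directed Erdős–Rényi graphs
matched to the ordered-pair edge density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "MOTIFS",
    "ClusteringProfile",
    "binarize",
    "directed_clustering",
    "er_null",
    "normalized_clustering",
    "clustering_vs_performance",
]

MOTIFS = ("cycle", "middleman", "fan_in", "fan_out", "total")


@dataclass
class ClusteringProfile:
    coefficients: dict  # motif -> (n,) array, NaN where undefined
    in_degree: np.ndarray
    out_degree: np.ndarray
    bidirectional_degree: np.ndarray
    null_mean: Optional[dict] = None  # motif -> float, from the ER ensemble
    null_sd: Optional[dict] = None

    def node_means(self) -> dict:
        """Mean coefficient across nodes where defined, per motif."""
        return {m: float(np.nanmean(v)) if np.isfinite(v).any() else np.nan
                for m, v in self.coefficients.items()}


def binarize(W: np.ndarray) -> np.ndarray:
    """Any nonzero weight becomes a directed edge; diagonal cleared."""
    A = (np.asarray(W) != 0).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def directed_clustering(adj: np.ndarray) -> ClusteringProfile:
    """Per-node clustering for the five directed triangle classes."""
    A = np.asarray(adj, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.diag(A).any():
        raise ValueError("adjacency diagonal must be zero")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("adjacency must be binary")

    At = A.T
    A2 = A @ A
    d_out = A.sum(axis=1)
    d_in = A.sum(axis=0)
    d_bi = np.diag(A2)
    d_tot = d_in + d_out
    S = A + At

    num = {
        "cycle": np.diag(A2 @ A),
        "middleman": np.diag(A @ At @ A),
        "fan_in": np.diag(At @ A2),
        "fan_out": np.diag(A2 @ At),
        "total": np.diag(S @ S @ S),
    }
    den = {
        "cycle": d_in * d_out - d_bi,
        "middleman": d_in * d_out - d_bi,
        "fan_in": d_in * (d_in - 1),
        "fan_out": d_out * (d_out - 1),
        "total": 2.0 * (d_tot * (d_tot - 1) - 2.0 * d_bi),
    }
    coeff = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for m in MOTIFS:
            c = num[m] / den[m]
            c[den[m] <= 0] = np.nan
            coeff[m] = c
    return ClusteringProfile(
        coefficients=coeff,
        in_degree=d_in.astype(int),
        out_degree=d_out.astype(int),
        bidirectional_degree=d_bi.astype(int),
    )


def er_null(
    n: int, p: float, n_graphs: int = 50, seed: int = 0
) -> tuple[dict, dict]:
    """Node-mean clustering of directed ER(n, p) graphs across an ensemble.

    Each null graph places every ordered-pair edge independently with
    probability ``p`` (so a bidirectional pair has probability p^2, matching
    the independent-placement convention).  Returns ``(mean, sd)`` per motif
    of the graph-level node-mean coefficients.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    per_graph = {m: [] for m in MOTIFS}
    for _ in range(n_graphs):
        A = (rng.random((n, n)) < p).astype(float)
        np.fill_diagonal(A, 0.0)
        prof = directed_clustering(A)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for m in MOTIFS:
                per_graph[m].append(np.nanmean(prof.coefficients[m]))
    mean = {m: float(np.nanmean(per_graph[m])) for m in MOTIFS}
    sd = {m: float(np.nanstd(per_graph[m], ddof=1)) for m in MOTIFS}
    return mean, sd


def ordered_pair_density(W: np.ndarray) -> float:
    """Directed edge density among ordered pairs (bidirectional counts twice)."""
    A = binarize(W)
    n = A.shape[0]
    return float(A.sum() / (n * (n - 1)))


def normalized_clustering(
    W: np.ndarray, n_graphs: int = 50, seed: int = 0
) -> ClusteringProfile:
    """Clustering of the binarized data graph with sparsity-matched ER nulls."""
    A = binarize(W)
    prof = directed_clustering(A)
    p = ordered_pair_density(W)
    null_mean, null_sd = er_null(A.shape[0], p, n_graphs=n_graphs, seed=seed)
    prof.null_mean = null_mean
    prof.null_sd = null_sd
    return prof


def clustering_vs_performance(
    profile: ClusteringProfile,
    ve: np.ndarray,
    n_bins: int = 5,
) -> dict:
    """Mean z-scored clustering per variance-explained bin, per motif.

    Coefficients are z-scored across nodes (undefined excluded); nodes are
    binned into equal-count bins of ``ve``.  Motifs with zero variance across
    nodes are omitted with a warning.
    """
    ve = np.asarray(ve, dtype=float)
    out: dict = {"bin_mean_ve": None, "motifs": {}}
    order = np.argsort(ve, kind="stable")
    order = order[np.isfinite(ve[order])]
    if order.size < n_bins:
        raise ValueError("fewer nodes with defined VE than bins")
    bins = np.array_split(order, n_bins)
    out["bin_mean_ve"] = np.array([ve[b].mean() for b in bins])
    for m, c in profile.coefficients.items():
        ok = np.isfinite(c)
        if ok.sum() < n_bins:
            warnings.warn(f"motif {m}: too few defined coefficients; omitted")
            continue
        sd = c[ok].std()
        if sd <= 1e-12 * max(1.0, float(np.abs(c[ok]).max())):
            warnings.warn(f"motif {m}: constant coefficient; omitted")
            continue
        z = (c - c[ok].mean()) / sd
        out["motifs"][m] = np.array([np.nanmean(z[b]) for b in bins])
    return out
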