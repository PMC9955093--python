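"""Fuzzy k-NN graph construction and the 2-D UMAP embedding.

The first phase of UMAP builds a weighted directed k-NN graph in the
high-dimensional marker space: for each cell i with neighbour distances
d_ij, the outgoing edge weights are

    w_ij = exp(−max(0, d_ij − ρ_i) / σ_i)

where ρ_i is the smallest strictly positive neighbour distance and σ_i is
calibrated so that Σ_j w_ij = log2(k).  That graph is re-implemented here
exactly (it is printed, closed-form, and testable); the second phase — the
stochastic attractive/repulsive layout optimisation — is delegated to
umap-learn, configured to the recommended operating point (nn=50,
min_dist=0.0, Euclidean metric, spectral initialisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io_core import RunConfig

logger = logging.getLogger("braque")

__all__ = [
    "NeighborGraph",
    "Embedding",
    "compute_neighbor_graph",
    "embed",
    "validate_graph",
]

#: σ sentinel for degenerate cells (all neighbours within ρ)
SIGMA_SENTINEL = 1e6
_SIGMA_LO, _SIGMA_HI = 1e-6, 1e6
_MAX_BISECT = 200
_SUM_TOL = 1e-3


@dataclass
class NeighborGraph:
    """Directed fuzzy k-NN graph with per-cell calibration parameters."""

    knn_indices: np.ndarray    # (N, k)
    knn_distances: np.ndarray  # (N, k)
    rho: np.ndarray            # (N,)
    sigma: np.ndarray          # (N,)
    weights: np.ndarray        # (N, k), each in [0, 1]
    k: int
    degenerate: np.ndarray = field(default=None)  # (N,) bool

    @property
    def n_cells(self) -> int:
        return self.knn_indices.shape[0]


@dataclass
class Embedding:
    """Per-cell 2-D coordinates plus the parameters that produced them."""

    coords: np.ndarray  # (N, 2)
    n_neighbors: int
    min_dist: float
    metric: str
    init: str
    seed: Optional[int]


def _knn_excluding_self(matrix: np.ndarray, k: int, metric: str):
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric)
    nn.fit(matrix)
    dist, idx = nn.kneighbors(matrix)
    n = matrix.shape[0]
    out_d = np.empty((n, k))
    out_i = np.empty((n, k), dtype=np.int64)
    rows = np.arange(n)
    self_pos = np.argmax(idx == rows[:, None], axis=1)
    has_self = (idx == rows[:, None]).any(axis=1)
    for i in range(n):
        drop = self_pos[i] if has_self[i] else k  # drop self, else farthest
        keep = np.r_[0:drop, drop + 1 : k + 1]
        out_d[i] = dist[i, keep]
        out_i[i] = idx[i, keep]
    return out_d, out_i


def _calibrate_sigma(d: np.ndarray, rho: float, target: float) -> tuple[float, bool]:
    """Solve Σ_j exp(−max(0, d_j − ρ)/σ) = target for σ by bisection.

    The sum is increasing in σ, so bisection on [1e-6, 1e6] converges.
    Returns (σ, degenerate): degenerate when the target is unreachable —
    e.g. every neighbour sits within ρ, making the sum constant.
    """

    def weight_sum(sigma: float) -> float:
        return float(np.exp(-np.maximum(0.0, d - rho) / sigma).sum())

    if np.all(d <= rho):
        return SIGMA_SENTINEL, True
    lo, hi = _SIGMA_LO, _SIGMA_HI
    if weight_sum(lo) > target:     # too many duplicate-range neighbours
        return lo, True
    if weight_sum(hi) < target:
        return hi, True
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        s = weight_sum(mid)
        if abs(s - target) <= _SUM_TOL:
            return mid, False
        if s < target:
            lo = mid
        else:
            hi = mid
    logger.warning("sigma bisection did not reach tolerance; using midpoint")
    return 0.5 * (lo + hi), False


def compute_neighbor_graph(
    matrix: np.ndarray, k: int, metric: str = "euclidean"
) -> NeighborGraph:
    """Exact k-NN graph with fuzzy weights normalised to Σ_j w_ij = log2(k).

    ρ_i is the smallest *strictly positive* neighbour distance, so
    duplicate points do not collapse the scale.  Cells whose k neighbours
    are all duplicates (or whose weight-sum target is unreachable) are
    flagged degenerate with a sentinel σ and logged.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}; use a smaller k")
    dist, idx = _knn_excluding_self(matrix, k, metric)
    target = np.log2(k)
    rho = np.empty(n)
    sigma = np.empty(n)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        pos = dist[i][dist[i] > 0]
        rho[i] = pos.min() if pos.size else 0.0
        sigma[i], degenerate[i] = _calibrate_sigma(dist[i], rho[i], target)
    weights = np.exp(-np.maximum(0.0, dist - rho[:, None]) / sigma[:, None])
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d degenerate cells in neighbor graph (sentinel sigma)", n_deg)
    return NeighborGraph(
        knn_indices=idx,
        knn_distances=dist,
        rho=rho,
        sigma=sigma,
        weights=weights,
        k=k,
        degenerate=degenerate,
    )


def validate_graph(graph: NeighborGraph, k: Optional[int] = None) -> dict:
    """Diagnostics: worst deviation of Σ_j w_ij from log2(k), degenerate
    cell count, σ range.  Degenerate cells are excluded from the deviation."""
    k = k or graph.k
    target = np.log2(k)
    sums = graph.weights.sum(axis=1)
    ok = ~graph.degenerate
    max_dev = float(np.abs(sums[ok] - target).max()) if ok.any() else float("nan")
    return {
        "target": float(target),
        "max_weight_sum_deviation": max_dev,
        "n_degenerate": int(graph.degenerate.sum()),
        "sigma_min": float(graph.sigma[ok].min()) if ok.any() else float("nan"),
        "sigma_max": float(graph.sigma[ok].max()) if ok.any() else float("nan"),
    }


def embed(matrix: np.ndarray, config: RunConfig, seed: Optional[int] = None) -> Embedding:
    """2-D UMAP embedding of the preprocessed marker matrix.

    Delegates the graph + layout optimisation to umap-learn with the
    configured neighbour count, min_dist, metric and spectral
    initialisation; a fixed seed makes the layout deterministic.
    """
    import umap  # deferred: numba JIT import cost

    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite values")
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_neighbors=config.umap_nn,
                min_dist=config.umap_min_dist,
                metric=config.umap_metric,
                init=config.umap_init,
                n_components=2,
                random_state=seed,
                low_memory=True,
            )
            coords = reducer.fit_transform(matrix)
    except Exception as exc:  # surface delegation failures with their message
        raise RuntimeError(f"UMAP embedding failed: {exc}") from exc
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        n_neighbors=config.umap_nn,
        min_dist=config.umap_min_dist,
        metric=config.umap_metric,
        init=config.umap_init,
        seed=seed,
    )
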