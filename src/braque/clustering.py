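"""Density-based clustering of the embedding with a two-phase policy.

HDBSCAN is applied on the 2-D embedding.  min_samples follows the rule
max(0.005% of cells, 10): proportional to sample size but floored to avoid
micro-clusterisation.  Phase 1 extracts clusters by excess-of-mass (eom).
Dense, spatially intermingled populations (e.g. CD4+ T cells and B cells
in lymphoid tissue) can survive phase 1 as a single large cluster, so
phase 2 re-clusters the biggest phase-1 cluster alone, using leaf
extraction and min_samples × 10 for a finer, more conservative split.
Cells that neither phase can place confidently keep the noise label −1 —
a bin of unclear cells that is deliberately left uncharacterised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import HDBSCAN

from ._hdbscan_compat import extract_labels
from .io_core import RunConfig

logger = logging.getLogger("braque")

__all__ = [
    "ClusterLabels",
    "compute_min_samples",
    "cluster_embedding",
    "two_phase_cluster",
    "finalize_labels",
]

NOISE = -1


@dataclass
class ClusterLabels:
    """Per-cell integer labels (−1 = noise) with phase provenance."""

    labels: np.ndarray                 # (N,) int, -1 = noise
    phase: np.ndarray                  # (N,) 1 or 2: which pass labelled the cell
    min_samples_used: dict = field(default_factory=dict)  # phase -> min_samples

    @property
    def n_clusters(self) -> int:
        return int((np.unique(self.labels) >= 0).sum())

    @property
    def noise_fraction(self) -> float:
        return float((self.labels == NOISE).mean())

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def compute_min_samples(
    n_cells: int, frac: float = 0.00005, floor: int = 10
) -> int:
    """min_samples = max(ceil(frac · n_cells), floor)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return max(math.ceil(frac * n_cells), floor)


def cluster_embedding(
    coords: np.ndarray,
    min_samples: int,
    selection_eps: float = 0.1,
    method: str = "eom",
    seed: Optional[int] = None,
) -> ClusterLabels:
    """One HDBSCAN pass on 2-D coordinates.

    min_cluster_size is set equal to min_samples.  The ``seed`` parameter
    is accepted for interface uniformity; the delegated implementation is
    deterministic.  An all-noise result is valid (warned, not raised).
    """
    coords = np.asarray(coords, dtype=float)
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if method not in ("eom", "leaf"):
        raise ValueError("method must be 'eom' or 'leaf'")
    # Fit with epsilon 0 to build the mutual-reachability single-linkage
    # tree, then extract labels at the requested epsilon/method through the
    # compat extractor (see braque._hdbscan_compat for why).
    model = HDBSCAN(
        min_cluster_size=min_samples,
        min_samples=min_samples,
        cluster_selection_epsilon=0.0,
        cluster_selection_method=method,
        copy=True,
    )
    model.fit(coords)
    labels = extract_labels(
        model._single_linkage_tree_,
        min_cluster_size=min_samples,
        method=method,
        epsilon=selection_eps,
    )
    if (labels >= 0).sum() == 0:
        logger.warning("HDBSCAN labelled every cell as noise")
    return ClusterLabels(
        labels=labels.astype(int),
        phase=np.ones(len(labels), dtype=int),
        min_samples_used={1: min_samples},
    )


def two_phase_cluster(
    coords: np.ndarray, config: RunConfig, seed: Optional[int] = None
) -> ClusterLabels:
    """eom pass over all cells, then a finer leaf pass on the biggest cluster.

    Phase-2 sublabels replace the biggest phase-1 cluster's labels; cells
    the leaf pass cannot place stay noise (−1) rather than reverting to the
    coarse label.  Final ids are contiguous, ordered by descending size.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    ms = compute_min_samples(
        n, config.hdbscan_min_samples_frac, config.hdbscan_min_samples_floor
    )
    phase1 = cluster_embedding(
        coords, ms, config.cluster_selection_eps, method="eom", seed=seed
    )
    if not config.two_phase or phase1.n_clusters == 0:
        if phase1.n_clusters == 0:
            logger.warning("phase 1 found no clusters; skipping phase 2")
        return finalize_labels(phase1)

    sizes = phase1.cluster_sizes()
    biggest = max(sizes, key=lambda c: (sizes[c], -c))
    member = phase1.labels == biggest
    ms2 = ms * config.phase2_min_samples_mult
    if member.sum() <= ms2:
        logger.warning(
            "biggest cluster (%d cells) too small for phase 2 (min_samples=%d)",
            member.sum(),
            ms2,
        )
        return finalize_labels(phase1)

    phase2 = cluster_embedding(
        coords[member], ms2, config.cluster_selection_eps, method="leaf", seed=seed
    )
    if phase2.n_clusters == 0:
        # nothing to split: the biggest cluster is homogeneous at the finer
        # scale, so it survives phase 1 intact rather than dissolving to noise
        logger.info("phase 2 found no sub-clusters; biggest cluster kept whole")
        return finalize_labels(phase1)
    labels = phase1.labels.copy()
    phase = phase1.phase.copy()
    offset = int(phase1.labels.max()) + 1
    sub = phase2.labels.copy()
    sub[sub >= 0] += offset
    labels[member] = sub
    phase[member] = 2
    merged = ClusterLabels(
        labels=labels,
        phase=phase,
        min_samples_used={1: ms, 2: ms2},
    )
    out = finalize_labels(merged)
    logger.info(
        "two-phase clustering: %d phase-1 clusters, biggest (%d cells) -> "
        "%d phase-2 clusters, %d final",
        len(sizes),
        int(member.sum()),
        phase2.n_clusters,
        out.n_clusters,
    )
    return out


def finalize_labels(labels: ClusterLabels) -> ClusterLabels:
    """Relabel clusters contiguously 0..n−1 by descending size (ties by
    ascending old label); noise stays −1.  Deterministic."""
    lab = np.asarray(labels.labels)
    ids, counts = np.unique(lab[lab >= 0], return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    mapping = {int(ids[i]): rank for rank, i in enumerate(order)}
    new = np.array([mapping[v] if v >= 0 else NOISE for v in lab], dtype=int)
    return ClusterLabels(
        labels=new,
        phase=np.asarray(labels.phase).copy(),
        min_samples_used=dict(labels.min_samples_used),
    )
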