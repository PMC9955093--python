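"""Per-cluster marker statistics, ranking, tier detection and report plots.

For every cluster, each marker is compared between group 2 (the cluster's
cells) and group 1 (every other cell in the sample, noise included) with a
one-tailed Welch t-test (alternative: cluster mean greater), Bonferroni
corrected over the whole run (M markers × n clusters).  Because p-values
at 1e5–1e6 cells become uninformative (everything is "significant"), the
ranking itself uses a signed robust effect size

    d_signed = (m2 − m1) / sqrt( v1·(N1+N2)/N1 + v2·(N1+N2)/N2 )

which equals t_welch / sqrt(N1+N2) and is antisymmetric under group swap.
Markers are ranked by descending d_signed, and the two biggest gaps in the
positive ranked effect sizes partition the top of the ranking into Tier 1
("probably expressed", above the first gap) and Tier 2 ("possibly
expressed", between the two gaps) — the summary an expert uses to assign a
cell type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import NOISE, ClusterLabels
from .io_core import CellTable

logger = logging.getLogger("braque")

__all__ = [
    "ClusterProfile",
    "welch_one_tailed",
    "bonferroni",
    "signed_effect_size",
    "rank_markers",
    "detect_tiers",
    "characterize_clusters",
    "render_cluster_report",
    "render_global_map",
]

#: p-value bands used only for plot colouring
P_BANDS = (0.05, 1e-5, 1e-100)


@dataclass
class ClusterProfile:
    """All per-marker statistics for one cluster vs the rest of the sample."""

    cluster_id: int
    marker_names: list[str]
    m1: np.ndarray         # rest-of-sample means
    m2: np.ndarray         # cluster means
    v1: np.ndarray
    v2: np.ndarray
    n1: int
    n2: int
    d_signed: np.ndarray
    p_raw: np.ndarray      # NaN when the test was not applicable
    p_bonf: np.ndarray
    ranked_markers: list[str]
    tier1: list[str] = field(default_factory=list)
    tier2: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        tier = np.full(len(self.marker_names), "none", dtype=object)
        for name in self.tier1:
            tier[self.marker_names.index(name)] = "1"
        for name in self.tier2:
            tier[self.marker_names.index(name)] = "2"
        return pd.DataFrame(
            {
                "marker": self.marker_names,
                "m1": self.m1,
                "m2": self.m2,
                "v1": self.v1,
                "v2": self.v2,
                "N1": self.n1,
                "N2": self.n2,
                "d_signed": self.d_signed,
                "p_raw": self.p_raw,
                "p_bonf": self.p_bonf,
                "tier": tier,
            }
        )


def welch_one_tailed(group2: np.ndarray, group1: np.ndarray) -> float:
    """Upper-tail Welch t-test p-value for mean(group2) > mean(group1).

    Unequal variances, Welch–Satterthwaite degrees of freedom.  A zero
    pooled standard error with equal means gives p = 0.5 (t = 0 by
    convention); with unequal means the p-value is the exact 0/1 limit.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 values")
    m1, m2 = g1.mean(), g2.mean()
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return 0.5 if m1 == m2 else (0.0 if m2 > m1 else 1.0)
    t = (m2 - m1) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(stats.t.sf(t, df))


def bonferroni(p_raw: float, n_tests: int) -> float:
    """min(1, p·n_tests); the family is all markers × all clusters."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_raw * n_tests)


def signed_effect_size(
    m1: float, v1: float, n1: int, m2: float, v2: float, n2: int
) -> float:
    """Signed robust Cohen's d of group 2 vs group 1.

    d_signed = (m2 − m1) / sqrt(v1·(N1+N2)/N1 + v2·(N1+N2)/N2), where v_i
    is the group variance.  Identically t_welch/sqrt(N1+N2); symmetric in
    magnitude and antisymmetric in sign under group swap.  Zero pooled
    variance with equal means gives 0; with unequal means a signed
    infinity sentinel (warned).
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("variances must be non-negative")
    big_v = v1 * (n1 + n2) / n1 + v2 * (n1 + n2) / n2
    diff = m2 - m1
    if big_v == 0.0:
        if diff == 0.0:
            return 0.0
        logger.warning("zero pooled variance with unequal means: infinite d")
        return math.copysign(math.inf, diff)
    return diff / math.sqrt(big_v)


def rank_markers(d_signed: dict[str, float]) -> list[str]:
    """Marker names by descending effect size; ties alphabetical."""
    if not d_signed:
        raise ValueError("need at least one marker")
    return sorted(d_signed, key=lambda name: (-d_signed[name], name))


def detect_tiers(ranked_positive: Sequence[float]) -> tuple[list[int], list[int]]:
    """Split ranked positive effect sizes at their two biggest gaps.

    Input: effect sizes of the positive markers, descending.  Gaps are
    consecutive differences; the two largest are located and the "first"
    gap is the one higher in the ranking.  Returns (tier1, tier2) as index
    lists into the input: tier1 = above the first gap, tier2 = between the
    gaps.  With fewer than 3 positive markers or fewer than 2 gaps, the
    degenerate rule applies: tier1 = all positive markers, tier2 = empty.
    """
    d = np.asarray(ranked_positive, dtype=float)
    if d.size and (np.any(d <= 0) or np.any(np.diff(d) > 0)):
        raise ValueError("input must be descending positive effect sizes")
    if d.size == 0:
        logger.warning("no positive markers: both tiers empty")
        return [], []
    if d.size < 3:
        logger.info("degenerate tier rule: %d positive markers", d.size)
        return list(range(d.size)), []
    gaps = -np.diff(d)  # gaps[i] between rank i and i+1
    top2 = np.argsort(-gaps, kind="stable")[:2]
    first, second = int(top2.min()), int(top2.max())
    tier1 = list(range(0, first + 1))
    tier2 = list(range(first + 1, second + 1))
    return tier1, tier2


def characterize_clusters(
    values: np.ndarray | CellTable,
    labels: ClusterLabels,
    marker_names: Optional[list[str]] = None,
    include_noise_in_rest: bool = True,
) -> list[ClusterProfile]:
    """Profile every non-noise cluster against the rest of the sample.

    ``values`` is the matrix characterisation operates on — by default the
    LNS-preprocessed matrix for pipeline consistency, but the raw marker
    matrix may be passed instead.  Noise cells belong to group 1 unless
    ``include_noise_in_rest`` is off; the noise cluster itself is never
    profiled.  Clusters smaller than 2 cells get effect sizes but NaN
    p-values (warned).
    """
    if isinstance(values, CellTable):
        marker_names = values.marker_names
        values = values.markers
    values = np.asarray(values, dtype=float)
    if marker_names is None:
        marker_names = [f"marker_{j}" for j in range(values.shape[1])]
    lab = np.asarray(labels.labels)
    cluster_ids = [int(c) for c in np.unique(lab) if c >= 0]
    if not cluster_ids:
        raise ValueError("no non-noise clusters to characterize")
    m_markers = values.shape[1]
    n_tests = m_markers * len(cluster_ids)

    profiles = []
    for cid in cluster_ids:
        in_cluster = lab == cid
        rest = ~in_cluster if include_noise_in_rest else (~in_cluster) & (lab != NOISE)
        g2 = values[in_cluster]
        g1 = values[rest]
        n2, n1 = g2.shape[0], g1.shape[0]
        m2, m1 = g2.mean(axis=0), g1.mean(axis=0)
        v2 = g2.var(ddof=1, axis=0) if n2 >= 2 else np.full(m_markers, np.nan)
        v1 = g1.var(ddof=1, axis=0) if n1 >= 2 else np.full(m_markers, np.nan)
        d = np.array(
            [
                signed_effect_size(
                    m1[j],
                    v1[j] if n1 >= 2 else 0.0,
                    n1,
                    m2[j],
                    v2[j] if n2 >= 2 else 0.0,
                    n2,
                )
                for j in range(m_markers)
            ]
        )
        if n1 >= 2 and n2 >= 2:
            p_raw = np.array(
                [welch_one_tailed(g2[:, j], g1[:, j]) for j in range(m_markers)]
            )
            p_bonf = np.array([bonferroni(p, n_tests) for p in p_raw])
        else:
            logger.warning(
                "cluster %d: group sizes (%d, %d) too small for a t-test", cid, n1, n2
            )
            p_raw = np.full(m_markers, np.nan)
            p_bonf = np.full(m_markers, np.nan)

        d_by_name = dict(zip(marker_names, d))
        ranked = rank_markers(d_by_name)
        ranked_pos = [name for name in ranked if d_by_name[name] > 0]
        t1_idx, t2_idx = detect_tiers([d_by_name[name] for name in ranked_pos])
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                marker_names=list(marker_names),
                m1=m1,
                m2=m2,
                v1=v1,
                v2=v2,
                n1=n1,
                n2=n2,
                d_signed=d,
                p_raw=p_raw,
                p_bonf=p_bonf,
                ranked_markers=ranked,
                tier1=[ranked_pos[i] for i in t1_idx],
                tier2=[ranked_pos[i] for i in t2_idx],
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# report plots
# ---------------------------------------------------------------------------


def _p_color(p: float) -> str:
    if not np.isfinite(p):
        return "0.6"
    if p < P_BANDS[2]:
        return "#b2182b"
    if p < P_BANDS[1]:
        return "#ef8a62"
    if p < P_BANDS[0]:
        return "#fddbc7"
    return "0.6"


def render_cluster_report(
    profile: ClusterProfile,
    table: CellTable,
    labels: ClusterLabels,
    embedding,
    out_dir,
    n_overlay_markers: int = 4,
) -> list[Path]:
    """Write the three per-cluster report figures plus the profile CSV.

    (a) ranked signed effect sizes, bars coloured by Welch p band;
    (b) whole-sample vs cluster distribution overlays for the top markers;
    (c) cluster highlighted in UMAP space and, when coordinates exist, in
        tissue space, with Tier 1/Tier 2 in the subtitle.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cid = profile.cluster_id
    written: list[Path] = []
    member = np.asarray(labels.labels) == cid
    d_by_name = dict(zip(profile.marker_names, profile.d_signed))
    p_by_name = dict(zip(profile.marker_names, profile.p_raw))

    # (a) ranked effect sizes
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(profile.ranked_markers))))
    names = profile.ranked_markers
    ax.barh(
        range(len(names))[::-1],
        [d_by_name[n] for n in names],
        color=[_p_color(p_by_name[n]) for n in names],
    )
    ax.set_yticks(range(len(names))[::-1], names, fontsize=6)
    ax.set_xlabel("signed effect size d")
    ax.set_title(f"cluster {cid}: ranked markers (n={profile.n2})")
    path = out_dir / f"cluster_{cid:03d}_ranked_markers.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    # (b) distribution overlays for the top-ranked markers
    top = profile.ranked_markers[:n_overlay_markers]
    fig, axes = plt.subplots(1, len(top), figsize=(3 * len(top), 2.6), squeeze=False)
    for ax, name in zip(axes[0], top):
        j = profile.marker_names.index(name)
        ax.hist(table.markers[:, j], bins=50, density=True, alpha=0.5,
                color="tab:blue", label="sample")
        ax.hist(table.markers[member, j], bins=50, density=True, alpha=0.5,
                color="tab:red", label="cluster")
        ax.set_title(name, fontsize=8)
    axes[0, 0].legend(fontsize=6)
    fig.suptitle(f"cluster {cid}: marker distributions")
    path = out_dir / f"cluster_{cid:03d}_distributions.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    # (c) UMAP-space and tissue-space location
    has_space = table.has_coordinates
    if not has_space:
        logger.warning("no spatial coordinates: location plot shows UMAP panel only")
    ncols = 2 if has_space else 1
    fig, axes = plt.subplots(1, ncols, figsize=(5 * ncols, 4.4), squeeze=False)
    coords = np.asarray(embedding.coords if hasattr(embedding, "coords") else embedding)
    axes[0, 0].scatter(coords[:, 0], coords[:, 1], s=1, c="0.8", rasterized=True)
    axes[0, 0].scatter(coords[member, 0], coords[member, 1], s=2, c="tab:red")
    axes[0, 0].set_title("UMAP embedding")
    if has_space:
        axes[0, 1].scatter(table.x, table.y, s=1, c="0.8", rasterized=True)
        axes[0, 1].scatter(table.x[member], table.y[member], s=2, c="tab:red")
        axes[0, 1].set_title("tissue coordinates")
    sub = "Tier 1: " + (", ".join(profile.tier1) or "—")
    if profile.tier2:
        sub += "  |  Tier 2: " + ", ".join(profile.tier2)
    fig.suptitle(f"cluster {cid} location\n{sub}", fontsize=9)
    path = out_dir / f"cluster_{cid:03d}_location.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    csv_path = out_dir / f"cluster_{cid:03d}_profile.csv"
    profile.to_frame().to_csv(csv_path, index=False)
    written.append(csv_path)
    return written


def render_global_map(
    table: CellTable,
    labels: ClusterLabels,
    profiles: list[ClusterProfile],
    path,
    n_label_markers: int = 3,
) -> Optional[Path]:
    """Tissue-space scatter of all clusters, each annotated with its top
    markers by effect size.  Skipped (None) without spatial coordinates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not table.has_coordinates:
        logger.warning("no spatial coordinates: global map skipped")
        return None
    lab = np.asarray(labels.labels)
    fig, ax = plt.subplots(figsize=(8, 7))
    cmap = plt.get_cmap("tab20")
    noise = lab == NOISE
    ax.scatter(table.x[noise], table.y[noise], s=1, c="0.85", rasterized=True)
    for prof in profiles:
        member = lab == prof.cluster_id
        color = cmap(prof.cluster_id % 20)
        ax.scatter(table.x[member], table.y[member], s=2, color=color, rasterized=True)
        cx, cy = table.x[member].mean(), table.y[member].mean()
        tag = ",".join(prof.ranked_markers[:n_label_markers])
        ax.annotate(f"{prof.cluster_id}:{tag}", (cx, cy), fontsize=5)
    ax.set_title("clusters on tissue, labelled by most expressed markers")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
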