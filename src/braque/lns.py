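"""Lognormal Shrinkage (LNS) preprocessing.

Marker intensities from immunofluorescence imaging are continuous,
non-negative, and typically well described per subpopulation by lognormal
distributions.  LNS exploits this: each marker is robustly scaled, shifted
and log-transformed, a univariate Bayesian Gaussian mixture with a
Dirichlet-process weight prior is fitted by variational inference, each
cell is assigned to the mixture component it most likely belongs to, and
its value is contracted towards that component's mean by a factor γ:

    x_new = m_i + (x − m_i) / γ

The contraction fragments the marker distribution at plausible
subpopulation boundaries while preserving the within-component ordering of
values, so the downstream embedding sees amplified gaps between candidate
subpopulations.  The goal is not a perfect deconvolution — over-guessing
components is harmless because the embedding and clustering steps decide
which fragments are real.

Zeros (absent marker after segmentation) are handled by the shift
constant: after ``log(x + ε)`` they form a spike far to the left of the
data which the mixture dedicates a component to, isolating the
"not expressed" subpopulation automatically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import median_abs_deviation
from sklearn.mixture import BayesianGaussianMixture

from .io_core import RunConfig

logger = logging.getLogger("braque")

__all__ = [
    "MarkerMixtureFit",
    "ShrinkageResult",
    "robust_scale",
    "log_shift",
    "fit_bayesian_mixture",
    "responsibilities",
    "assign_to_component",
    "shrink_values",
    "convert_contraction_factor",
    "lns_transform_marker",
    "lns_transform_table",
    "saturation_report",
    "SaturationReport",
    "lognormal_moments",
]


@dataclass
class MarkerMixtureFit:
    """Fitted per-marker mixture in log space.

    ``used_component_count`` counts components that received at least one
    cell by argmax-responsibility assignment; Dirichlet-process variational
    weights are never exactly zero, so occupancy — not a weight threshold —
    defines whether a component is "used".
    """

    means: np.ndarray            # (K,) component means, log space
    variances: np.ndarray        # (K,) component variances, log space
    weights: np.ndarray          # (K,) mixture weights, sum to 1
    n_components_requested: int
    assignments: np.ndarray      # (N,) per-cell component index
    used_component_count: int
    mad_pre: float               # MAD used for the robust scaling step
    shift: float                 # shift constant added before the log
    converged: bool

    def __post_init__(self) -> None:
        assert abs(self.weights.sum() - 1.0) < 1e-9
        assert np.all(self.variances > 0)


@dataclass
class ShrinkageResult:
    """Output of LNS on one marker, back in the original (linear) space."""

    values_out: np.ndarray
    fit: Optional[MarkerMixtureFit]   # None for degenerate (constant) markers
    contraction_factor: float
    log_base: float
    degenerate: bool = False


def robust_scale(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide by the median absolute deviation (no centering).

    The plain MAD is used (no 1.4826 normal-consistency constant).  A zero
    MAD falls back to the standard deviation; if that is also zero the
    marker is constant — the caller treats it as degenerate.  Returns the
    scaled values and the divisor used (0.0 signals a degenerate marker).
    """
    values = np.asarray(values, dtype=float)
    mad = float(median_abs_deviation(values, scale=1.0))
    if mad == 0.0:
        sd = float(values.std())
        if sd == 0.0:
            logger.warning("constant marker: MAD and SD both zero, passthrough")
            return values.copy(), 0.0
        logger.warning("MAD is zero, falling back to standard deviation")
        mad = sd
    return values / mad, mad


def log_shift(values: np.ndarray, shift_epsilon: float, log_base: float) -> np.ndarray:
    """``log_base(values + shift_epsilon)``; zeros map to ``log_base(ε)``."""
    if shift_epsilon <= 0:
        raise ValueError("shift_epsilon must be positive")
    return np.log(np.asarray(values, dtype=float) + shift_epsilon) / math.log(log_base)


def fit_bayesian_mixture(
    logvalues: np.ndarray,
    k_max: int = 15,
    tol: float = 1e-2,
    max_iter: int = 1500,
    seed: Optional[int] = None,
) -> MarkerMixtureFit:
    """Variational Bayesian Gaussian mixture fit on 1-D log-space values.

    Uses a Dirichlet-process weight prior and free per-component variance,
    so only as many of the ``k_max`` components as the data support receive
    appreciable weight.  Non-convergence within ``max_iter`` is logged, not
    raised — a time-bounded fit is still a usable guess.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    x = np.asarray(logvalues, dtype=float).reshape(-1, 1)
    bgm = BayesianGaussianMixture(
        n_components=k_max,
        weight_concentration_prior_type="dirichlet_process",
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # sklearn convergence warning; we log it
        bgm.fit(x)
    if not bgm.converged_:
        logger.warning(
            "mixture fit did not converge in %d iterations (tol=%g)", max_iter, tol
        )
    means = bgm.means_.ravel()
    variances = bgm.covariances_.reshape(-1)
    weights = bgm.weights_ / bgm.weights_.sum()
    assignments = _assign_all(x.ravel(), means, variances, weights)
    used = int(len(np.unique(assignments)))
    return MarkerMixtureFit(
        means=means,
        variances=variances,
        weights=weights,
        n_components_requested=k_max,
        assignments=assignments,
        used_component_count=used,
        mad_pre=float("nan"),
        shift=float("nan"),
        converged=bool(bgm.converged_),
    )


def responsibilities(x, means, variances, weights) -> np.ndarray:
    """Posterior component responsibilities P(component i | x), rows sum to 1."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    log_pdf = (
        -0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        - 0.5 * np.log(2 * np.pi * variances[None, :])
        + np.log(weights[None, :])
    )
    log_pdf -= log_pdf.max(axis=1, keepdims=True)
    p = np.exp(log_pdf)
    return p / p.sum(axis=1, keepdims=True)


def _assign_all(x, means, variances, weights) -> np.ndarray:
    # argmax returns the first (lowest-index) maximizer: the tie rule
    return np.argmax(responsibilities(x, means, variances, weights), axis=1)


def assign_to_component(x: float, fit: MarkerMixtureFit) -> int:
    """Index of the component ``x`` most likely belongs to.

    Assignment maximises the posterior responsibility
    π_i·N(x; m_i, σ_i²); ties break to the lowest component index.
    """
    return int(_assign_all(x, fit.means, fit.variances, fit.weights)[0])


def shrink_values(
    logvalues: np.ndarray,
    assignments: np.ndarray,
    fit: MarkerMixtureFit,
    contraction_factor: float,
) -> np.ndarray:
    """Contract each value towards its component mean: m + (x − m)/γ.

    γ=1 is the identity; γ→∞ collapses each component to its mean.  The
    map is affine and increasing within a component, so within-component
    ordering is exactly preserved.
    """
    if contraction_factor < 1:
        raise ValueError("contraction factor must be >= 1")
    m = fit.means[np.asarray(assignments)]
    return m + (np.asarray(logvalues, dtype=float) - m) / contraction_factor


def convert_contraction_factor(gamma_base2: float, new_base: float) -> float:
    """Contraction factor to use when switching the log base from 2.

    Implements the recommended rule γ_new = γ_base2 / ln(new_base) — e.g.
    base 10 with γ_base2 = 5 gives 5/ln(10) ≈ 2.17 ≈ 2.  Note this is a
    rule of thumb, not the exact change-of-base factor
    γ·ln(2)/ln(new_base) ≈ 1.505; see docs/methods.md.
    """
    if new_base <= 1:
        raise ValueError("new_base must be > 1")
    return gamma_base2 / math.log(new_base)


def lns_transform_marker(
    values: np.ndarray, config: RunConfig, seed: Optional[int] = None
) -> ShrinkageResult:
    """Full LNS on one marker: scale, shift, log, fit, assign, shrink,
    back-transform, re-anchor at zero, optional robust rescale."""
    values = np.asarray(values, dtype=float)
    scaled, mad = robust_scale(values)
    if mad == 0.0:
        return ShrinkageResult(
            values_out=values.copy(),
            fit=None,
            contraction_factor=config.contraction_factor,
            log_base=config.log_base,
            degenerate=True,
        )
    logv = log_shift(scaled, config.shift_epsilon, config.log_base)
    fit = fit_bayesian_mixture(
        logv,
        k_max=config.bgm_max_components,
        tol=config.bgm_tol,
        max_iter=config.bgm_max_iter,
        seed=seed,
    )
    fit.mad_pre = mad
    fit.shift = config.shift_epsilon
    shrunk = shrink_values(logv, fit.assignments, fit, config.contraction_factor)
    out = np.power(config.log_base, shrunk)
    out -= out.min()
    if config.rescale_after_lns:
        post_mad = float(median_abs_deviation(out, scale=1.0))
        if post_mad == 0.0:
            post_mad = float(out.std()) or 1.0
        out /= post_mad
    return ShrinkageResult(
        values_out=out,
        fit=fit,
        contraction_factor=config.contraction_factor,
        log_base=config.log_base,
    )


def marker_seed(run_seed: int, marker_index: int) -> int:
    """Deterministic per-marker seed below 2**31."""
    ss = np.random.SeedSequence(entropy=run_seed, spawn_key=(marker_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def lns_transform_table(
    markers: np.ndarray, config: RunConfig, seed: int
) -> tuple[np.ndarray, list[Optional[MarkerMixtureFit]]]:
    """Apply LNS independently to every marker column.

    Per-marker seeds derive deterministically from the run seed, so markers
    are independent but the run reproduces bit-for-bit.  A degenerate
    marker passes through unchanged (with a warning); it never aborts the
    table.  Returns the transformed matrix (input row order) and one fit
    record per marker (``None`` where degenerate).
    """
    markers = np.asarray(markers, dtype=float)
    out = np.empty_like(markers)
    fits: list[Optional[MarkerMixtureFit]] = []
    for j in range(markers.shape[1]):
        res = lns_transform_marker(markers[:, j], config, seed=marker_seed(seed, j))
        out[:, j] = res.values_out
        fits.append(res.fit)
    return out, fits


@dataclass
class SaturationReport:
    """Did the component budget K_max suffice for (almost) every marker?"""

    histogram: dict[int, int]      # used_component_count -> n markers
    fraction_with_discard: float   # markers with >= 1 unused component
    saturated: bool                # True when that fraction < 0.95
    n_markers: int


def saturation_report(
    fits: list[Optional[MarkerMixtureFit]], k_max: int
) -> SaturationReport:
    """Check whether ``k_max`` mixture components were enough.

    A marker "discards" a component when at least one of its ``k_max``
    components receives no cells.  If fewer than 95% of markers discard,
    the budget is flagged saturated and should be raised.
    Degenerate markers (no fit) are excluded from the denominator.
    """
    counts = [f.used_component_count for f in fits if f is not None]
    if not counts:
        raise ValueError("no non-degenerate marker fits")
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    frac = sum(1 for c in counts if c < k_max) / len(counts)
    return SaturationReport(
        histogram=dict(sorted(hist.items())),
        fraction_with_discard=frac,
        saturated=frac < 0.95,
        n_markers=len(counts),
    )


def lognormal_moments(
    mu_log: float, var_log: float, base: float = math.e
) -> tuple[float, float]:
    """Mean and variance in linear space of ``base**Normal(mu_log, var_log)``.

    A normal component in log space back-transforms to a lognormal with

        mean     = exp(μ' + σ'²/2)
        variance = (exp(σ'²) − 1) · exp(2μ' + σ'²)

    where μ' = μ·ln(base), σ'² = σ²·ln(base)² convert base-``base``
    log-space parameters to natural-log ones.
    """
    if var_log < 0:
        raise ValueError("variance must be non-negative")
    lb = math.log(base)
    mu = mu_log * lb
    var = var_log * lb * lb
    mean = math.exp(mu + var / 2.0)
    variance = (math.exp(var) - 1.0) * math.exp(2.0 * mu + var)
    return mean, variance
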