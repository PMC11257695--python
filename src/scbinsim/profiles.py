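"""Gene distribution categories, parametric fits and the classifier cascade.

Each gene of the reference is assigned exactly one category:

* ``DISCARDED`` — excessive dropout, insufficient dynamic range
  (amplitude below a fraction of the median amplitude), or too few
  non-zero observations to support a fit.
* ``BIMODAL`` — significant Hartigan dip test and a high Bimodality
  Index on the non-zero values; fitted with a two-component Gaussian
  mixture.
* ``ZERO_INFLATED`` — the kernel-density peak of the full distribution
  sits in the lowest band of the gene's amplitude (an excess of zeros
  dominates); the non-zero sub-distribution falls back to a unimodal or
  bimodal fit.
* ``UNIMODAL`` — everything else; a nonparametric quantile table plus
  (mu, sigma) of the non-zero values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .dropout import DropoutParams, rate_param
from .stats import GeneStats, compute_gene_stats, fit_gaussian_mixture2

__all__ = [
    "GeneCategory",
    "ClassifierConfig",
    "UnimodalFit",
    "BimodalFit",
    "GeneProfile",
    "classify_gene",
    "fit_profile",
]


class GeneCategory(str, enum.Enum):
    DISCARDED = "discarded"
    BIMODAL = "bimodal"
    ZERO_INFLATED = "zero_inflated"
    UNIMODAL = "unimodal"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the classification cascade.

    dropout_discard_threshold: discard genes with a higher zero fraction.
    amplitude_divisor: discard genes with amplitude below
        median_amplitude / amplitude_divisor.
    dip_alpha, bi_threshold: a gene is bimodal when its dip-test p-value
        is below dip_alpha AND its Bimodality Index exceeds bi_threshold.
    zero_peak_fraction: a non-bimodal gene is zero-inflated when its
        density peak lies within the lowest fraction of its amplitude.
    min_nonzero: minimum positive observations to attempt any fit.
    """

    dropout_discard_threshold: float = 0.95
    amplitude_divisor: float = 10.0
    dip_alpha: float = 0.05
    bi_threshold: float = 1.5
    zero_peak_fraction: float = 0.10
    min_nonzero: int = 10
    random_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.dropout_discard_threshold <= 1.0:
            raise ValueError("dropout_discard_threshold must be in (0, 1]")
        if self.amplitude_divisor <= 0:
            raise ValueError("amplitude_divisor must be positive")
        if not 0.0 < self.dip_alpha < 1.0:
            raise ValueError("dip_alpha must be in (0, 1)")
        if self.bi_threshold < 0:
            raise ValueError("bi_threshold must be non-negative")
        if not 0.0 < self.zero_peak_fraction < 1.0:
            raise ValueError("zero_peak_fraction must be in (0, 1)")
        if self.min_nonzero < 2:
            raise ValueError("min_nonzero must be at least 2")


_QUANTILE_PROBS = np.linspace(0.0, 1.0, 201)


@dataclass(frozen=True)
class UnimodalFit:
    """Mean/sd of the non-zero values plus an empirical quantile table.

    The quantile table stores linearly interpolated ("type 7") quantiles
    of the non-zero values on a fixed probability grid; Q(q) between
    grid points is linearly interpolated, which is exact for the default
    binarisation quantiles (multiples of 0.005).
    """

    mu: float
    sigma: float
    quantile_values: np.ndarray
    quantile_probs: np.ndarray = field(default_factory=lambda: _QUANTILE_PROBS.copy())

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        q = np.asarray(self.quantile_values, dtype=float)
        if np.any(np.diff(q) < -1e-12):
            raise ValueError("quantile table must be non-decreasing")

    def quantile(self, q: float) -> float:
        return float(np.interp(q, self.quantile_probs, self.quantile_values))

    @property
    def iqr(self) -> float:
        return self.quantile(0.75) - self.quantile(0.25)

    @classmethod
    def from_values(cls, nonzero_values) -> "UnimodalFit":
        x = np.asarray(nonzero_values, dtype=float)
        qv = np.quantile(x, _QUANTILE_PROBS, method="linear")
        sigma = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return cls(mu=float(np.mean(x)), sigma=sigma, quantile_values=qv)


@dataclass(frozen=True)
class BimodalFit:
    """Two-component Gaussian mixture with mu2 > mu1."""

    phi1: float
    mu1: float
    sigma1: float
    phi2: float
    mu2: float
    sigma2: float

    def __post_init__(self):
        if not np.isclose(self.phi1 + self.phi2, 1.0):
            raise ValueError("component weights must sum to 1")
        if self.phi1 <= 0 or self.phi2 <= 0:
            raise ValueError("component weights must be positive")
        if not self.mu2 > self.mu1:
            raise ValueError("component means must satisfy mu2 > mu1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component standard deviations must be positive")


@dataclass(frozen=True)
class GeneProfile:
    """Everything learnt about one gene.

    For ZERO_INFLATED genes ``fit`` describes the non-zero
    sub-distribution and ``subcategory`` names which sub-case applies
    (unimodal or bimodal); for DISCARDED genes only ``stats`` is
    populated, with the reason recorded.
    """

    category: GeneCategory
    stats: GeneStats
    fit: UnimodalFit | BimodalFit | None = None
    subcategory: GeneCategory | None = None
    dropout: DropoutParams | None = None
    discard_reason: str | None = None

    def __post_init__(self):
        if self.category is GeneCategory.DISCARDED:
            if self.fit is not None:
                raise ValueError("discarded genes carry stats only")
        elif self.fit is None:
            raise ValueError(f"{self.category.value} gene requires a fit")
        if self.category is GeneCategory.BIMODAL and not isinstance(self.fit, BimodalFit):
            raise ValueError("bimodal gene requires a BimodalFit")
        if self.category is GeneCategory.UNIMODAL and not isinstance(self.fit, UnimodalFit):
            raise ValueError("unimodal gene requires a UnimodalFit")


def classify_gene(
    stats: GeneStats,
    median_amplitude: float,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[GeneCategory, str | None]:
    """Fixed-order classification cascade; returns (category, discard reason).

    1. discard on dropout rate / amplitude / support;
    2. bimodal on dip significance AND bimodality index;
    3. zero-inflated on a density peak in the lowest amplitude band;
    4. unimodal otherwise.
    """
    if stats.dropout_rate > config.dropout_discard_threshold:
        return GeneCategory.DISCARDED, (
            f"dropout rate {stats.dropout_rate:.3f} > {config.dropout_discard_threshold}"
        )
    if stats.amplitude < median_amplitude / config.amplitude_divisor:
        return GeneCategory.DISCARDED, (
            f"amplitude {stats.amplitude:.3f} < median amplitude "
            f"{median_amplitude:.3f} / {config.amplitude_divisor:g}"
        )
    if stats.n_nonzero < config.min_nonzero:
        return GeneCategory.DISCARDED, (
            f"only {stats.n_nonzero} non-zero observations (< {config.min_nonzero})"
        )
    if (
        np.isfinite(stats.dip_pvalue)
        and stats.dip_pvalue < config.dip_alpha
        and stats.bimodality_index > config.bi_threshold
    ):
        return GeneCategory.BIMODAL, None
    if stats.density_peak - stats.min_value <= config.zero_peak_fraction * stats.amplitude:
        return GeneCategory.ZERO_INFLATED, None
    return GeneCategory.UNIMODAL, None


def _fit_bimodal(nz: np.ndarray, config: ClassifierConfig) -> BimodalFit:
    """EM fit with bounded retries against variance collapse."""
    last = None
    for attempt in range(5):
        phi1, mu1, s1, phi2, mu2, s2 = fit_gaussian_mixture2(
            nz, seed=config.random_seed + attempt
        )
        last = (phi1, mu1, s1, phi2, mu2, s2)
        if s1 > 1e-8 and s2 > 1e-8 and mu2 > mu1 and phi1 > 0 and phi2 > 0:
            return BimodalFit(phi1, mu1, s1, phi2, mu2, s2)
    raise RuntimeError(
        f"EM failed to produce a non-degenerate 2-component fit after 5 "
        f"initialisations (last parameters: {last})"
    )


def fit_profile(
    values,
    category: GeneCategory,
    config: ClassifierConfig = ClassifierConfig(),
    stats: GeneStats | None = None,
) -> GeneProfile:
    """Fit the parametric model matching a gene's category.

    ZERO_INFLATED genes re-test their non-zero sub-distribution for
    bimodality (same dip/BI criteria as the cascade) and fall back to
    the corresponding sub-case fit.
    """
    x = np.asarray(values, dtype=float)
    if stats is None:
        stats = compute_gene_stats(x, min_nonzero=config.min_nonzero,
                                   seed=config.random_seed)
    nz = x[x > 0]
    dropout = None
    if stats.n_nonzero > 0 and stats.mean_nz > 0:
        dropout = DropoutParams(lambda_=rate_param(stats.mean_nz),
                                tau_ref=stats.dropout_rate)
    if category is GeneCategory.DISCARDED:
        return GeneProfile(category=category, stats=stats, dropout=dropout)
    if stats.n_nonzero < config.min_nonzero:
        raise ValueError(
            f"cannot fit a {category.value} profile with {stats.n_nonzero} "
            f"non-zero observations (min_nonzero={config.min_nonzero})"
        )
    if category is GeneCategory.BIMODAL:
        return GeneProfile(category=category, stats=stats,
                           fit=_fit_bimodal(nz, config), dropout=dropout)
    if category is GeneCategory.ZERO_INFLATED:
        sub_bimodal = (
            np.isfinite(stats.dip_pvalue)
            and stats.dip_pvalue < config.dip_alpha
            and stats.bimodality_index > config.bi_threshold
        )
        if sub_bimodal:
            return GeneProfile(category=category, stats=stats,
                               fit=_fit_bimodal(nz, config),
                               subcategory=GeneCategory.BIMODAL, dropout=dropout)
        return GeneProfile(category=category, stats=stats,
                           fit=UnimodalFit.from_values(nz),
                           subcategory=GeneCategory.UNIMODAL, dropout=dropout)
    if category is GeneCategory.UNIMODAL:
        return GeneProfile(category=category, stats=stats,
                           fit=UnimodalFit.from_values(nz), dropout=dropout)
    raise ValueError(f"unknown category: {category}")
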