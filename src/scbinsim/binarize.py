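"""Category-dependent three-valued binarisation of expression matrices.

* bimodal genes: posterior component membership of the fitted mixture
  against a confidence threshold theta (0.5 < theta <= 1);
* unimodal genes: Tukey-style quantile fences Q(q) - alpha*IQR and
  Q(1-q) + alpha*IQR on the non-zero empirical quantiles;
* zero-inflated genes: non-zero observations are active, zeros take the
  configurable label z (undetermined by default, or 0).

Binarisation is deterministic: no randomness is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import UNDETERMINED, validate_expression
from .model import ReferenceProfiles
from .profiles import BimodalFit, GeneCategory, UnimodalFit

__all__ = [
    "BinarizationConfig",
    "posterior_components",
    "binarize_bimodal",
    "binarize_unimodal",
    "binarize_zero_inflated",
    "binarize_matrix",
    "expected_binarized_fraction",
    "bimodal_determined_mass",
]


@dataclass(frozen=True)
class BinarizationConfig:
    """Thresholds of the three category-specific rules.

    theta: posterior confidence for bimodal calls, 0.5 < theta <= 1.
    q: margin quantile of the unimodal fences (fraction binarised per
       tail when alpha = 0).
    alpha: IQR multiplier widening the fences.
    zero_inflated_zero: label assigned to zeros of zero-inflated genes;
       NaN (undetermined) or 0.
    """

    theta: float = 0.95
    q: float = 0.05
    alpha: float = 0.0
    zero_inflated_zero: float = UNDETERMINED

    def __post_init__(self):
        if not 0.5 < self.theta <= 1.0:
            raise ValueError("theta must satisfy 0.5 < theta <= 1")
        if not 0.0 < self.q < 0.5:
            raise ValueError("q must be in (0, 0.5)")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        z = self.zero_inflated_zero
        if not (np.isnan(z) or z == 0.0):
            raise ValueError("zero_inflated_zero must be 0 or undetermined (NaN)")


def _log_gauss(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma)


def posterior_components(x, fit: BimodalFit):
    """Posterior membership p(C1|x), p(C2|x) of the two mixture components."""
    x = np.asarray(x, dtype=float)
    l1 = np.log(fit.phi1) + _log_gauss(x, fit.mu1, fit.sigma1)
    l2 = np.log(fit.phi2) + _log_gauss(x, fit.mu2, fit.sigma2)
    m = np.maximum(l1, l2)
    w1, w2 = np.exp(l1 - m), np.exp(l2 - m)
    total = w1 + w2
    return w1 / total, w2 / total


def binarize_bimodal(x, fit: BimodalFit, theta: float = 0.95):
    """0 / 1 / undetermined by posterior confidence (exclusive for theta > 0.5)."""
    p1, p2 = posterior_components(x, fit)
    out = np.full(np.shape(p1), UNDETERMINED)
    out = np.where(p1 >= theta, 0.0, out)
    out = np.where(p2 >= theta, 1.0, out)
    return out if out.shape else float(out)


def binarize_unimodal(x, fit: UnimodalFit, q: float = 0.05, alpha: float = 0.0):
    """Quantile-fence rule: 0 below Q(q)-alpha*IQR, 1 above Q(1-q)+alpha*IQR."""
    x = np.asarray(x, dtype=float)
    lo = fit.quantile(q) - alpha * fit.iqr
    hi = fit.quantile(1.0 - q) + alpha * fit.iqr
    out = np.full(x.shape, UNDETERMINED)
    out = np.where(x < lo, 0.0, out)
    out = np.where(x > hi, 1.0, out)
    return out if out.shape else float(out)


def binarize_zero_inflated(x, z: float = UNDETERMINED):
    """Zero-or-not rule: 1 for positive values, label z for zeros."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, 1.0, z)
    return out if out.shape else float(out)


def binarize_matrix(
    matrix: pd.DataFrame,
    profiles: ReferenceProfiles,
    config: BinarizationConfig | None = None,
    keep_discarded: bool = False,
) -> pd.DataFrame:
    """Binarise each gene by its learnt category's rule.

    Genes classified DISCARDED are dropped from the output (or kept as
    all-undetermined columns with ``keep_discarded=True``).  Genes of
    the input absent from the profiles raise a KeyError.
    """
    cfg = config or BinarizationConfig()
    validate_expression(matrix)
    unknown = [g for g in matrix.columns if g not in profiles]
    if unknown:
        raise KeyError(f"genes missing from reference profiles: {unknown[:10]}")
    out = {}
    for gene in matrix.columns:
        prof = profiles[gene]
        x = matrix[gene].to_numpy(dtype=float)
        if prof.category is GeneCategory.DISCARDED:
            if keep_discarded:
                out[gene] = np.full(x.shape, UNDETERMINED)
            continue
        out[gene] = _binarize_gene(x, prof, cfg)
    return pd.DataFrame(out, index=matrix.index)


def _binarize_gene(x, prof, cfg: BinarizationConfig):
    if prof.category is GeneCategory.BIMODAL:
        return binarize_bimodal(x, prof.fit, cfg.theta)
    if prof.category is GeneCategory.ZERO_INFLATED:
        return binarize_zero_inflated(x, cfg.zero_inflated_zero)
    return binarize_unimodal(x, prof.fit, cfg.q, cfg.alpha)


def bimodal_determined_mass(fit: BimodalFit, theta: float = 0.95,
                            n_grid: int = 4001) -> float:
    """Mixture probability mass on which the bimodal rule decides 0 or 1.

    Numeric integration of the mixture density over the region where
    either posterior exceeds theta (the p-star of the expected
    binarised-fraction estimate).
    """
    lo = min(fit.mu1 - 8 * fit.sigma1, fit.mu2 - 8 * fit.sigma2)
    hi = max(fit.mu1 + 8 * fit.sigma1, fit.mu2 + 8 * fit.sigma2)
    grid = np.linspace(lo, hi, n_grid)
    p1, p2 = posterior_components(grid, fit)
    dens = (fit.phi1 / (np.sqrt(2 * np.pi) * fit.sigma1)
            * np.exp(-0.5 * ((grid - fit.mu1) / fit.sigma1) ** 2)
            + fit.phi2 / (np.sqrt(2 * np.pi) * fit.sigma2)
            * np.exp(-0.5 * ((grid - fit.mu2) / fit.sigma2) ** 2))
    decided = (p1 >= theta) | (p2 >= theta)
    return float(np.trapezoid(dens * decided, grid))


def expected_binarized_fraction(
    profiles: ReferenceProfiles,
    config: BinarizationConfig | None = None,
    p_star: float | None = None,
) -> float:
    """Estimate of the overall fraction of observations binarised to 0/1.

    With xi, b, eta the proportions of zero-inflated, bimodal and
    unimodal genes among the kept genes, tau the average reference
    dropout rate of the zero-inflated genes, and p_star the mean decided
    mass of the bimodal fits, the estimate is

        xi * (1 - tau) + b * p_star + eta * 2 q

    (zero-inflated genes decide all observations when zeros are labelled
    0 rather than undetermined, in which case the first term is xi).
    """
    cfg = config or BinarizationConfig()
    kept = [profiles[g] for g in profiles.genes
            if profiles[g].category is not GeneCategory.DISCARDED]
    if not kept:
        raise ValueError("no kept genes")
    n = len(kept)
    zi = [p for p in kept if p.category is GeneCategory.ZERO_INFLATED]
    bi = [p for p in kept if p.category is GeneCategory.BIMODAL]
    uni = [p for p in kept if p.category is GeneCategory.UNIMODAL]
    xi, b, eta = len(zi) / n, len(bi) / n, len(uni) / n
    tau = float(np.mean([p.dropout.tau_ref for p in zi])) if zi else 0.0
    if p_star is None:
        p_star = (float(np.mean([bimodal_determined_mass(p.fit, cfg.theta)
                                 for p in bi])) if bi else 0.0)
    zi_term = xi if cfg.zero_inflated_zero == 0.0 else xi * (1.0 - tau)
    return zi_term + b * p_star + eta * 2.0 * cfg.q
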