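"""Per-gene summary statistics of log-pseudocount distributions.

The moments and shape statistics that drive the classification cascade
are computed on the *non-zero* part of each gene's distribution, so that
dropout zeros do not deflate means or inflate variances; the dropout
rate and the amplitude are computed over all values so the discard rule
stays sensitive to the full dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from ._dip import dip_pvalue

__all__ = [
    "GeneStats",
    "compute_gene_stats",
    "fit_gaussian_mixture2",
    "bimodality_index",
    "matrix_moments",
]


@dataclass(frozen=True)
class GeneStats:
    """Summary statistics of one gene; ``*_nz`` fields use non-zero values.

    Fields that cannot be computed (too few non-zero observations, or a
    degenerate distribution) are NaN.
    """

    n: int
    n_nonzero: int
    dropout_rate: float
    amplitude: float
    min_value: float = 0.0
    mean_nz: float = np.nan
    var_nz: float = np.nan
    median_nz: float = np.nan
    skewness_nz: float = np.nan
    excess_kurtosis_nz: float = np.nan
    dip_pvalue: float = np.nan
    bimodality_index: float = np.nan
    density_peak: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def fit_gaussian_mixture2(values, seed: int = 0, *, n_init: int = 5,
                          tol: float = 1e-6, max_iter: int = 500):
    """Two-component univariate Gaussian mixture by EM.

    Values are sorted before fitting so the result is invariant to the
    ordering of cells; components are relabelled so that mu2 > mu1.
    Returns (phi1, mu1, sigma1, phi2, mu2, sigma2).
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    x = np.sort(np.asarray(values, dtype=float)).reshape(-1, 1)
    with warnings.catch_warnings():
        # provisional shape fits on near-degenerate genes may stop at
        # max_iter; the relabelled point estimates are still usable
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm = GaussianMixture(
            n_components=2, covariance_type="full", n_init=n_init, tol=tol,
            max_iter=max_iter, init_params="kmeans", reg_covar=1e-9,
            random_state=int(seed) % (2**31),
        ).fit(x)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    phi = gm.weights_.ravel()
    order = np.argsort(mu)
    phi, mu, sd = phi[order], mu[order], sd[order]
    return float(phi[0]), float(mu[0]), float(sd[0]), float(phi[1]), float(mu[1]), float(sd[1])


def bimodality_index(values, seed: int = 0) -> float:
    """Bimodality Index delta * sqrt(p (1-p)) from a provisional 2-GMM.

    delta = (mu2 - mu1) / sigma_pooled with the pooled within-component
    standard deviation sqrt(phi1 s1^2 + phi2 s2^2); p is a component
    weight (the index is symmetric in p vs 1-p).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return np.nan
    phi1, mu1, s1, phi2, mu2, s2 = fit_gaussian_mixture2(x, seed=seed)
    pooled = np.sqrt(phi1 * s1**2 + phi2 * s2**2)
    if pooled < 1e-12:
        return np.inf if mu2 - mu1 > 1e-12 else 0.0
    return float((mu2 - mu1) / pooled * np.sqrt(phi1 * phi2))


def _density_peak(values) -> float:
    """Location of the highest Gaussian-KDE peak (Silverman bandwidth)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return float(x[0]) if x.size else np.nan
    kde = sps.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def compute_gene_stats(values, *, min_nonzero: int = 10, seed: int = 0) -> GeneStats:
    """Summary statistics of one gene's log pseudocounts.

    Dropout rate and amplitude are over all values; the distributional
    statistics (moments, dip test, bimodality index) are over the
    strictly positive values only.  Statistics needing at least
    ``min_nonzero`` positive observations are NaN below that support.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty value vector")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("log pseudocounts must be finite and non-negative")
    nz = x[x > 0]
    n, n_nz = x.size, nz.size
    out = dict(
        n=n, n_nonzero=int(n_nz),
        dropout_rate=float(np.mean(x == 0)),
        amplitude=float(np.ptp(x)) if n else 0.0,
        min_value=float(np.min(x)),
        density_peak=_density_peak(x),
    )
    if n_nz >= 2:
        out.update(
            mean_nz=float(np.mean(nz)),
            var_nz=float(np.var(nz, ddof=1)),
            median_nz=float(np.median(nz)),
        )
        if np.ptp(nz) > 0:
            out.update(
                skewness_nz=float(sps.skew(nz)),
                excess_kurtosis_nz=float(sps.kurtosis(nz)),
            )
        else:
            out.update(skewness_nz=np.nan, excess_kurtosis_nz=np.nan)
    elif n_nz == 1:
        out.update(mean_nz=float(nz[0]), var_nz=0.0, median_nz=float(nz[0]))
    if n_nz >= max(4, min_nonzero):
        out.update(
            dip_pvalue=dip_pvalue(nz),
            bimodality_index=bimodality_index(nz, seed=seed),
        )
    return GeneStats(**out)


def matrix_moments(matrix) -> "pd.DataFrame":
    """Full-data per-gene moments and dropout rate of a matrix.

    Population formulae (variance with ddof=0, Fisher skewness and
    excess kurtosis), so Boolean 0/1 columns evaluate to their Bernoulli
    closed forms.  Degenerate columns (zero variance) get NaN shape
    moments.
    """
    import warnings

    import pandas as pd

    matrix = pd.DataFrame(matrix)
    values = matrix.to_numpy(dtype=float)
    out = pd.DataFrame(index=matrix.columns)
    out["mean"] = values.mean(axis=0)
    out["variance"] = values.var(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns
        out["skewness"] = sps.skew(values, axis=0)
        out["excess_kurtosis"] = sps.kurtosis(values, axis=0)
    degenerate = out["variance"].to_numpy() <= 0
    out.loc[degenerate, ["skewness", "excess_kurtosis"]] = np.nan
    out["dropout_rate"] = (values == 0).mean(axis=0)
    return out
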