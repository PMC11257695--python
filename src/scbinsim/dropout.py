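"""Gene-wise probabilistic dropout model.

The probability of observing a zero for gene g given its prior log
pseudocount x is an exponential decay

    P(x_obs = 0 | x) = beta_g * exp(-lambda_g * x),

clipped to 1.  The rate lambda_g is set by matching the half-life of the
decay to the gene's non-zero mean (lambda = ln 2 / mean_nz), so a cell
expressing the gene at its typical level is dropped with probability
beta/2.  The normalisation beta_g is chosen per generated batch so that
the expected dropout rate of the batch (the mean of a Poisson-binomial
distribution: independent Bernoulli trials with unequal probabilities)
equals the target rate, by default the gene's reference dropout rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DropoutParams",
    "rate_param",
    "norm_constant",
    "dropout_probability",
    "expected_dropout_rate",
    "simulate_dropout",
]


@dataclass(frozen=True)
class DropoutParams:
    """Parameters (lambda_g, beta_g, tau_g^ref) of the dropout decay.

    beta is ephemeral (recomputed per generated batch from the sampled
    prior pseudocounts) and may be NaN in stored profiles.
    """

    lambda_: float
    tau_ref: float
    beta: float = np.nan

    def __post_init__(self):
        if not np.isnan(self.tau_ref) and not 0.0 <= self.tau_ref <= 1.0:
            raise ValueError(f"tau_ref must be in [0, 1], got {self.tau_ref}")
        if not np.isnan(self.beta) and self.beta < 0:
            raise ValueError("beta must be non-negative")


def rate_param(mean_nz: float) -> float:
    """Decay rate lambda = ln(2) / mean_nz (half-life at the non-zero mean)."""
    if not mean_nz > 0:
        raise ValueError(f"mean_nz must be positive, got {mean_nz}")
    return float(np.log(2.0) / mean_nz)


def norm_constant(x_sample, lambda_: float, tau_ref: float) -> float:
    """Normalisation beta = n tau_ref / sum_c exp(-lambda x_c).

    Minimises the quadratic deviation between the expected Poisson-
    binomial dropout rate of the sample and the target tau_ref; when no
    clipped probability exceeds 1, the expectation matches exactly.
    """
    x = np.asarray(x_sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty prior sample")
    if not 0.0 <= tau_ref <= 1.0:
        raise ValueError(f"tau_ref must be in [0, 1], got {tau_ref}")
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    return float(x.size * tau_ref / np.sum(np.exp(-lambda_ * x)))


def dropout_probability(x, params: DropoutParams):
    """Pointwise dropout probability min(1, beta e^{-lambda x})."""
    p = params.beta * np.exp(-params.lambda_ * np.asarray(x, dtype=float))
    return np.minimum(p, 1.0)


def expected_dropout_rate(x_sample, params: DropoutParams) -> float:
    """Mean of the Poisson-binomial dropout count / n, with clipping."""
    return float(np.mean(dropout_probability(x_sample, params)))


def poisson_binomial_sd(x_sample, params: DropoutParams) -> float:
    """Standard deviation of the realised dropout *rate*: sqrt(sum p(1-p))/n."""
    p = dropout_probability(x_sample, params)
    return float(np.sqrt(np.sum(p * (1.0 - p))) / p.size)


def simulate_dropout(
    matrix: pd.DataFrame,
    params: dict[str, DropoutParams],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Independently zero entries with their pointwise dropout probability.

    Entries are never increased; existing zeros get p = min(1, beta) and
    remain zero regardless of the draw.  Each gene consumes its own
    random substream derived from ``rng`` keyed by gene id, so the
    result does not depend on column order.
    """
    missing = [g for g in matrix.columns if g not in params]
    if missing:
        raise KeyError(f"missing dropout parameters for genes: {missing[:5]}")
    out = matrix.copy()
    base = rng.integers(0, 2**31 - 1)
    for gene in matrix.columns:
        x = matrix[gene].to_numpy(dtype=float)
        p = dropout_probability(x, params[gene])
        sub = np.random.default_rng([int(base), _gene_key(gene)])
        dropped = sub.random(x.size) < p
        out[gene] = np.where(dropped, 0.0, x)
    return out


def _gene_key(gene_id: str) -> int:
    """Stable non-negative integer key for a gene id (order-free streams)."""
    import zlib

    return zlib.crc32(str(gene_id).encode("utf8"))
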