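"""Synthetic log-pseudocount generation biased by Boolean activation states.

For each Boolean sample (one row of a state matrix) and each mapped
gene, pseudocounts are drawn from the part of the gene's learnt
distribution matching the activation state:

* unimodal fit (mu, sigma): active cells draw mu + |N(0, sigma^2)|,
  inactive cells mu - |N(0, sigma^2)| (half-normal on either side);
* bimodal fit: the component matching the state (N(mu1, sigma1^2) for
  inactive, N(mu2, sigma2^2) for active);
* zero-inflated genes use their non-zero sub-fit's rule.

Draws are clipped at zero, then dropout is simulated with the gene's
exponential-decay model: lambda is the learnt rate and beta is solved
on the generated batch so the expected Poisson-binomial dropout rate
hits the target (the reference rate, a user-supplied rate, or skipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dropout import DropoutParams, norm_constant, dropout_probability
from .matrix import validate_boolean_states
from .model import ReferenceProfiles
from .profiles import BimodalFit, GeneCategory, UnimodalFit

__all__ = [
    "GenerationConfig",
    "sample_unimodal",
    "sample_bimodal",
    "clip_nonnegative",
    "generate_from_boolean",
]


@dataclass(frozen=True)
class GenerationConfig:
    """How many cells per Boolean state, and how dropout is simulated.

    dropout_mode: "learned" targets each gene's reference dropout rate;
    "user_rates" targets caller-supplied per-gene rates (keeping the
    gene-specific decay shape); "none" skips dropout simulation.
    """

    n_samples_per_state: int = 1
    dropout_mode: str = "learned"
    user_rates: dict[str, float] | None = None
    random_seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_state < 1:
            raise ValueError("n_samples_per_state must be >= 1")
        if self.dropout_mode not in ("learned", "none", "user_rates"):
            raise ValueError(f"unknown dropout_mode: {self.dropout_mode!r}")
        if (self.dropout_mode == "user_rates") != (self.user_rates is not None):
            raise ValueError("user_rates must be given exactly when dropout_mode='user_rates'")
        if self.user_rates is not None:
            bad = {g: r for g, r in self.user_rates.items() if not 0.0 <= r <= 1.0}
            if bad:
                raise ValueError(f"user dropout rates outside [0, 1]: {bad}")


def sample_unimodal(state: int, fit: UnimodalFit, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Half-normal draws above (active) or below (inactive) the mean."""
    half = np.abs(rng.normal(0.0, fit.sigma, size=n)) if fit.sigma > 0 else np.zeros(n)
    return fit.mu + half if state else fit.mu - half


def sample_bimodal(state: int, fit: BimodalFit, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draws from the mixture component matching the activation state."""
    mu, sigma = (fit.mu2, fit.sigma2) if state else (fit.mu1, fit.sigma1)
    return rng.normal(mu, sigma, size=n)


def clip_nonnegative(values) -> np.ndarray:
    """Correct negative draws to 0 (log pseudocounts are non-negative)."""
    return np.maximum(np.asarray(values, dtype=float), 0.0)


def _sample_gene(states: np.ndarray, prof, n_per: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Prior (pre-dropout) draws for one gene across all Boolean samples."""
    fit = prof.fit
    total = states.size * n_per
    rep = np.repeat(states, n_per)
    if isinstance(fit, BimodalFit):
        draws = np.where(
            rep == 1,
            rng.normal(fit.mu2, fit.sigma2, size=total),
            rng.normal(fit.mu1, fit.sigma1, size=total),
        )
    else:
        half = np.abs(rng.normal(0.0, fit.sigma, size=total)) if fit.sigma > 0 else np.zeros(total)
        draws = np.where(rep == 1, fit.mu + half, fit.mu - half)
    return clip_nonnegative(draws)


def generate_from_boolean(
    states: pd.DataFrame,
    profiles: ReferenceProfiles,
    mapping: dict[str, str] | None = None,
    config: GenerationConfig | None = None,
) -> pd.DataFrame:
    """Generate a synthetic expression matrix from Boolean states.

    ``states`` has Boolean samples as rows and nodes as columns;
    ``mapping`` maps node ids to distinct non-discarded reference genes
    (identity when omitted and node ids are gene ids).  Each Boolean
    sample yields ``n_samples_per_state`` synthetic cells, indexed
    "<sample_id>::<replicate>"; columns are named by node id.

    Per-gene random substreams are derived from the seed and the node
    id, so results do not depend on column order.
    """
    cfg = config or GenerationConfig()
    states = validate_boolean_states(pd.DataFrame(states))
    if mapping is None:
        mapping = {node: node for node in states.columns}
    missing_nodes = [n for n in states.columns if n not in mapping]
    if missing_nodes:
        raise KeyError(f"nodes without a gene mapping: {missing_nodes[:10]}")
    genes = list(mapping.values())
    if len(set(genes)) != len(genes):
        raise ValueError("node->gene mapping must be injective")
    for node, gene in mapping.items():
        if gene not in profiles:
            raise KeyError(f"mapped gene {gene!r} (node {node!r}) not in profiles")
        if profiles[gene].category is GeneCategory.DISCARDED:
            raise ValueError(f"node {node!r} mapped to discarded gene {gene!r}")
    if cfg.dropout_mode == "user_rates":
        missing = [mapping[n] for n in states.columns
                   if mapping[n] not in cfg.user_rates and n not in cfg.user_rates]
        if missing:
            raise KeyError(f"user_rates missing for genes: {missing[:10]}")

    n_per = cfg.n_samples_per_state
    index = [f"{sid}::{k}" for sid in states.index for k in range(n_per)]
    out = {}
    import zlib

    for node in states.columns:
        gene = mapping[node]
        prof = profiles[gene]
        sub = np.random.default_rng(
            [int(cfg.random_seed) % 2**31, zlib.crc32(str(node).encode("utf8"))]
        )
        x = _sample_gene(states[node].to_numpy(dtype=int), prof, n_per, sub)
        if cfg.dropout_mode != "none":
            if cfg.dropout_mode == "learned":
                target = prof.dropout.tau_ref if prof.dropout is not None else 0.0
            else:
                target = cfg.user_rates.get(gene, cfg.user_rates.get(node))
            if target > 0 and prof.dropout is not None:
                beta = norm_constant(x, prof.dropout.lambda_, target)
                params = DropoutParams(lambda_=prof.dropout.lambda_,
                                       tau_ref=target, beta=beta)
                p = dropout_probability(x, params)
                x = np.where(sub.random(x.size) < p, 0.0, x)
        out[node] = x
    return pd.DataFrame(out, index=index)
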