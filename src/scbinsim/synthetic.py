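"""Synthetic reference matrices with known ground truth, and validation stats.

The generator draws each gene from a declared parametric distribution
(normal, two-component mixture, or a low-mean normal for zero-inflated
genes; a shifted log-normal variant exercises the nonparametric
unimodal path), clips at zero, then applies the exponential-decay
dropout model targeting a declared rate — i.e. exactly the data the
learning side assumes, so recovery tests isolate implementation errors
from model misspecification.  The validation helpers reproduce the
mean-variance / mean-dropout comparisons and cross-moment correlation
tables used to judge statistical realism of generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dropout import norm_constant, rate_param
from .sampling import clip_nonnegative
from .stats import matrix_moments

__all__ = [
    "GeneSpec",
    "FixtureSpec",
    "generate_reference_fixture",
    "default_fixture_spec",
    "calibration_fixture_spec",
    "lognormal_fixture_spec",
    "summarize",
    "compare_summaries",
    "boolean_states_from_binary",
]


@dataclass(frozen=True)
class GeneSpec:
    """Declared distribution of one fixture gene.

    category: ground-truth label (unimodal / bimodal / zero_inflated).
    params: mu, sigma for normal kinds; phi1, mu1, sigma1, mu2, sigma2
        for mixtures; mu (shift), s (log-sd), scale for log-normal.
    tau: target dropout rate of the simulated dropout step, in [0, 1).
    dist: "normal", "mixture" or "lognormal".
    """

    name: str
    category: str
    params: dict
    tau: float = 0.0
    dist: str = "normal"

    def __post_init__(self):
        if self.category not in ("unimodal", "bimodal", "zero_inflated"):
            raise ValueError(f"unknown category {self.category!r}")
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must be in [0, 1)")
        if self.dist not in ("normal", "mixture", "lognormal"):
            raise ValueError(f"unknown dist {self.dist!r}")


@dataclass(frozen=True)
class FixtureSpec:
    genes: tuple
    n_cells: int = 2000
    random_seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in fixture spec")


def _draw_prior(gene: GeneSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = gene.params
    if gene.dist == "mixture":
        comp = rng.random(n) < p["phi1"]
        return np.where(comp, rng.normal(p["mu1"], p["sigma1"], n),
                        rng.normal(p["mu2"], p["sigma2"], n))
    if gene.dist == "lognormal":
        return p["mu"] + p.get("scale", 1.0) * rng.lognormal(0.0, p["s"], n)
    return rng.normal(p["mu"], p["sigma"], n)


def generate_reference_fixture(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample a reference matrix and return it with ground-truth labels.

    Per gene: draw from the declared distribution, clip negatives to 0,
    then simulate dropout with lambda = ln2 / mean of positive draws and
    beta solved to target the declared rate on this sample.
    """
    rng = np.random.default_rng(spec.random_seed)
    import zlib

    columns = {}
    for gene in spec.genes:
        sub = np.random.default_rng(
            [spec.random_seed % 2**31, zlib.crc32(gene.name.encode("utf8"))]
        )
        x = clip_nonnegative(_draw_prior(gene, spec.n_cells, sub))
        if gene.tau > 0:
            pos = x[x > 0]
            if pos.size:
                lam = rate_param(float(pos.mean()))
                beta = norm_constant(x, lam, gene.tau)
                pdrop = np.minimum(beta * np.exp(-lam * x), 1.0)
                x = np.where(sub.random(x.size) < pdrop, 0.0, x)
        columns[gene.name] = x
    matrix = pd.DataFrame(columns,
                          index=[f"cell{i}" for i in range(spec.n_cells)])
    labels = pd.Series({g.name: g.category for g in spec.genes}, name="category")
    return matrix, labels


def default_fixture_spec(n_cells: int = 2000, seed: int = 0) -> FixtureSpec:
    """30 well-separated genes, 10 per category.

    Unimodal genes are tight high-expression normals without dropout
    (their binarised fraction then follows the 2q law exactly); bimodal
    genes have clearly separated components and moderate dropout;
    zero-inflated genes are low-mean normals with heavy dropout.
    """
    genes = []
    for i in range(10):
        genes.append(GeneSpec(
            name=f"uni{i}", category="unimodal",
            params={"mu": 4.0 + 0.3 * i, "sigma": 0.5 + 0.05 * i}, tau=0.0))
    for i in range(10):
        genes.append(GeneSpec(
            name=f"bim{i}", category="bimodal", dist="mixture",
            params={"phi1": 0.35 + 0.03 * i, "mu1": 1.2 + 0.08 * i, "sigma1": 0.45,
                    "mu2": 5.0 + 0.2 * i, "sigma2": 0.55},
            tau=0.10 + 0.02 * i))
    for i in range(10):
        genes.append(GeneSpec(
            name=f"zi{i}", category="zero_inflated",
            params={"mu": 1.2 + 0.06 * i, "sigma": 0.4},
            tau=0.55 + 0.02 * i))
    return FixtureSpec(genes=tuple(genes), n_cells=n_cells, random_seed=seed)


def calibration_fixture_spec(n_cells: int = 1000, seed: int = 0,
                             taus=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)) -> FixtureSpec:
    """Tight normal genes spanning dropout targets 0.1..0.8.

    The narrow spread (sigma = 0.15 around mu = 2) keeps every pointwise
    dropout probability below 1 even at the 0.8 target (this needs
    roughly 3.3 sigma < ln(1/tau)/lambda ~ 0.64), so the Poisson-
    binomial expectation matches the target exactly.
    """
    genes = tuple(
        GeneSpec(name=f"cal{int(round(t * 100)):02d}", category="unimodal",
                 params={"mu": 2.0, "sigma": 0.15}, tau=float(t))
        for t in taus
    )
    return FixtureSpec(genes=genes, n_cells=n_cells, random_seed=seed)


def lognormal_fixture_spec(n_cells: int = 2000, seed: int = 0) -> FixtureSpec:
    """Misspecified unimodal genes with log-normal tails.

    Exercises the nonparametric quantile binarisation path: skewness
    does not hinder the fence rule, which makes no parametric
    assumption.
    """
    genes = tuple(
        GeneSpec(name=f"lgn{i}", category="unimodal", dist="lognormal",
                 params={"mu": 3.0 + 0.3 * i, "s": 0.5, "scale": 1.0}, tau=0.0)
        for i in range(6)
    )
    return FixtureSpec(genes=genes, n_cells=n_cells, random_seed=seed)


def summarize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene full-data mean, variance, skewness, kurtosis, dropout rate."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty matrix")
    return matrix_moments(matrix)


_STATS = ["mean", "variance", "skewness", "excess_kurtosis", "dropout_rate"]


def compare_summaries(ref: pd.DataFrame, synth: pd.DataFrame) -> dict:
    """Correlation diagnostics between reference and synthetic summaries.

    Returns per-statistic Pearson/Spearman correlations across genes,
    the cross-statistic correlation matrix within each summary, and the
    sign-agreement score between the two cross matrices.  Constant
    statistics yield correlation 0 (no association measurable).
    """
    if set(ref.index) != set(synth.index):
        raise ValueError("summaries cover different gene sets")
    synth = synth.loc[ref.index]
    per_stat = {}
    for stat in _STATS:
        a, b = ref[stat].to_numpy(), synth[stat].to_numpy()
        per_stat[stat] = {
            "pearson": _safe_corr(a, b, sps.pearsonr),
            "spearman": _safe_corr(a, b, sps.spearmanr),
        }
    per_stat = pd.DataFrame(per_stat).T
    ref_cross = _cross_corr(ref)
    synth_cross = _cross_corr(synth)
    mask = ~(np.eye(len(_STATS), dtype=bool))
    agree = float(np.mean(
        np.sign(ref_cross.to_numpy()[mask]) == np.sign(synth_cross.to_numpy()[mask])
    ))
    return {"per_statistic": per_stat, "ref_cross": ref_cross,
            "synth_cross": synth_cross, "cross_sign_agreement": agree}


def _safe_corr(a, b, fn) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(fn(a, b)[0])


def _cross_corr(summary: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=_STATS, columns=_STATS, dtype=float)
    for s1 in _STATS:
        for s2 in _STATS:
            out.loc[s1, s2] = _safe_corr(summary[s1].to_numpy(),
                                         summary[s2].to_numpy(), sps.spearmanr)
    return out


def boolean_states_from_binary(
    binary: pd.DataFrame,
    expression: pd.DataFrame,
    profiles,
) -> pd.DataFrame:
    """Resolve undetermined entries of a binarised matrix into strict 0/1.

    Undetermined calls are filled by comparing the expression value to
    the gene's non-zero median (above -> active).  This is a pragmatic
    closure for feeding a dataset's own binarisation back into the
    generator; it is not part of the binarisation contract.
    """
    out = binary.copy()
    for gene in binary.columns:
        med = profiles[gene].stats.median_nz
        fill = (expression.loc[binary.index, gene] > med).astype(float)
        mask = binary[gene].isna()
        out.loc[mask, gene] = fill[mask]
    return out.astype(int)
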