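"""Matching Boolean nodes to reference genes via scaled moment profiles.

Boolean nodes of an artificial model do not correspond to genes of the
reference dataset, so each node is first classified as unimodal,
bimodal or zero-inflated from the shape of its Boolean value
distribution, then assigned a distinct gene of that category.

The features are the first four moments (mean, variance, skewness,
excess kurtosis).  Node moments are computed from the 0/1 values
directly; a reference gene is embedded as the Bernoulli moments of its
*learnt activity fraction* — the weight of the active mixture component
for bimodal genes, the non-zero fraction (1 - tau_ref) otherwise — so
genes and Boolean nodes live on the same Bernoulli moment curve:
a mostly-active node sits next to the always-on unimodal genes, a
balanced node next to bimodal genes with even component weights, and a
rarely-active node next to heavily dropped-out zero-inflated genes.
Both tables are put on a common footing by per-moment min-max scaling
fitted on the reference; a k-nearest-neighbours classifier trained on
the scaled reference moments labels each node, and within each category
nodes take distinct genes greedily by ascending nearest-gene distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler

from .model import ReferenceProfiles
from .profiles import GeneCategory

__all__ = [
    "MOMENT_COLUMNS",
    "scaled_moments",
    "bernoulli_moments",
    "boolean_activity_moments",
    "reference_activity_moments",
    "classify_nodes",
    "match_genes",
    "map_nodes_to_genes",
]

MOMENT_COLUMNS = ["mean", "variance", "skewness", "excess_kurtosis"]

#: Activity fractions are clamped to this range before computing shape
#: moments: the Bernoulli skewness/kurtosis diverge as p -> 0 or 1, and
#: unbounded tails would dominate the min-max scaled distances.
P_CLAMP = (0.02, 0.98)


def bernoulli_moments(p: float, clamp: tuple = P_CLAMP) -> dict:
    """Population moments of a Bernoulli(p) variable, p clamped away from 0/1."""
    p = float(np.clip(p, *clamp))
    q = 1.0 - p
    var = p * q
    return {
        "mean": p,
        "variance": var,
        "skewness": (q - p) / np.sqrt(var),
        "excess_kurtosis": (1.0 - 6.0 * var) / var,
    }


def boolean_activity_moments(states: pd.DataFrame) -> pd.DataFrame:
    """Bernoulli moment embedding of Boolean node columns.

    Uses the closed forms at each node's activity fraction, which equal
    the sample moments of a 0/1 column away from the clamp boundaries.
    """
    rows = {node: bernoulli_moments(float(states[node].astype(float).mean()))
            for node in states.columns}
    return pd.DataFrame.from_dict(rows, orient="index")[MOMENT_COLUMNS]


def reference_activity_moments(profiles: ReferenceProfiles) -> tuple[pd.DataFrame, pd.Series]:
    """Bernoulli moment embedding and category labels of the kept genes.

    The activity fraction is phi2 for bimodal genes and the non-zero
    fraction 1 - tau_ref for unimodal and zero-inflated genes.
    """
    rows, labels = {}, {}
    for gene in profiles.genes:
        prof = profiles[gene]
        if prof.category is GeneCategory.DISCARDED:
            continue
        if prof.category is GeneCategory.BIMODAL:
            p = prof.fit.phi2
        else:
            p = 1.0 - prof.stats.dropout_rate
        rows[gene] = bernoulli_moments(float(p))
        labels[gene] = prof.category.value
    return (pd.DataFrame.from_dict(rows, orient="index")[MOMENT_COLUMNS],
            pd.Series(labels, name="category"))


def _impute_degenerate(moments: pd.DataFrame) -> pd.DataFrame:
    """Zero-variance vectors have undefined shape moments; impute 0."""
    out = moments[MOMENT_COLUMNS].copy()
    return out.fillna(0.0)


def fit_moment_scaler(reference_moments: pd.DataFrame) -> MinMaxScaler:
    """Min-max scaler per moment, fitted on the reference gene moments."""
    scaler = MinMaxScaler()
    scaler.fit(_impute_degenerate(reference_moments).to_numpy())
    return scaler


def scaled_moments(moments: pd.DataFrame, scaler: MinMaxScaler) -> pd.DataFrame:
    """Apply the reference-fitted min-max scaling to a moment table."""
    vals = scaler.transform(_impute_degenerate(moments).to_numpy())
    return pd.DataFrame(vals, index=moments.index, columns=MOMENT_COLUMNS)


def classify_nodes(
    node_moments: pd.DataFrame,
    reference_moments: pd.DataFrame,
    reference_labels: pd.Series,
    k: int = 5,
) -> pd.Series:
    """k-NN category per node in scaled-moment space (Euclidean).

    reference_labels holds the learnt categories (unimodal / bimodal /
    zero-inflated) of the reference genes, aligned to
    ``reference_moments``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(reference_moments):
        raise ValueError(f"k={k} exceeds the {len(reference_moments)} reference genes")
    scaler = fit_moment_scaler(reference_moments)
    ref = scaled_moments(reference_moments, scaler)
    query = scaled_moments(node_moments, scaler)
    knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    knn.fit(ref.to_numpy(), reference_labels.loc[ref.index].to_numpy())
    return pd.Series(knn.predict(query.to_numpy()), index=query.index, name="category")


def match_genes(
    node_moments: pd.DataFrame,
    node_categories: pd.Series,
    reference_moments: pd.DataFrame,
    reference_labels: pd.Series,
) -> dict[str, str]:
    """Injective node -> gene assignment within matching categories.

    Greedy nearest-first: among all remaining (node, gene) pairs of a
    category, repeatedly assign the pair at the smallest scaled-moment
    Euclidean distance (ties broken lexicographically by node id then
    gene id).  Raises when a category has more nodes than genes.
    """
    scaler = fit_moment_scaler(reference_moments)
    ref = scaled_moments(reference_moments, scaler)
    query = scaled_moments(node_moments, scaler)
    mapping: dict[str, str] = {}
    for category in sorted(node_categories.unique()):
        nodes = sorted(node_categories.index[node_categories == category])
        genes = sorted(reference_labels.index[reference_labels == category])
        if len(nodes) > len(genes):
            raise ValueError(
                f"category {category!r}: {len(nodes)} nodes but only "
                f"{len(genes)} reference genes available"
            )
        pairs = []
        for node in nodes:
            dv = ref.loc[genes].to_numpy() - query.loc[node].to_numpy()
            dist = np.sqrt((dv**2).sum(axis=1))
            pairs.extend((float(d), node, gene) for d, gene in zip(dist, genes))
        pairs.sort(key=lambda t: (t[0], t[1], t[2]))
        used_nodes: set[str] = set()
        used_genes: set[str] = set()
        for dist, node, gene in pairs:
            if node in used_nodes or gene in used_genes:
                continue
            mapping[node] = gene
            used_nodes.add(node)
            used_genes.add(gene)
    return mapping


def map_nodes_to_genes(
    states: pd.DataFrame,
    profiles: ReferenceProfiles,
    k: int = 5,
) -> dict[str, str]:
    """Full pipeline: Boolean states + learnt profiles -> node->gene map.

    Classifies each node by k-NN against the reference activity-moment
    embedding (non-discarded genes only), then assigns genes greedily
    within categories.
    """
    ref_moments, labels = reference_activity_moments(profiles)
    node_moments = boolean_activity_moments(states)
    cats = classify_nodes(node_moments, ref_moments, labels,
                          k=min(k, len(ref_moments)))
    return match_genes(node_moments, cats, ref_moments, labels)
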