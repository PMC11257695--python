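"""Model/results objects tying profile learning, binarisation and simulation.

`PseudocountModel` wraps a reference log-pseudocount matrix (cells x
genes, assumed pre-filtered to highly variable genes) together with a
`ClassifierConfig`; `fit()` learns one `GeneProfile` per gene and
returns a `ReferenceProfiles` results object, from which expression
matrices can be binarised (`binarize`) and synthetic matrices generated
from Boolean states (`simulate`).

Example
-------
>>> model = PseudocountModel(reference_df)
>>> profiles = model.fit()
>>> binary = profiles.binarize(reference_df)
>>> synthetic = profiles.simulate(boolean_states, n_samples_per_state=50, seed=7)
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .dropout import DropoutParams
from .matrix import validate_expression
from .profiles import (
    BimodalFit,
    ClassifierConfig,
    GeneCategory,
    GeneProfile,
    UnimodalFit,
    classify_gene,
    fit_profile,
)
from .stats import GeneStats, compute_gene_stats

__all__ = ["PseudocountModel", "ReferenceProfiles"]


class PseudocountModel:
    """Per-gene distribution model of a reference scRNA-seq matrix.

    Parameters
    ----------
    data : DataFrame
        Log pseudocounts, cells as rows and genes as columns.  The
        caller is expected to have restricted the matrix to highly
        variable genes (plus any markers of interest); this is a
        documented contract, not enforced.
    config : ClassifierConfig, optional
        Thresholds of the classification cascade.
    """

    def __init__(self, data: pd.DataFrame, config: ClassifierConfig | None = None):
        self.data = validate_expression(pd.DataFrame(data))
        self.config = config or ClassifierConfig()

    @classmethod
    def from_csv(cls, path, delimiter: str = ",", orientation: str = "cells_by_genes",
                 config: ClassifierConfig | None = None) -> "PseudocountModel":
        from .matrix import read_expression

        return cls(read_expression(path, delimiter, orientation), config=config)

    def fit(self) -> "ReferenceProfiles":
        """Learn statistics, category, parametric fit and dropout params per gene."""
        cfg = self.config
        stats: dict[str, GeneStats] = {}
        for gene in self.data.columns:
            stats[gene] = compute_gene_stats(
                self.data[gene].to_numpy(dtype=float),
                min_nonzero=cfg.min_nonzero, seed=cfg.random_seed,
            )
        median_amplitude = float(np.median([s.amplitude for s in stats.values()]))
        profiles: dict[str, GeneProfile] = {}
        for gene in self.data.columns:
            category, reason = classify_gene(stats[gene], median_amplitude, cfg)
            try:
                profile = fit_profile(
                    self.data[gene].to_numpy(dtype=float), category, cfg,
                    stats=stats[gene],
                )
            except Exception as exc:
                raise RuntimeError(f"profile fit failed for gene {gene!r}: {exc}") from exc
            if reason is not None:
                profile = dataclasses.replace(profile, discard_reason=reason)
            profiles[gene] = profile
        return ReferenceProfiles(
            profiles=profiles, config=cfg, n_cells=int(self.data.shape[0]),
            median_amplitude=median_amplitude,
        )


class ReferenceProfiles:
    """Fitted per-gene profiles of a reference dataset (results object)."""

    def __init__(self, profiles: dict[str, GeneProfile], config: ClassifierConfig,
                 n_cells: int, median_amplitude: float = np.nan):
        self.profiles = profiles
        self.config = config
        self.n_cells = n_cells
        self.median_amplitude = median_amplitude

    # -- access ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.profiles)

    def __getitem__(self, gene: str) -> GeneProfile:
        return self.profiles[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.profiles

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def categories(self) -> pd.Series:
        return pd.Series({g: p.category.value for g, p in self.profiles.items()},
                         name="category")

    def genes_of(self, category: GeneCategory) -> list[str]:
        return [g for g, p in self.profiles.items() if p.category is category]

    # -- presentation ---------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        """One row per gene: category, fitted parameters, dropout params."""
        rows = {}
        for gene, p in self.profiles.items():
            row = {"category": p.category.value,
                   "subcategory": p.subcategory.value if p.subcategory else None,
                   **p.stats.to_dict()}
            if isinstance(p.fit, BimodalFit):
                row.update(phi1=p.fit.phi1, mu1=p.fit.mu1, sigma1=p.fit.sigma1,
                           phi2=p.fit.phi2, mu2=p.fit.mu2, sigma2=p.fit.sigma2)
            elif isinstance(p.fit, UnimodalFit):
                row.update(mu=p.fit.mu, sigma=p.fit.sigma, iqr=p.fit.iqr)
            if p.dropout is not None:
                row.update(lambda_=p.dropout.lambda_, tau_ref=p.dropout.tau_ref)
            row["discard_reason"] = p.discard_reason
            rows[gene] = row
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")

    def summary(self) -> str:
        counts = self.categories.value_counts()
        lines = [
            "Reference pseudocount profiles",
            "==============================",
            f"cells: {self.n_cells}    genes: {len(self)}",
            f"median amplitude: {self.median_amplitude:.4g}",
            "category counts:",
        ]
        for cat in GeneCategory:
            lines.append(f"  {cat.value:>13}: {int(counts.get(cat.value, 0))}")
        kept = [g for g, p in self.profiles.items()
                if p.category is not GeneCategory.DISCARDED]
        taus = [self.profiles[g].dropout.tau_ref for g in kept
                if self.profiles[g].dropout is not None]
        if taus:
            lines.append(f"mean reference dropout rate (kept genes): {np.mean(taus):.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<ReferenceProfiles: {len(self)} genes, {self.n_cells} cells, "
                f"{(self.categories != 'discarded').sum()} kept>")

    # -- downstream operations ------------------------------------------
    def binarize(self, data: pd.DataFrame, config=None, keep_discarded: bool = False):
        """Three-valued binarisation of an expression matrix (see binarize module)."""
        from .binarize import binarize_matrix

        return binarize_matrix(data, self, config=config, keep_discarded=keep_discarded)

    def simulate(self, states: pd.DataFrame, mapping: dict[str, str] | None = None,
                 n_samples_per_state: int = 1, dropout_mode: str = "learned",
                 user_rates: dict[str, float] | None = None, seed: int = 0):
        """Synthetic expression from Boolean states (see sampling module)."""
        from .sampling import GenerationConfig, generate_from_boolean

        cfg = GenerationConfig(n_samples_per_state=n_samples_per_state,
                               dropout_mode=dropout_mode, user_rates=user_rates,
                               random_seed=seed)
        return generate_from_boolean(states, self, mapping=mapping, config=cfg)

    # -- serialisation --------------------------------------------------
    def to_json(self, path=None) -> str | None:
        records = {}
        for gene, p in self.profiles.items():
            rec = {
                "category": p.category.value,
                "subcategory": p.subcategory.value if p.subcategory else None,
                "stats": _jsonable(p.stats.to_dict()),
                "discard_reason": p.discard_reason,
            }
            if p.dropout is not None:
                rec["dropout"] = {"lambda": p.dropout.lambda_,
                                  "tau_ref": p.dropout.tau_ref}
            if isinstance(p.fit, BimodalFit):
                rec["fit"] = {"type": "bimodal",
                              **{k: getattr(p.fit, k) for k in
                                 ("phi1", "mu1", "sigma1", "phi2", "mu2", "sigma2")}}
            elif isinstance(p.fit, UnimodalFit):
                rec["fit"] = {"type": "unimodal", "mu": p.fit.mu, "sigma": p.fit.sigma,
                              "quantile_probs": list(p.fit.quantile_probs),
                              "quantile_values": list(p.fit.quantile_values)}
            records[gene] = rec
        payload = {
            "config": dataclasses.asdict(self.config),
            "n_cells": self.n_cells,
            "median_amplitude": _nan_to_none(self.median_amplitude),
            "profiles": records,
        }
        text = json.dumps(payload, indent=1, allow_nan=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "ReferenceProfiles":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        config = ClassifierConfig(**payload["config"])
        profiles: dict[str, GeneProfile] = {}
        for gene, rec in payload["profiles"].items():
            stats = GeneStats(**{k: (np.nan if v is None else v)
                                 for k, v in rec["stats"].items()})
            fit = None
            fit_rec = rec.get("fit")
            if fit_rec is not None and fit_rec["type"] == "bimodal":
                fit = BimodalFit(**{k: fit_rec[k] for k in
                                    ("phi1", "mu1", "sigma1", "phi2", "mu2", "sigma2")})
            elif fit_rec is not None:
                fit = UnimodalFit(mu=fit_rec["mu"], sigma=fit_rec["sigma"],
                                  quantile_values=np.asarray(fit_rec["quantile_values"]),
                                  quantile_probs=np.asarray(fit_rec["quantile_probs"]))
            dropout = None
            if "dropout" in rec:
                dropout = DropoutParams(lambda_=rec["dropout"]["lambda"],
                                        tau_ref=rec["dropout"]["tau_ref"])
            profiles[gene] = GeneProfile(
                category=GeneCategory(rec["category"]), stats=stats, fit=fit,
                subcategory=GeneCategory(rec["subcategory"]) if rec["subcategory"] else None,
                dropout=dropout, discard_reason=rec.get("discard_reason"),
            )
        ma = payload.get("median_amplitude")
        return cls(profiles=profiles, config=config, n_cells=payload["n_cells"],
                   median_amplitude=np.nan if ma is None else ma)


def _jsonable(d: dict) -> dict:
    return {k: _nan_to_none(v) for k, v in d.items()}


def _nan_to_none(v):
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v
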