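"""Gene statistics, classification cascade and parametric fits."""

import numpy as np
import pytest

from scbinsim import (
    ClassifierConfig,
    GeneCategory,
    bimodality_index,
    classify_gene,
    compute_gene_stats,
    fit_profile,
)
from scbinsim.profiles import BimodalFit, UnimodalFit
from scbinsim.stats import fit_gaussian_mixture2


class TestComputeGeneStats:
    def test_all_zero_gene(self):
        s = compute_gene_stats(np.zeros(50))
        assert s.dropout_rate == 1.0
        assert s.n_nonzero == 0
        assert s.amplitude == 0.0
        assert np.isnan(s.mean_nz) and np.isnan(s.dip_pvalue)

    def test_small_example_arithmetic(self):
        s = compute_gene_stats(np.array([0.0, 0.0, 2.0, 4.0]))
        assert s.dropout_rate == 0.5
        assert s.mean_nz == 3.0
        assert s.amplitude == 4.0
        assert s.median_nz == 3.0
        assert s.n_nonzero == 2

    def test_bimodal_sample_flags(self, rng):
        """A well-separated mixture has a significant dip and a high BI."""
        x = np.concatenate([rng.normal(2, 0.5, 500), rng.normal(6, 0.5, 500)])
        s = compute_gene_stats(np.clip(x, 0, None), seed=0)
        assert s.dip_pvalue < 0.05
        assert s.bimodality_index > 1.5

    def test_unimodal_sample_not_flagged(self, rng):
        x = np.abs(rng.normal(5, 1, 800))
        s = compute_gene_stats(x, seed=0)
        assert s.dip_pvalue > 0.05 or s.bimodality_index <= 1.5

    def test_nonzero_statistics_exclude_zeros(self, rng):
        """Adding zeros changes dropout rate but not the *_nz moments."""
        base = rng.normal(5, 1, 400)
        with_zeros = np.concatenate([base, np.zeros(100)])
        a = compute_gene_stats(np.abs(base))
        b = compute_gene_stats(np.abs(with_zeros))
        assert a.mean_nz == pytest.approx(b.mean_nz)
        assert a.var_nz == pytest.approx(b.var_nz)
        assert b.dropout_rate == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_gene_stats(np.array([]))

    def test_bimodality_index_formula(self, rng):
        """BI approximates delta*sqrt(p(1-p)) from the known mixture."""
        mu1, mu2, sd, p = 2.0, 6.0, 0.5, 0.5
        x = np.concatenate([rng.normal(mu1, sd, 1000), rng.normal(mu2, sd, 1000)])
        expected = (mu2 - mu1) / sd * np.sqrt(p * (1 - p))
        assert bimodality_index(x, seed=0) == pytest.approx(expected, rel=0.1)


class TestClassifyCascade:
    CFG = ClassifierConfig()

    def make_stats(self, **kw):
        base = dict(n=1000, n_nonzero=900, dropout_rate=0.1, amplitude=6.0,
                    min_value=0.0, mean_nz=4.0, dip_pvalue=0.5,
                    bimodality_index=0.3, density_peak=4.0)
        base.update(kw)
        from scbinsim.stats import GeneStats

        return GeneStats(**base)

    def test_discard_on_dropout(self):
        s = self.make_stats(dropout_rate=0.96)
        cat, reason = classify_gene(s, 6.0, self.CFG)
        assert cat is GeneCategory.DISCARDED and "dropout" in reason

    def test_discard_on_amplitude(self):
        s = self.make_stats(amplitude=0.5)
        cat, reason = classify_gene(s, 6.0, self.CFG)
        assert cat is GeneCategory.DISCARDED and "amplitude" in reason

    def test_discard_on_support(self):
        s = self.make_stats(n_nonzero=5)
        cat, _ = classify_gene(s, 6.0, self.CFG)
        assert cat is GeneCategory.DISCARDED

    def test_bimodal_requires_both_criteria(self):
        both = self.make_stats(dip_pvalue=0.001, bimodality_index=2.5)
        assert classify_gene(both, 6.0, self.CFG)[0] is GeneCategory.BIMODAL
        only_dip = self.make_stats(dip_pvalue=0.001, bimodality_index=1.0)
        assert classify_gene(only_dip, 6.0, self.CFG)[0] is not GeneCategory.BIMODAL

    def test_zero_inflated_on_low_peak(self):
        s = self.make_stats(density_peak=0.2)
        assert classify_gene(s, 6.0, self.CFG)[0] is GeneCategory.ZERO_INFLATED

    def test_unimodal_otherwise(self):
        assert classify_gene(self.make_stats(), 6.0, self.CFG)[0] is GeneCategory.UNIMODAL

    def test_simulated_unimodal_gene(self, rng):
        """N(5,1) with 5% zeros lands in the unimodal branch end to end."""
        x = np.concatenate([np.zeros(50), np.abs(rng.normal(5, 1, 950))])
        s = compute_gene_stats(x, seed=0)
        assert classify_gene(s, s.amplitude, self.CFG)[0] is GeneCategory.UNIMODAL

    def test_simulated_zero_inflated_gene(self, rng):
        """70% zeros with a low non-zero bulk peaks at zero."""
        x = np.concatenate([np.zeros(700), np.abs(rng.normal(2, 0.5, 300))])
        s = compute_gene_stats(x, seed=0)
        assert classify_gene(s, 7.0, self.CFG)[0] is GeneCategory.ZERO_INFLATED


class TestFitProfile:
    def test_mixture_parameter_recovery(self, rng):
        """EM recovers well-separated mixture parameters within tolerance."""
        x = np.concatenate([rng.normal(1, 0.3, 1000), rng.normal(5, 0.3, 1000)])
        x = np.clip(x, 1e-6, None)
        prof = fit_profile(x, GeneCategory.BIMODAL)
        assert abs(prof.fit.mu1 - 1.0) < 0.1
        assert abs(prof.fit.mu2 - 5.0) < 0.1
        assert abs(prof.fit.phi1 - 0.5) < 0.05

    def test_mu2_exceeds_mu1_regardless_of_labels(self, rng):
        for seed in range(5):
            x = np.concatenate([rng.normal(2, 0.4, 300), rng.normal(6, 0.8, 700)])
            prof = fit_profile(np.abs(x), GeneCategory.BIMODAL,
                               ClassifierConfig(random_seed=seed))
            assert prof.fit.mu2 > prof.fit.mu1

    def test_constant_gene_unimodal_fit(self):
        x = np.full(100, 3.7)
        prof = fit_profile(x, GeneCategory.UNIMODAL)
        assert prof.fit.mu == pytest.approx(3.7)
        assert prof.fit.sigma == 0.0
        assert prof.fit.iqr == 0.0

    def test_zero_inflated_unimodal_subcase(self, rng):
        """A zero-inflated gene with unimodal non-zero part carries a
        UnimodalFit plus the sub-case flag."""
        x = np.concatenate([np.zeros(700), np.abs(rng.normal(2, 0.5, 300))])
        prof = fit_profile(x, GeneCategory.ZERO_INFLATED)
        assert isinstance(prof.fit, UnimodalFit)
        assert prof.subcategory is GeneCategory.UNIMODAL
        assert prof.category is GeneCategory.ZERO_INFLATED

    def test_zero_inflated_bimodal_subcase(self, rng):
        x = np.concatenate([np.zeros(1500),
                            rng.normal(1.5, 0.3, 250), rng.normal(5, 0.3, 250)])
        prof = fit_profile(np.clip(x, 0, None), GeneCategory.ZERO_INFLATED)
        assert isinstance(prof.fit, BimodalFit)
        assert prof.subcategory is GeneCategory.BIMODAL

    def test_discarded_carries_stats_only(self):
        prof = fit_profile(np.zeros(20), GeneCategory.DISCARDED)
        assert prof.fit is None
        assert prof.stats.dropout_rate == 1.0

    def test_insufficient_support_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            fit_profile(np.array([0.0] * 95 + [1.0] * 5), GeneCategory.UNIMODAL)

    def test_quantile_convention(self):
        """Type-7 linear interpolation: Q(0.05) of 1..100 is 5.95."""
        fit = UnimodalFit.from_values(np.arange(1.0, 101.0))
        assert fit.quantile(0.05) == pytest.approx(5.95)
        assert fit.quantile(0.95) == pytest.approx(95.05)
        assert fit.iqr == pytest.approx(49.5)


def test_em_cell_order_invariance(rng):
    """Sorting inside the EM wrapper makes fits order-independent."""
    x = np.concatenate([rng.normal(2, 0.5, 400), rng.normal(6, 0.5, 600)])
    a = fit_gaussian_mixture2(x, seed=1)
    b = fit_gaussian_mixture2(rng.permutation(x), seed=1)
    assert a == pytest.approx(b, rel=1e-9)
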