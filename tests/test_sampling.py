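"""Biased sampling from learnt fits and dropout-aware generation."""

import numpy as np
import pandas as pd
import pytest

from scbinsim import (
    GenerationConfig,
    clip_nonnegative,
    generate_from_boolean,
    sample_bimodal,
    sample_unimodal,
)
from scbinsim.profiles import BimodalFit, UnimodalFit

UNI = UnimodalFit.from_values(np.random.default_rng(0).normal(4, 1, 500))
BIM = BimodalFit(phi1=0.4, mu1=1.5, sigma1=0.4, phi2=0.6, mu2=5.0, sigma2=0.6)


class TestSampleUnimodal:
    def test_half_normal_support(self, rng):
        active = sample_unimodal(1, UNI, 2000, rng)
        inactive = sample_unimodal(0, UNI, 2000, rng)
        assert (active >= UNI.mu).all()
        assert (inactive <= UNI.mu).all()

    def test_half_normal_mean(self, rng):
        """Active mean converges to mu + sigma*sqrt(2/pi)."""
        n = 100_000
        draws = sample_unimodal(1, UNI, n, rng)
        expected = UNI.mu + UNI.sigma * np.sqrt(2 / np.pi)
        se = UNI.sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_sigma_zero_is_constant(self, rng):
        fit = UnimodalFit(mu=2.0, sigma=0.0, quantile_values=np.full(201, 2.0))
        assert (sample_unimodal(0, fit, 50, rng) == 2.0).all()
        assert (sample_unimodal(1, fit, 50, rng) == 2.0).all()


class TestSampleBimodal:
    def test_component_selection(self, rng):
        n = 100_000
        active = sample_bimodal(1, BIM, n, rng)
        inactive = sample_bimodal(0, BIM, n, rng)
        assert abs(active.mean() - BIM.mu2) < 3 * BIM.sigma2 / np.sqrt(n)
        assert abs(inactive.var() - BIM.sigma1**2) / BIM.sigma1**2 < 0.05


class TestClip:
    def test_examples(self):
        np.testing.assert_array_equal(clip_nonnegative([-0.3, 0.0, 2.1]),
                                      [0.0, 0.0, 2.1])
        x = np.array([0.5, 1.0])
        np.testing.assert_array_equal(clip_nonnegative(x), x)

    def test_negative_mass_becomes_zeros(self, rng):
        draws = clip_nonnegative(rng.normal(0.2, 1.0, 5000))
        assert (draws == 0).mean() > 0.2  # P(N(0.2,1) < 0) ~ 0.42


class TestGenerateFromBoolean:
    @pytest.fixture()
    def states(self, learned_profiles):
        genes = [g for g in learned_profiles.genes
                 if learned_profiles[g].category.value != "discarded"]
        rng = np.random.default_rng(4)
        data = rng.integers(0, 2, (6, len(genes)))
        return pd.DataFrame(data, columns=genes,
                            index=[f"state{i}" for i in range(6)])

    def test_shape_and_row_tagging(self, states, learned_profiles):
        out = generate_from_boolean(states, learned_profiles,
                                    config=GenerationConfig(n_samples_per_state=7))
        assert out.shape == (6 * 7, states.shape[1])
        assert out.index[0] == "state0::0"
        assert out.index[-1] == "state5::6"

    def test_all_active_unimodal_no_dropout_floor(self, learned_profiles):
        """Active unimodal cells never fall below the gene's mean."""
        genes = [g for g, p in learned_profiles.profiles.items()
                 if p.category.value == "unimodal"]
        states = pd.DataFrame(np.ones((1, len(genes)), dtype=int), columns=genes,
                              index=["all_on"])
        out = generate_from_boolean(states, learned_profiles,
                                    config=GenerationConfig(n_samples_per_state=200,
                                                            dropout_mode="none"))
        for g in genes:
            assert (out[g] >= learned_profiles[g].fit.mu - 1e-12).all()

    def test_biased_ordering(self, learned_profiles):
        """Per gene, active-state means exceed inactive-state means."""
        genes = [g for g, p in learned_profiles.profiles.items()
                 if p.category.value != "discarded"]
        states = pd.DataFrame(
            np.vstack([np.ones(len(genes), dtype=int), np.zeros(len(genes), dtype=int)]),
            columns=genes, index=["on", "off"])
        out = generate_from_boolean(states, learned_profiles,
                                    config=GenerationConfig(n_samples_per_state=300,
                                                            dropout_mode="none",
                                                            random_seed=1))
        on = out.loc[[i for i in out.index if i.startswith("on")]]
        off = out.loc[[i for i in out.index if i.startswith("off")]]
        for g in genes:
            assert on[g].mean() > off[g].mean(), g

    def test_learned_dropout_calibration(self, learned_profiles):
        """Realised dropout per gene stays within 4 Poisson-binomial SDs
        of the reference rate (plus clipping zeros for low genes)."""
        genes = [g for g, p in learned_profiles.profiles.items()
                 if p.category.value == "bimodal"]
        states = pd.DataFrame(np.ones((2, len(genes)), dtype=int), columns=genes,
                              index=["a", "b"])
        out = generate_from_boolean(states, learned_profiles,
                                    config=GenerationConfig(n_samples_per_state=500,
                                                            random_seed=9))
        for g in genes:
            prof = learned_profiles[g]
            tau = prof.dropout.tau_ref
            realised = float((out[g] == 0).mean())
            sd = np.sqrt(tau * (1 - tau) / len(out))
            assert abs(realised - tau) < max(4 * sd, 0.03), g

    def test_user_rates_zero_gives_no_dropout_zeros(self, states, learned_profiles):
        rates = {g: 0.0 for g in states.columns}
        out = generate_from_boolean(
            states, learned_profiles,
            config=GenerationConfig(n_samples_per_state=50, dropout_mode="user_rates",
                                    user_rates=rates))
        # only clipping zeros possible; high-mean unimodal genes have none
        for g in states.columns:
            if learned_profiles[g].category.value == "unimodal":
                assert (out[g] > 0).all()

    def test_user_rates_hit_targets(self, learned_profiles):
        """Arbitrary per-gene rate targets are reproduced."""
        genes = [g for g, p in learned_profiles.profiles.items()
                 if p.category.value == "bimodal"][:4]
        states = pd.DataFrame(np.ones((1, len(genes)), dtype=int), columns=genes)
        rates = {g: r for g, r in zip(genes, (0.1, 0.25, 0.4, 0.6))}
        out = generate_from_boolean(
            states, learned_profiles,
            config=GenerationConfig(n_samples_per_state=2000,
                                    dropout_mode="user_rates", user_rates=rates,
                                    random_seed=3))
        for g in genes:
            assert abs((out[g] == 0).mean() - rates[g]) < 0.05, g

    def test_undetermined_states_rejected(self, learned_profiles):
        genes = list(learned_profiles.genes)[:2]
        states = pd.DataFrame({genes[0]: [0.0, np.nan], genes[1]: [1.0, 0.0]})
        with pytest.raises(ValueError, match="undetermined"):
            generate_from_boolean(states, learned_profiles)

    def test_gene_order_invariance(self, states, learned_profiles):
        cfg = GenerationConfig(n_samples_per_state=5, random_seed=11)
        a = generate_from_boolean(states, learned_profiles, config=cfg)
        b = generate_from_boolean(states[states.columns[::-1]], learned_profiles,
                                  config=cfg)
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_discarded_gene_in_mapping_rejected(self):
        from scbinsim import PseudocountModel

        rng = np.random.default_rng(2)
        data = pd.DataFrame({
            "dead": np.zeros(300),
            "alive": np.abs(rng.normal(5, 1, 300)),
        })
        profiles = PseudocountModel(data).fit()
        states = pd.DataFrame({"n1": [0, 1]})
        with pytest.raises(ValueError, match="discarded"):
            generate_from_boolean(states, profiles, mapping={"n1": "dead"})

    def test_non_injective_mapping_rejected(self, states, learned_profiles):
        g = states.columns[0]
        mapping = {n: g for n in states.columns[:2]}
        small = states[states.columns[:2]]
        with pytest.raises(ValueError, match="injective"):
            generate_from_boolean(small, learned_profiles, mapping=mapping)
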