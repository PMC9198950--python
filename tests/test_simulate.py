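import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest, norm

from flowscreen.experiments import DEFAULT_GATES
from flowscreen.gating import summarize_wells
from flowscreen.io import PlateMap
from flowscreen.simulate import (
    DEFAULT_BASELINE,
    DEFAULT_BOUNDARIES,
    EffectSpec,
    MixtureModel,
    SimConfig,
    apply_effect,
    compose_effects,
    expected_mfi,
    expected_stratum_fractions,
    simulate_screen,
)


def _one_well_map(gene="GeneA") -> PlateMap:
    rows = [
        dict(plate_id="c1-P01", well_id="A1", role="target",
             target_gene=gene, culture_id="c1", culture_age="pup"),
        dict(plate_id="c1-P01", well_id="H10", role="nontargeted_control",
             target_gene="", culture_id="c1", culture_age="pup"),
    ]
    return PlateMap(pd.DataFrame(rows))


class TestMixtureModel:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureModel((0.5, 0.2, 0.2, 0.2), (1, 2, 3, 4), (1, 1, 1, 1))

    def test_means_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MixtureModel((0.25,) * 4, (1, 3, 2, 4), (1, 1, 1, 1))


class TestEffects:
    def test_null_effect_is_identity(self):
        eff = EffectSpec(target_gene="x")
        assert eff.is_null
        out = apply_effect(DEFAULT_BASELINE, eff)
        assert out.weights == DEFAULT_BASELINE.weights
        assert out.mu == DEFAULT_BASELINE.mu

    def test_renormalized_bright_weight_closed_form(self):
        # f=0.5 on w_B=0.10: w'_B = 0.5*0.10 / (1 - 0.5*0.10) = 0.05/0.95
        eff = EffectSpec(target_gene="x", bright_weight_factor=0.5)
        out = apply_effect(DEFAULT_BASELINE, eff)
        assert out.weights[3] == pytest.approx(0.05 / 0.95, abs=1e-12)
        assert sum(out.weights) == pytest.approx(1.0, abs=1e-12)

    def test_compose_multiplies_factors_and_adds_shifts(self):
        a = EffectSpec("g", bright_weight_factor=0.5, intensity_shift=-0.1)
        b = EffectSpec("g", bright_weight_factor=0.8, intensity_shift=-0.2,
                       viability_factor=0.9)
        c = compose_effects([a, b])
        assert c.bright_weight_factor == pytest.approx(0.4)
        assert c.intensity_shift == pytest.approx(-0.3)
        assert c.viability_factor == pytest.approx(0.9)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            EffectSpec(target_gene="x", bright_weight_factor=0.0)

    @given(f=st.floats(0.05, 1.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_decreasing_bright_factor_never_raises_expected_bright(self, f):
        eff = apply_effect(DEFAULT_BASELINE,
                           EffectSpec("x", bright_weight_factor=f))
        frac = expected_stratum_fractions(eff, DEFAULT_BOUNDARIES)[3]
        base = expected_stratum_fractions(DEFAULT_BASELINE,
                                          DEFAULT_BOUNDARIES)[3]
        assert frac <= base + 1e-12


class TestSimulateScreen:
    def test_seeded_determinism(self):
        pm = _one_well_map()
        cfg = SimConfig(seed=42, n_events_per_well=500)
        ev1, tr1 = simulate_screen(cfg, pm)
        ev2, tr2 = simulate_screen(cfg, pm)
        pd.testing.assert_frame_equal(ev1, ev2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_different_seed_differs(self):
        pm = _one_well_map()
        ev1, _ = simulate_screen(SimConfig(seed=1, n_events_per_well=500), pm)
        ev2, _ = simulate_screen(SimConfig(seed=2, n_events_per_well=500), pm)
        assert not ev1["intensity"].equals(ev2["intensity"])

    def test_realized_weights_sum_to_one(self):
        pm = _one_well_map()
        _, truth = simulate_screen(SimConfig(seed=0, n_events_per_well=10), pm)
        sums = truth[["w_negative", "w_dim", "w_mid", "w_bright"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_noise_free_effect_halves_bright_weight(self):
        pm = _one_well_map("GeneA")
        cfg = SimConfig(
            effects={"GeneA": EffectSpec("GeneA", bright_weight_factor=0.5)},
            culture_noise_sd=0.0, well_noise_sd=0.0,
            seed=0, n_events_per_well=10,
        )
        _, truth = simulate_screen(cfg, pm)
        w = truth.set_index("well_key").loc["c1-P01:A1", "w_bright"]
        assert w == pytest.approx(0.05 / 0.95, abs=1e-12)

    def test_gated_bright_within_binomial_bound_of_weight(self):
        pm = _one_well_map()
        n = 10_000
        cfg = SimConfig(seed=3, n_events_per_well=n, culture_noise_sd=0.0,
                        well_noise_sd=0.0, base_viability=1.0)
        events, truth = simulate_screen(cfg, pm)
        summaries = summarize_wells(events, DEFAULT_GATES)
        # compare against the mixture-theoretic gated fraction, which folds
        # in inter-stratum overlap, not the raw component weight
        expected = expected_stratum_fractions(
            DEFAULT_BASELINE, DEFAULT_GATES.boundaries
        )[3]
        se = np.sqrt(expected * (1 - expected) / n)
        got = summaries["pct_bright"].iloc[0] / 100.0
        assert abs(got - expected) < 3 * se

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="n_events_per_well"):
            SimConfig(n_events_per_well=0)

    def test_viability_thinning(self):
        pm = _one_well_map()
        cfg = SimConfig(seed=5, n_events_per_well=5000, base_viability=0.5)
        events, truth = simulate_screen(cfg, pm)
        frac = events.groupby("well_key")["viable"].mean()
        assert ((frac - 0.5).abs() < 3 * np.sqrt(0.25 / 5000)).all()


class TestNullCalibration:
    """Distributional checks on the all-null screen (shared session run)."""

    def test_per_replicate_z_standardized(self, null_run):
        zt = null_run["ztable"]
        # avg over R=3 of standardized scores: mean 0 by construction
        assert abs(zt["avg_z_all"].mean()) < 1e-9

    def test_avg_z_sd_close_to_inverse_sqrt_r(self, null_run):
        sd = null_run["avg_z"].std(ddof=1)
        assert sd == pytest.approx(1 / np.sqrt(3), rel=0.05)

    def test_avg_z_cdf_close_to_normal(self, null_run):
        ks = kstest(null_run["avg_z"], "norm",
                    args=(0, 1 / np.sqrt(3))).statistic
        assert ks < 0.05

    def test_tail_fraction_matches_normal_tail(self, null_run):
        expected = 1 - norm.cdf(np.sqrt(3))  # ~4.2% at R=3
        assert null_run["fraction_avg_z_gt1"] == pytest.approx(
            expected, abs=0.01
        )
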