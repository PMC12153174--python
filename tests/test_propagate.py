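"""Monte Carlo engine tests: truncated draws, perturbation, harmonization,
the per-tree prediction chain, and the full simulation loop."""

import numpy as np
import pytest

from allomprop.models import VarianceFnParams
from allomprop.propagate import (
    REPORT_COMPONENTS,
    SimulationConfig,
    draw_replicate,
    draw_truncated_z,
    harmonize,
    perturbed_prediction,
    predict_tree_replicate,
    run_simulation,
)

POWER_VFN = VarianceFnParams("power", 0.1075, 0.9667)


def degenerate_config(n_replicates=5, seed=0, **overrides):
    kwargs = dict(
        n_replicates=n_replicates,
        seed=seed,
        parameter_uncertainty=False,
        residual_uncertainty=False,
        wdsg_uncertainty=False,
        cf_uncertainty=False,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestTruncatedNormal:
    def test_hard_bound_and_moments(self, rng):
        z = draw_truncated_z(rng, size=100_000)
        assert np.all(np.abs(z) <= 3.0)
        assert abs(z.mean()) < 0.01
        # closed form: SD of N(0,1) truncated at +/-3 is 0.98658
        assert z.std() == pytest.approx(0.98658, abs=0.01)
        assert 0.96 <= z.std() <= 1.00

    def test_same_seed_gives_same_stream(self):
        z1 = draw_truncated_z(np.random.default_rng(4), size=1000)
        z2 = draw_truncated_z(np.random.default_rng(4), size=1000)
        np.testing.assert_array_equal(z1, z2)


class TestPerturbedPrediction:
    def test_zero_deviate_leaves_prediction(self):
        assert perturbed_prediction(1.7, POWER_VFN, 0.0) == 1.7

    def test_unit_deviate_at_unit_prediction(self):
        assert perturbed_prediction(1.0, POWER_VFN, 1.0) == pytest.approx(1.1075)

    def test_monte_carlo_sd_matches_variance_function(self, rng):
        z = draw_truncated_z(rng, size=10_000)
        vals = perturbed_prediction(2.0, POWER_VFN, z)
        target = 0.98658 * 0.1075 * 2.0**0.9667  # truncation shrinks the SD
        assert vals.std() == pytest.approx(target, rel=0.03)

    def test_negative_outcomes_clamped(self):
        out = perturbed_prediction(0.01, VarianceFnParams("power", 1.0, 1.0), -3.0)
        assert out == 0.0


class TestHarmonize:
    def test_doubling_example(self):
        np.testing.assert_allclose(harmonize(2.0, 1.0, 1.0, 8.0), (4.0, 2.0, 2.0))

    def test_consistent_sum_unchanged(self):
        np.testing.assert_allclose(harmonize(3.0, 2.0, 1.0, 6.0), (3.0, 2.0, 1.0))

    def test_outputs_sum_to_total(self, rng):
        x = rng.uniform(0.1, 50.0, (200, 4))
        a, b, c = harmonize(x[:, 0], x[:, 1], x[:, 2], x[:, 3])
        np.testing.assert_allclose(a + b + c, x[:, 3], rtol=1e-12)
        np.testing.assert_allclose(a / b, x[:, 0] / x[:, 1], rtol=1e-12)

    def test_zero_sum_raises(self):
        with pytest.raises(ValueError):
            harmonize(0.0, 0.0, 0.0, 5.0)


class TestTreeChain:
    def test_degenerate_draw_is_deterministic(self, small_fit):
        system = small_fit.system
        cfg = degenerate_config()
        rng = np.random.default_rng(0)
        draw = draw_replicate(system, cfg, rng)
        c1, m1 = predict_tree_replicate(35.0, 24.0, draw, system, cfg, rng)
        c2, m2 = predict_tree_replicate(35.0, 24.0, draw, system, cfg, rng)
        assert m1 == m2
        for k in c1:
            assert c1[k] == c2[k] or (np.isnan(c1[k]) and np.isnan(c2[k]))

    def test_additivity_identities_per_tree(self, small_fit):
        """Volume, harmonized biomass, and carbon all satisfy OB = IB + BK;
        harmonized components sum to the aboveground total; carbon equals
        biomass times the replicate carbon fraction."""
        system = small_fit.system
        cfg = SimulationConfig(n_replicates=2, seed=1)
        root = np.random.default_rng(42)
        for rep in range(4):
            draw = draw_replicate(system, cfg, root)
            for dbh, height in [(3.0, 4.5), (14.0, 12.0), (36.0, 25.0), (85.0, 38.0)]:
                comp, merch = predict_tree_replicate(dbh, height, draw, system, cfg, root)
                assert comp["TSV_OB"] == pytest.approx(
                    comp["TSV_IB"] + comp["TSV_BK"], rel=1e-9
                )
                assert comp["TSBH_OB"] == pytest.approx(
                    comp["TSBH_IB"] + comp["TSBH_BK"], rel=1e-9
                )
                assert comp["B_AG"] == pytest.approx(
                    comp["TSBH_IB"] + comp["TSBH_BK"] + comp["BH_BR"], rel=1e-9
                )
                assert comp["C_AG"] == pytest.approx(
                    comp["TSCH_IB"] + comp["TSCH_BK"] + comp["CH_BR"], rel=1e-9
                )
                assert comp["TSCH_IB"] == pytest.approx(
                    comp["TSBH_IB"] * draw.cf, rel=1e-12
                )
                if merch:
                    assert comp["MSV_OB"] == pytest.approx(
                        comp["MSV_IB"] + comp["MSV_BK"], rel=1e-9
                    )
                    assert comp["MSCH_OB"] == pytest.approx(
                        comp["MSBH_OB"] * draw.cf, rel=1e-12
                    )
                    assert comp["MSV_IB"] <= comp["TSV_IB"] * (1 + 1e-12)
                    assert comp["MSV_OB"] <= comp["TSV_OB"] * (1 + 1e-12)

    def test_small_tree_never_merchantable(self, small_fit):
        system = small_fit.system
        cfg = degenerate_config()
        rng = np.random.default_rng(3)
        draw = draw_replicate(system, cfg, rng)
        comp, merch = predict_tree_replicate(5.0, 6.0, draw, system, cfg, rng)
        assert not merch
        assert np.isnan(comp["MSV_IB"])

    def test_below_domain_threshold_rejected(self, small_fit):
        system = small_fit.system
        cfg = degenerate_config()
        rng = np.random.default_rng(3)
        draw = draw_replicate(system, cfg, rng)
        with pytest.raises(ValueError):
            predict_tree_replicate(2.0, 3.0, draw, system, cfg, rng)


class TestRunSimulation:
    def test_all_sources_disabled_gives_zero_model_variance(
        self, small_fit, small_inventory
    ):
        res = run_simulation(small_inventory, small_fit.system, degenerate_config())
        for name in REPORT_COMPONENTS:
            d = res.decompose(name)
            # identical replicates up to one ulp of the replicate mean
            assert np.sqrt(d.v_m) <= 1e-12 * abs(d.y)
            assert d.m_pct < 1e-9 and d.s_pct < 1e-9

    def test_seeded_runs_reproduce(self, small_fit, small_inventory):
        cfg = SimulationConfig(n_replicates=4, seed=9)
        r1 = run_simulation(small_inventory, small_fit.system, cfg)
        r2 = run_simulation(small_inventory, small_fit.system, cfg)
        for name in REPORT_COMPONENTS:
            np.testing.assert_array_equal(r1.y_r[name], r2.y_r[name])
            np.testing.assert_array_equal(r1.v_y_r[name], r2.v_y_r[name])

    def test_wdsg_only_uncertainty_isolates_biomass(self, small_fit, small_inventory):
        """With only WDSG uncertainty active, volume components carry no
        model variance while stem-wood biomass does."""
        cfg = degenerate_config(n_replicates=12, seed=5, wdsg_uncertainty=True)
        res = run_simulation(small_inventory, small_fit.system, cfg)
        for name in ("TSV_IB", "TSV_BK", "TSV_OB", "MSV_IB", "MSV_OB"):
            d = res.decompose(name)
            assert np.sqrt(d.v_m) <= 1e-12 * abs(d.y), name
        d = res.decompose("TSBH_IB")
        assert np.sqrt(d.v_m) > 1e-6 * abs(d.y)
        d = res.decompose("MSBH_IB")
        assert np.sqrt(d.v_m) > 1e-6 * abs(d.y)

    def test_larger_wdsg_se_increases_model_variance(self, small_fit, small_inventory):
        from dataclasses import replace

        base = small_fit.system
        doubled = small_fit.system
        doubled.wdsg = replace(base.wdsg, se=2 * base.wdsg.se)
        cfg = degenerate_config(n_replicates=40, seed=5, wdsg_uncertainty=True)
        v_base = run_simulation(small_inventory, base, cfg).decompose("TSBH_IB").v_m
        v_doubled = run_simulation(small_inventory, doubled, cfg).decompose("TSBH_IB").v_m
        assert v_doubled > v_base

    def test_replicate_table_shape(self, small_fit, small_inventory):
        cfg = SimulationConfig(n_replicates=3, seed=2)
        res = run_simulation(small_inventory, small_fit.system, cfg)
        frame = res.to_frame()
        assert len(frame) == 3 * len(REPORT_COMPONENTS)
        assert set(frame["component"]) == set(REPORT_COMPONENTS)
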