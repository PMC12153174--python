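"""Fitting-stage tests: NLS recovery, bootstrap ensembles, residual groups,
variance-function fits, and scalar-mean summaries."""

import numpy as np
import pandas as pd
import pytest

from allomprop.fitting import (
    FitError,
    ScalarMeanEstimate,
    bootstrap_ensemble,
    fit_model,
    fit_variance_fn,
    group_residuals,
    se_of_mean,
)
from allomprop.fitting import ResidualGroups
from allomprop.models import COMPONENT_FORMS, predict_component
from allomprop.synthdata import TRUE_PARAMS, GeneratorConfig, generate_fitting_data


def make_allometric_frame(rng, form, theta, n=300, noise_sd=0.0):
    dbh = rng.uniform(4.0, 90.0, n)
    height = 3.0 * dbh**0.55 * np.exp(rng.normal(0, 0.2, n))
    y = predict_component(form, theta, dbh=dbh, height=height)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"tree_id": np.arange(n), "D_cm": dbh, "H_m": height, "y": y})


def make_profile_frame(rng, theta, n_trees=60, per_tree=10, noise_sd=0.0):
    height = rng.uniform(8.0, 40.0, n_trees).repeat(per_tree)
    tree_id = np.arange(n_trees).repeat(per_tree)
    h = height * rng.uniform(0.02, 0.99, n_trees * per_tree)
    r = predict_component("ratio", theta, h=h, height=height)
    if noise_sd:
        r = np.clip(r + rng.normal(0, noise_sd, r.size), 0.0, 1.0)
    return pd.DataFrame({"tree_id": tree_id, "h_m": h, "H_m": height, "R": r})


class TestFitModel:
    @pytest.mark.parametrize(
        "form, theta",
        [
            ("power", (8.0e-5, 1.95, 0.93)),
            ("segmented", (1.0e-5, 2.0, 0.85, 1.8)),
            ("exp_decay", (6.0e-5, 2.0, 0.95, 0.002)),
        ],
    )
    def test_noise_free_recovery(self, rng, form, theta):
        frame = make_allometric_frame(rng, form, theta)
        fit = fit_model(form, frame)
        np.testing.assert_allclose(fit.theta, theta, rtol=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_ratio_noise_free_recovery(self, rng):
        frame = make_profile_frame(rng, (2.5, 1.2))
        fit = fit_model("ratio", frame)
        np.testing.assert_allclose(fit.theta, (2.5, 1.2), rtol=1e-6)

    def test_noisy_recovery_within_bootstrap_uncertainty(self, rng):
        """With heteroscedastic noise at n=500, the estimate lands within
        three bootstrap standard errors of the truth."""
        theta = (8.0e-5, 1.95, 0.93)
        frame = make_allometric_frame(rng, "power", theta, n=500)
        yhat = frame["y"].to_numpy()
        frame["y"] = yhat + rng.normal(0, 0.1075 * yhat**0.9667)
        ens = bootstrap_ensemble("power", frame, n_boot=200, seed=5)
        se = ens.draws.std(axis=0, ddof=1)
        assert np.all(np.abs(ens.point - np.asarray(theta)) < 3 * se)

    def test_too_few_rows_raise(self, rng):
        frame = make_allometric_frame(rng, "power", (1e-4, 2, 1), n=3)
        with pytest.raises(FitError):
            fit_model("power", frame)

    def test_fixed_parameters_are_respected(self, rng):
        frame = make_allometric_frame(rng, "power", (2.0, 0.0, 0.0), noise_sd=0.3)
        fit = fit_model("power", frame, start=(1.0, 0.0, 0.0), fixed={"b": 0.0, "c": 0.0})
        assert fit.theta[1] == 0.0 and fit.theta[2] == 0.0
        assert fit.theta[0] == pytest.approx(frame["y"].mean(), rel=1e-8)


class TestBootstrapEnsemble:
    def test_seeded_runs_are_identical(self, rng):
        frame = make_allometric_frame(rng, "power", (8e-5, 1.95, 0.93), noise_sd=0.05)
        e1 = bootstrap_ensemble("power", frame, n_boot=8, seed=3)
        e2 = bootstrap_ensemble("power", frame, n_boot=8, seed=3)
        np.testing.assert_array_equal(e1.draws, e2.draws)

    def test_noise_free_data_collapse_to_point(self, rng):
        frame = make_allometric_frame(rng, "power", (8e-5, 1.95, 0.93))
        ens = bootstrap_ensemble("power", frame, n_boot=6, seed=1)
        np.testing.assert_allclose(
            ens.draws, np.tile(ens.point, (6, 1)), rtol=1e-5, atol=1e-10
        )

    def test_variance_matches_analytic_mean_estimation(self, rng):
        """With both exponents pinned at zero the model is plain mean
        estimation, whose sampling variance is sigma^2/n."""
        n, sigma = 400, 0.5
        frame = make_allometric_frame(rng, "power", (2.0, 0.0, 0.0), n=n)
        frame["y"] = 2.0 + rng.normal(0, sigma, n)

        # tree-level bootstrap of the sample mean (each row is one tree)
        y = frame["y"].to_numpy()
        boot_rng = np.random.default_rng(99)
        draws = np.empty(2500)
        for b in range(2500):
            draws[b] = y[boot_rng.integers(n, size=n)].mean()
        assert draws.var(ddof=1) == pytest.approx(sigma**2 / n, rel=0.15)

    def test_ensemble_mean_approaches_point_with_draws(self, rng):
        frame = make_allometric_frame(rng, "power", (8e-5, 1.95, 0.93), n=250)
        yhat = frame["y"].to_numpy()
        frame["y"] = yhat + rng.normal(0, 0.1 * yhat)
        small = bootstrap_ensemble("power", frame, n_boot=25, seed=2)
        large = bootstrap_ensemble("power", frame, n_boot=400, seed=2)
        rel = lambda e: np.linalg.norm((e.mean() - e.point) / e.point)
        assert rel(large) < rel(small)

    def test_profile_resampling_moves_whole_trees(self, rng):
        """Bootstrap of profile data keeps all rows of a tree together, so
        every resample size is a multiple of the per-tree row count."""
        frame = make_profile_frame(rng, (2.5, 1.2), n_trees=25, per_tree=7, noise_sd=0.02)
        ens = bootstrap_ensemble("ratio", frame, n_boot=4, seed=8)
        assert ens.draws.shape == (4, 2)


class TestResidualGroups:
    def test_two_exact_groups_of_minimum_size(self, rng):
        frame = make_allometric_frame(rng, "power", (1e-4, 2.0, 1.0), n=50, noise_sd=0.01)
        groups = group_residuals(frame, "power", (1e-4, 2.0, 1.0))
        np.testing.assert_array_equal(groups.sizes, [25, 25])

    def test_remainder_absorbed_into_last_group(self, rng):
        frame = make_allometric_frame(rng, "power", (1e-4, 2.0, 1.0), n=60, noise_sd=0.01)
        groups = group_residuals(frame, "power", (1e-4, 2.0, 1.0))
        np.testing.assert_array_equal(groups.sizes, [25, 35])

    def test_sizes_partition_sample(self, rng):
        frame = make_allometric_frame(rng, "power", (1e-4, 2.0, 1.0), n=487, noise_sd=0.05)
        groups = group_residuals(frame, "power", (1e-4, 2.0, 1.0))
        assert groups.sizes.sum() == 487
        assert np.all(groups.sizes[:-1] == 25)
        assert np.all(np.diff(groups.y_hat_mean) > 0)  # ordered by size

    def test_small_sample_warns_single_group(self, rng):
        frame = make_allometric_frame(rng, "power", (1e-4, 2.0, 1.0), n=30, noise_sd=0.01)
        with pytest.warns(UserWarning):
            groups = group_residuals(frame, "power", (1e-4, 2.0, 1.0))
        assert groups.single_group and groups.n_groups == 1

    def test_homoscedastic_noise_gives_flat_group_sds(self, rng):
        frame = make_allometric_frame(rng, "power", (1e-4, 2.0, 1.0), n=2000)
        frame["y"] = frame["y"] + rng.normal(0, 0.3, 2000)
        groups = group_residuals(frame, "power", (1e-4, 2.0, 1.0), min_group=200)
        # chi-distribution spread at group size 200 is ~5%; allow 4 sigma
        assert groups.residual_sd.std() / groups.residual_sd.mean() < 0.20


class TestVarianceFunctionFit:
    def test_exact_power_groups_recover_parameters(self):
        ybar = np.linspace(0.05, 3.0, 12)
        sd = 0.1075 * ybar**0.9667
        params, stats = fit_variance_fn(
            ResidualGroups(ybar, sd, np.full(12, 25)), "power"
        )
        assert params.phi1 == pytest.approx(0.1075, rel=1e-8)
        assert params.phi2 == pytest.approx(0.9667, rel=1e-8)
        assert stats["r_squared"] == pytest.approx(1.0)

    def test_two_power_groups_interpolate_exactly(self):
        ybar = np.array([0.5, 2.0])
        sd = 0.2 * ybar**1.1
        params, stats = fit_variance_fn(ResidualGroups(ybar, sd, np.full(2, 25)), "power")
        assert stats["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_jittered_bell_groups_recover_parameters(self, rng):
        ybar = np.linspace(0.02, 0.99, 40)
        sd = 0.0470 * 0.0012 ** ((ybar - 0.5603) ** 2)
        sd = sd * (1 + rng.normal(0, 0.02, sd.size))
        params, _ = fit_variance_fn(ResidualGroups(ybar, sd, np.full(40, 25)), "bell")
        assert params.phi1 == pytest.approx(0.0470, rel=0.10)
        assert params.phi2 == pytest.approx(0.0012, rel=0.5)
        assert params.phi3 == pytest.approx(0.5603, rel=0.10)

    def test_bell_needs_four_groups(self):
        with pytest.raises(FitError):
            fit_variance_fn(
                ResidualGroups(np.array([0.2, 0.5, 0.8]), np.array([0.01, 0.04, 0.02]),
                               np.full(3, 25)),
                "bell",
            )


class TestScalarMeans:
    @pytest.mark.parametrize(
        "sd, n, expected",
        [(0.16, 96, 0.016), (0.0, 17, 0.0), (1.0, 4, 0.5)],
    )
    def test_se_of_mean(self, sd, n, expected):
        assert se_of_mean(sd, n) == pytest.approx(expected, abs=5e-4)

    def test_from_sample(self, rng):
        x = rng.normal(0.338, 0.039, 96)
        est = ScalarMeanEstimate.from_sample(x)
        assert est.n == 96
        assert est.mean == pytest.approx(np.mean(x))
        assert est.se == pytest.approx(np.std(x, ddof=1) / np.sqrt(96))


class TestRecoveryAtScale:
    def test_generated_data_recover_generating_parameters(self, small_data):
        """Fitting the synthetic datasets returns the generator's frozen
        coefficients to within a few percent at reduced sample sizes."""
        for name in ("TSV_IB", "TSV_OB", "B_AG", "R_IB"):
            fit = fit_model(COMPONENT_FORMS[name], small_data.frames[name])
            truth = np.asarray(TRUE_PARAMS[name])
            scale = np.maximum(np.abs(truth), 0.05)
            assert np.all(np.abs(fit.theta - truth) / scale < 0.35), name
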