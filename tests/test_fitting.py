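"""Tests for the two-step SSR/Nelder-Mead fit and bootstrap CIs."""

import numpy as np
import pytest

from emaxfit import (
    DegenerateDataError,
    DrugEffect,
    FitConfig,
    GrowthParameters,
    NoiseModel,
    bootstrap_ci,
    fit_control,
    fit_treated,
    ssr,
    two_step_fit,
)
from emaxfit.data import GrowthDataset, records_frame
from emaxfit.synth import DesignTemplate, design_preset, generate_growth_dataset

from conftest import TRUTH


def make_dataset(rows, plating=None):
    return GrowthDataset(records_frame(rows), plating_density=plating)


class TestSSR:
    def test_zero_on_own_predictions(self, noiseless_dataset):
        pred = noiseless_dataset.records["count"].to_numpy()
        assert ssr(noiseless_dataset, pred) == 0.0

    def test_two_residuals(self):
        ds = make_dataset(
            [("L", "c", 0.0, 1.0, 0, 10.0), ("L", "c", 0.0, 2.0, 0, 20.0)]
        )
        assert ssr(ds, {(0.0, 1.0): 7.0, (0.0, 2.0): 16.0}) == pytest.approx(25.0)

    def test_brute_force_oracle(self, noiseless_dataset, rng):
        rec = noiseless_dataset.records
        pred = rng.uniform(0, 1e5, len(rec))
        # independent elementwise re-summation
        expected = 0.0
        for obs, p in zip(rec["count"], pred):
            expected += (obs - p) ** 2
        assert ssr(noiseless_dataset, pred) == pytest.approx(expected, rel=1e-12)

    def test_missing_prediction_names_point(self):
        ds = make_dataset([("L", "c", 0.0, 1.0, 0, 10.0)])
        with pytest.raises(KeyError, match="dose=0.0, day=1.0"):
            ssr(ds, {(0.0, 2.0): 10.0})

    def test_shuffle_invariance(self, noiseless_dataset, rng):
        result = two_step_fit(noiseless_dataset)
        shuffled = GrowthDataset(
            noiseless_dataset.records.sample(frac=1.0, random_state=7),
            plating_density=noiseless_dataset.plating_density,
        )
        result_shuffled = two_step_fit(shuffled)
        for key in result.params:
            assert result_shuffled.params[key] == pytest.approx(
                result.params[key], rel=1e-6
            )


class TestFitControl:
    def test_noiseless_recovery(self, noiseless_dataset):
        res = fit_control(noiseless_dataset)
        assert res.converged
        assert res.params["lambda"] == pytest.approx(TRUTH["lambda_"], rel=1e-3)
        assert res.params["K"] == pytest.approx(TRUTH["K"], rel=1e-3)

    def test_noiseless_recovery_with_free_n0(self, noiseless_dataset):
        res = fit_control(noiseless_dataset, FitConfig(estimate_n0=True))
        assert res.params["N0"] == pytest.approx(TRUTH["N0"], rel=1e-2)

    def test_grid_search_oracle(self, noiseless_dataset):
        res = fit_control(noiseless_dataset)
        ctrl = noiseless_dataset.control()
        day = ctrl.records["day"].to_numpy(float)
        count = ctrl.records["count"].to_numpy(float)
        lams = np.exp(np.linspace(np.log(0.5 * TRUTH["lambda_"]), np.log(1.5 * TRUTH["lambda_"]), 50))
        Ks = np.exp(np.linspace(np.log(0.5 * TRUTH["K"]), np.log(1.5 * TRUTH["K"]), 50))
        N0 = TRUTH["N0"]
        for lam in lams:
            # vectorized over K for speed; brute-force SSR at every node
            for K in Ks:
                c = K / N0 - 1.0
                pred = K / (1.0 + c * np.exp(-lam * day))
                node = float(np.sum((count - pred) ** 2))
                assert res.ssr <= node + 1e-9

    def test_saturated_well(self):
        rows = [
            ("L", "control", 0.0, d, r, 4321.0)
            for d in (2.0, 4.0, 6.0, 8.0)
            for r in range(3)
        ]
        ds = make_dataset(rows, plating=4321.0)
        res = fit_control(ds)
        assert res.params["K"] == pytest.approx(4321.0, rel=1e-2)
        assert any("constant" in w for w in res.warnings)

    def test_all_zero_counts_degenerate(self):
        rows = [("L", "control", 0.0, d, 0, 0.0) for d in (2.0, 4.0, 6.0)]
        with pytest.raises(DegenerateDataError, match="zero"):
            fit_control(make_dataset(rows, plating=100.0))

    def test_too_few_days_degenerate(self):
        rows = [("L", "control", 0.0, d, 0, 100.0 * d) for d in (2.0, 4.0)]
        with pytest.raises(DegenerateDataError, match="3 distinct days"):
            fit_control(make_dataset(rows, plating=100.0))

    def test_max_day_truncation(self, truth_params, truth_effect, growth_template):
        ds = generate_growth_dataset(
            truth_params, truth_effect, growth_template, NoiseModel(sigma=0.0), seed=2
        )
        res = fit_control(ds, FitConfig(max_day=8.0))
        assert res.converged
        assert res.params["lambda"] == pytest.approx(TRUTH["lambda_"], rel=1e-3)


class TestFitTreated:
    def test_noiseless_recovery(self, noiseless_dataset, truth_params):
        res = fit_treated(noiseless_dataset, truth_params)
        assert res.converged
        assert res.params["Emax"] == pytest.approx(TRUTH["Emax"], rel=1e-2)
        assert res.params["IC50"] == pytest.approx(TRUTH["IC50"], rel=1e-2)

    def test_zero_emax_truth(self, truth_params, growth_template):
        ds = generate_growth_dataset(
            truth_params, DrugEffect(0.0, 1e-3), growth_template,
            NoiseModel(sigma=0.0), seed=4,
        )
        res = fit_treated(ds, truth_params)
        assert res.params["Emax"] <= 0.01
        # no drug effect: residuals equal those of the bare control model
        control_pred = {}
        for dose in ds.treated().doses:
            for day in ds.days:
                c = truth_params.K / truth_params.N0 - 1.0
                control_pred[(dose, day)] = truth_params.K / (
                    1.0 + c * np.exp(-truth_params.lambda_ * day)
                )
        control_ssr = ssr(ds.treated(), control_pred)
        assert res.ssr == pytest.approx(control_ssr, abs=1e-6)

    def test_grid_search_oracle(self, noiseless_dataset, truth_params):
        res = fit_treated(noiseless_dataset, truth_params)
        trt = noiseless_dataset.treated()
        dose = trt.records["dose_ug_ml"].to_numpy(float)
        day = trt.records["day"].to_numpy(float)
        count = trt.records["count"].to_numpy(float)
        lam, K, N0 = truth_params.lambda_, truth_params.K, truth_params.N0
        c = K / N0 - 1.0
        for emax in np.linspace(0.0, 2.0, 50):
            for ic50 in np.logspace(np.log10(TRUTH["IC50"]) - 1, np.log10(TRUTH["IC50"]) + 1, 50):
                r = lam * (1.0 - emax * dose / (dose + ic50))
                pred = K / (1.0 + c * np.exp(-r * day))
                node = float(np.sum((count - pred) ** 2))
                assert res.ssr <= node + 1e-9

    def test_single_dose_warns(self, truth_params, truth_effect):
        template = DesignTemplate(
            plating_density=1000.0, days=(2.0, 4.0, 6.0, 8.0),
            doses=(0.0, 5e-3), replicates=3,
        )
        ds = generate_growth_dataset(
            truth_params, truth_effect, template, NoiseModel(sigma=0.0), seed=5
        )
        res = fit_treated(ds, truth_params)
        assert any("confounded" in w for w in res.warnings)

    def test_emax_boundary_flagged(self, truth_params, growth_template):
        # effect strong enough that the optimum presses the upper bound
        ds = generate_growth_dataset(
            truth_params, DrugEffect(2.0, 1e-6), growth_template,
            NoiseModel(sigma=0.0), seed=6,
        )
        res = fit_treated(ds, truth_params)
        assert res.boundary_hit

    def test_two_step_invariance(self, noiseless_dataset, truth_params):
        # truth-fixed control on noise-free data returns truth
        res = fit_treated(noiseless_dataset, truth_params)
        assert res.params["Emax"] == pytest.approx(TRUTH["Emax"], rel=1e-3)
        assert res.params["IC50"] == pytest.approx(TRUTH["IC50"], rel=1e-3)
        # perturbing the fixed control changes the answer deterministically
        bumped = GrowthParameters(
            truth_params.lambda_ * 1.1, truth_params.K * 1.1, truth_params.N0
        )
        res_a = fit_treated(noiseless_dataset, bumped)
        res_b = fit_treated(noiseless_dataset, bumped)
        assert res_a.params == res_b.params
        assert res_a.params["Emax"] != pytest.approx(TRUTH["Emax"], rel=1e-4)


class TestTwoStepFit:
    def test_combined_report(self, noiseless_dataset):
        res = two_step_fit(noiseless_dataset)
        assert set(res.params) == {"lambda", "K", "Emax", "IC50"}
        report = res.report()
        assert report["converged"] is True
        assert report["ssr"] >= 0.0

    def test_noisy_recovery_single_dataset(self, truth_params, truth_effect, growth_template):
        ds = generate_growth_dataset(
            truth_params, truth_effect, growth_template, NoiseModel(sigma=0.1), seed=11
        )
        res = two_step_fit(ds)
        assert res.converged
        assert res.params["Emax"] == pytest.approx(TRUTH["Emax"], rel=0.5)


class TestBootstrap:
    def test_default_replicates_is_1000(self):
        assert FitConfig().n_boot == 1000

    def test_identical_seeds_bit_identical(self, truth_params, truth_effect, growth_template):
        ds = generate_growth_dataset(
            truth_params, truth_effect, growth_template, NoiseModel(sigma=0.1), seed=8
        )
        fit = two_step_fit(ds)
        a = bootstrap_ci(ds, fit, n_boot=25, seed=99)
        b = bootstrap_ci(ds, fit, n_boot=25, seed=99)
        np.testing.assert_array_equal(a.bootstrap_samples, b.bootstrap_samples)
        c = bootstrap_ci(ds, fit, n_boot=25, seed=100)
        assert not np.array_equal(a.bootstrap_samples, c.bootstrap_samples)

    def test_noise_free_intervals_collapse(self, noiseless_dataset):
        fit = two_step_fit(noiseless_dataset)
        res = bootstrap_ci(noiseless_dataset, fit, n_boot=30, seed=1)
        for key, value in res.params.items():
            width = res.ci_upper[key] - res.ci_lower[key]
            assert width <= 1e-3 * abs(value)

    def test_interval_contains_point_estimate(self, truth_params, truth_effect, growth_template):
        ds = generate_growth_dataset(
            truth_params, truth_effect, growth_template, NoiseModel(sigma=0.1), seed=9
        )
        fit = two_step_fit(ds)
        res = bootstrap_ci(ds, fit, n_boot=100, seed=2)
        for key, value in res.params.items():
            assert res.ci_lower[key] <= value <= res.ci_upper[key]

    def test_residual_scheme_single_replicate(self, truth_params, truth_effect):
        template = DesignTemplate(
            plating_density=1000.0, days=tuple(float(d) for d in range(2, 15, 2)),
            doses=(0.0, 5e-5, 5e-4, 5e-3, 5e-2), replicates=1,
        )
        ds = generate_growth_dataset(
            truth_params, truth_effect, template, NoiseModel(sigma=0.1), seed=10
        )
        fit = two_step_fit(ds)
        res = bootstrap_ci(ds, fit, n_boot=25, seed=3)  # auto -> residual
        assert res.bootstrap_samples is not None
        assert np.isfinite(res.bootstrap_samples).sum() > 0

    def test_rejects_tiny_n_boot(self, noiseless_dataset):
        fit = two_step_fit(noiseless_dataset)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(noiseless_dataset, fit, n_boot=1, seed=0)
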