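"""The PM2.5-stroke example model and its input-uncertainty sampler."""

import numpy as np
import pandas as pd
import pytest

import voikit as vk
from voikit.impact_model import D_COLS


class TestScenarioConcentration:
    def test_worked_value(self):
        assert vk.scenario_concentration(20.0, 0.4, 0.5) == pytest.approx(16.0)

    def test_identity_cases(self):
        assert vk.scenario_concentration(12.3, 0.4, 1.0) == pytest.approx(12.3)
        assert vk.scenario_concentration(12.3, 0.0, 0.5) == pytest.approx(12.3)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            vk.scenario_concentration(-1.0, 0.4, 0.5)
        with pytest.raises(ValueError):
            vk.scenario_concentration(10.0, 1.4, 0.5)


class TestDoseResponse:
    def test_below_threshold_is_null(self):
        d = vk.DoseResponseParams(1.0, 0.1, 1.0, 5.0)
        assert vk.dose_response(3.0, d) == 1.0
        assert vk.dose_response(0.0, d) == 1.0

    def test_flat_curve(self):
        d = vk.DoseResponseParams(0.0, 0.1, 1.0, 5.0)
        assert np.all(vk.dose_response(np.linspace(0, 40, 9), d) == 1.0)

    def test_worked_value(self):
        d = vk.DoseResponseParams(1.0, 0.1, 1.0, 5.0)
        assert vk.dose_response(15.0, d) == pytest.approx(1 + (1 - np.exp(-1.0)))

    def test_bounds(self):
        d = vk.DoseResponseParams(0.7, 0.05, 1.3, 4.0)
        rr = vk.dose_response(np.linspace(0, 200, 101), d)
        assert np.all((rr >= 1.0) & (rr <= 1.7))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            vk.DoseResponseParams(-0.1, 0.1, 1.0, 5.0)


class TestCasesAverted:
    def setup_method(self):
        self.cfg = vk.HealthModelConfig()

    def test_no_change_scenario(self):
        cfg = vk.HealthModelConfig(D=1.0)
        d = vk.DoseResponseParams(1.0, 0.1, 1.0, 5.0)
        assert vk.cases_averted(20.0, 0.4, d, cfg) == pytest.approx(0.0)

    def test_risk_ratio_arithmetic(self):
        # RR ratio 0.9 at I0=1000 -> 100 cases averted; build via a curve
        # hitting those relative risks exactly is unnecessary: check formula
        cfg = vk.HealthModelConfig(I0=1000.0)
        d = vk.DoseResponseParams(1.0, 0.1, 1.0, 5.0)
        expected = 1000.0 * (1 - vk.dose_response(16.0, d) / vk.dose_response(20.0, d))
        assert vk.cases_averted(20.0, 0.4, d, cfg) == pytest.approx(expected)

    def test_bounded_by_baseline_incidence(self, example_run):
        _, _, y_est, _ = example_run
        assert (y_est.y <= vk.HealthModelConfig().I0).all()


class TestSampleInputs:
    def test_marginal_moments(self, example_run):
        _, inputs, _, _ = example_run
        v = inputs.values
        # Beta(5.7, 8.9) mean = 5.7/14.6 = 0.39
        assert v["pi"].mean() == pytest.approx(5.7 / 14.6, abs=0.01)
        # log-normal(2.7, 0.3) credible limits exp(2.7 -/+ 1.96*0.3)
        lo, hi = np.quantile(v["mu"], [0.025, 0.975])
        assert lo == pytest.approx(np.exp(2.7 - 1.96 * 0.3), rel=0.05)
        assert hi == pytest.approx(np.exp(2.7 + 1.96 * 0.3), rel=0.05)

    def test_reproducible_under_seed(self):
        cfg = vk.HealthModelConfig()
        a = vk.sample_inputs(cfg, 50, seed=9).values
        b = vk.sample_inputs(cfg, 50, seed=9).values
        pd.testing.assert_frame_equal(a, b)


class TestGenerateDrSample:
    def test_collapses_without_noise(self):
        table = vk.default_dr_table(se_log_rr=1e-9)
        d = vk.generate_dr_sample(table, 30, seed=1)
        assert d.std().max() < 1e-3

    def test_parameter_recovery(self):
        d_star = vk.DoseResponseParams(0.6, 0.06, 1.2, 4.0)
        table = vk.default_dr_table(d_star=d_star, se_log_rr=0.02)
        d = vk.generate_dr_sample(table, 200, seed=3)
        medians = d.median()
        for name, truth in zip(D_COLS, d_star.as_array()):
            assert abs(medians[name] - truth) / truth < 0.10

    def test_fitted_curves_respect_bounds(self):
        d = vk.generate_dr_sample(vk.default_dr_table(), 100, seed=5)
        x = np.linspace(0, 40, 41)
        for _, row in d.head(20).iterrows():
            rr = vk.dose_response(x, vk.DoseResponseParams(*row[D_COLS]))
            assert np.all(rr >= 1.0) and np.all(rr <= 1.0 + row["alpha"] + 1e-9)

    def test_rejects_degenerate_tables(self):
        with pytest.raises(ValueError, match="at least 5"):
            vk.generate_dr_sample(vk.default_dr_table().head(3), 10)
        decreasing = vk.default_dr_table().iloc[::-1].reset_index(drop=True)
        decreasing["x"] = sorted(decreasing["x"])
        with pytest.raises(ValueError, match="increasing"):
            vk.generate_dr_sample(decreasing, 10)


class TestStrengthExtremes:
    def test_flat_curves_warn_and_match(self):
        d = pd.DataFrame({"alpha": np.zeros(200), "beta": np.full(200, 0.1),
                          "gamma": np.ones(200), "tau": np.full(200, 4.0)})
        with pytest.warns(UserWarning, match="identical pair"):
            lo, hi = vk.strength_extremes(d)
        assert lo.as_array() == pytest.approx(hi.as_array())

    def test_strength_ratio_below_one(self, example_run):
        _, inputs, _, _ = example_run
        d = inputs.values[D_COLS]
        arr = tuple(d[c].to_numpy() for c in D_COLS)
        rho = vk.dose_response(10.0, arr) / vk.dose_response(15.0, arr)
        assert np.all(rho <= 1.0 + 1e-12)

    def test_matches_sort_oracle(self, rng):
        r = 1000
        d = pd.DataFrame({
            "alpha": rng.uniform(0.2, 1.5, r), "beta": rng.uniform(0.01, 0.2, r),
            "gamma": rng.uniform(0.8, 1.6, r), "tau": rng.uniform(0, 4.9, r)})
        lo, hi = vk.strength_extremes(d)
        arr = tuple(d[c].to_numpy() for c in D_COLS)
        rho = vk.dose_response(10.0, arr) / vk.dose_response(15.0, arr)
        order = np.argsort(rho, kind="stable")
        assert lo.as_array() == pytest.approx(d.iloc[order[24]][D_COLS].to_numpy())
        assert hi.as_array() == pytest.approx(d.iloc[order[974]][D_COLS].to_numpy())

    def test_needs_enough_draws(self):
        d = pd.DataFrame({c: np.ones(50) for c in D_COLS})
        with pytest.raises(ValueError, match="100"):
            vk.strength_extremes(d)


class TestRunExample:
    def test_output_composition(self, example_run):
        cfg, inputs, y_est, nb = example_run
        v = inputs.values
        d = tuple(v[c].to_numpy() for c in D_COLS)
        direct = vk.cases_averted(v["mu"].to_numpy(), v["pi"].to_numpy(), d, cfg)
        assert np.allclose(direct, y_est.y)
        # decision net benefits are the estimation outputs shifted by k
        assert np.allclose(nb.values["policy"] + cfg.k, y_est.y)
        assert (nb.values["status_quo"] == 0).all()

    def test_seeded_reproducibility(self):
        a = vk.run_example(R=40, seed=13, mode="decision")
        b = vk.run_example(R=40, seed=13, mode="decision")
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)

    def test_mc_mean_differs_from_plug_in(self, example_run):
        # the model is nonlinear: f(E(theta)) is a biased estimate of E(f(theta))
        cfg, inputs, y_est, _ = example_run
        v = inputs.values
        med = {"mu": float(np.exp(cfg.mu_meanlog)),
               "pi": float(np.median(v["pi"]))}
        d_med = tuple(np.array([v[c].median()]) for c in D_COLS)
        plug_in = vk.cases_averted(np.array([med["mu"]]), np.array([med["pi"]]),
                                   d_med, cfg)[0]
        mc_mean = y_est.y.mean()
        assert abs(mc_mean - plug_in) / mc_mean > 0.05
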