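"""EVPPI/EVSI estimators against closed forms, limits and invariants."""

import numpy as np
import pandas as pd
import pytest

import voikit as vk


def _draws(dict_of_cols):
    return vk.ParameterDraws(pd.DataFrame(dict_of_cols))


def _boot_se_group_var(t, y, n_boot=200, seed=0):
    """Bootstrap SE of var(E[y | t]) for a discrete summary t."""
    rng = np.random.default_rng(seed)
    vals = []
    frame = pd.DataFrame({"t": t, "y": y})
    for _ in range(n_boot):
        b = frame.sample(frac=1.0, replace=True, random_state=rng.integers(2**31))
        vals.append(b.groupby("t")["y"].transform("mean").var(ddof=1))
    return float(np.std(vals, ddof=1))


@pytest.fixture(scope="module")
def linear_gaussian():
    """Y = theta1 + theta2, theta_i iid N(0,1): EVPPI(theta1) = 1."""
    rng = np.random.default_rng(42)
    t1 = rng.standard_normal(10_000)
    t2 = rng.standard_normal(10_000)
    inputs = _draws({"t1": t1, "t2": t2, "noise_par": rng.standard_normal(10_000)})
    y = vk.OutputDraws("estimation", t1 + t2)
    return inputs, y


class TestEvppiEstimation:
    def test_linear_gaussian_closed_form(self, linear_gaussian):
        inputs, y = linear_gaussian
        est = vk.evppi_estimation(y, inputs, ["t1"])
        assert est.value == pytest.approx(1.0, abs=0.05)

    def test_all_parameters_of_deterministic_model(self, linear_gaussian):
        inputs, y = linear_gaussian
        est = vk.evppi_estimation(y, inputs, ["t1", "t2"])
        var_y = np.var(y.y, ddof=1)
        assert est.value == pytest.approx(var_y, rel=0.03)

    def test_irrelevant_parameter(self, linear_gaussian):
        inputs, y = linear_gaussian
        est = vk.evppi_estimation(y, inputs, ["noise_par"])
        assert est.value < 0.02 * np.var(y.y)

    def test_estimator_pair_agrees(self, linear_gaussian):
        # (a) var(fitted) vs (b) var(y) - resid_var: law of total variance
        inputs, y = linear_gaussian
        meta = vk.evppi_estimation(y, inputs, ["t1"]).meta
        a, b = meta["estimator_a_var_fitted"], meta["estimator_b_var_minus_resid"]
        assert abs(a - b) / meta["var_y"] < 0.02

    def test_bounded_by_var_y(self, linear_gaussian):
        inputs, y = linear_gaussian
        for pars in (["t1"], ["t1", "t2"], ["noise_par"]):
            v = vk.evppi_estimation(y, inputs, pars).value
            assert 0.0 <= v <= np.var(y.y, ddof=1)


class TestEvppiDecision:
    def test_gaussian_closed_form(self, rng):
        # NB2 = theta ~ N(0,1) vs NB1 = 0: EVPPI(theta) = EVPI = 1/sqrt(2 pi)
        theta = rng.standard_normal(100_000)
        nb = vk.OutputDraws("decision", pd.DataFrame(
            {"a1": np.zeros(theta.size), "a2": theta}))
        est = vk.evppi_decision(nb, _draws({"theta": theta}), ["theta"])
        truth = 1.0 / np.sqrt(2 * np.pi)
        assert abs(est.value - truth) < 3 * est.mc_se + 0.01

    def test_irrelevant_parameter_and_full_information(self, rng):
        t1 = rng.standard_normal(10_000)
        t2 = rng.standard_normal(10_000)
        junk = rng.standard_normal(10_000)
        nb = vk.OutputDraws("decision", pd.DataFrame(
            {"a1": np.zeros(10_000), "a2": t1 + t2}))
        inputs = _draws({"t1": t1, "t2": t2, "junk": junk})
        evpi = vk.evpi_decision(nb).value
        none = vk.evppi_decision(nb, inputs, ["junk"]).value
        full = vk.evppi_decision(nb, inputs, ["t1", "t2"]).value
        assert none < 0.05 * evpi
        assert full == pytest.approx(evpi, rel=0.05)
        assert 0.0 <= none <= full <= evpi * 1.01

    def test_method_dispatch_by_dimension(self, rng):
        r = 2000
        cols = {f"p{i}": rng.standard_normal(r) for i in range(6)}
        nb = vk.OutputDraws("decision", pd.DataFrame(
            {"a1": np.zeros(r), "a2": cols["p0"] + cols["p1"]}))
        inputs = _draws(cols)
        est = vk.evppi_decision(nb, inputs, list(cols))
        assert est.meta["method"] == "adaptive_splines"
        with pytest.raises(ValueError, match="not supported"):
            vk.evppi_decision(nb, _draws(
                {f"q{i}": rng.standard_normal(r) for i in range(16)}),
                [f"q{i}" for i in range(16)])


class TestEvsiEstimation:
    """Beta-binomial family: Y = pi ~ Beta(a, b), binary study of size n.

    Closed form: EVSI(n) = V0 * n / (a + b + n) with V0 = var(pi).
    """

    @staticmethod
    @pytest.fixture(scope="class")
    def beta_problem():
        rng = np.random.default_rng(17)
        pi = rng.beta(1, 1, 10_000)
        inputs = _draws({"pi": pi})
        y = vk.OutputDraws("estimation", pi)
        return inputs, y, pi

    def test_closed_form_across_sizes(self, beta_problem):
        inputs, y, pi = beta_problem
        design = vk.binary_design("pi")
        ns = [2, 10, 50]
        ests = vk.evsi_estimation(y, inputs, design, ns, seed=5)
        v0 = 1.0 / 12.0
        for n, est in zip(ns, ests):
            truth = v0 * n / (2 + n)
            t = np.random.default_rng([5, ns.index(n)])  # reproduce the sim seed
            z = t.binomial(n, pi)
            se = _boot_se_group_var(z, pi)
            assert abs(est.value - truth) < 3 * se + 0.002

    def test_zero_sample_size_and_monotonicity(self, beta_problem):
        inputs, y, pi = beta_problem
        design = vk.binary_design("pi")
        ests = vk.evsi_estimation(y, inputs, design, [0, 10, 100], seed=2)
        vals = [e.value for e in ests]
        assert vals[0] == 0.0
        assert vals[1] <= vals[2] + 0.003  # nondecreasing within MC error

    def test_large_n_approaches_evppi(self, beta_problem):
        inputs, y, pi = beta_problem
        evppi = vk.evppi_estimation(y, inputs, ["pi"]).value
        est = vk.evsi_estimation(y, inputs, vk.binary_design("pi"), [10_000],
                                 seed=9)[0]
        assert est.value == pytest.approx(evppi, rel=0.05)
        assert est.value <= evppi * 1.02


class TestEvsiDecision:
    @staticmethod
    @pytest.fixture(scope="class")
    def beta_decision():
        rng = np.random.default_rng(23)
        pi = rng.beta(1, 1, 10_000)
        nb = vk.OutputDraws("decision", pd.DataFrame(
            {"status_quo": np.zeros(pi.size), "policy": pi - 0.5}))
        return _draws({"pi": pi}), nb, pi

    def test_zero_and_monotone(self, beta_decision):
        inputs, nb, _ = beta_decision
        ests = vk.evsi_decision(nb, inputs, vk.binary_design("pi"),
                                [0, 10, 100], seed=4)
        assert ests[0].value == 0.0
        assert ests[1].value <= ests[2].value + 0.005

    def test_large_n_approaches_evppi(self, beta_decision):
        inputs, nb, pi = beta_decision
        evppi = vk.evppi_decision(nb, inputs, ["pi"]).value
        est = vk.evsi_decision(nb, inputs, vk.binary_design("pi"), [10_000],
                               seed=6)[0]
        # truth: E[max(0, pi - 0.5)] = 1/8 for pi ~ U(0,1)
        assert evppi == pytest.approx(1 / 8, abs=0.01)
        assert est.value == pytest.approx(evppi, abs=0.01)


class TestEnbs:
    def test_arithmetic(self):
        assert vk.enbs(vk.VoIEstimate("EVSI", 10.0), 4.0).value == 6.0
        assert vk.enbs(vk.VoIEstimate("EVSI", 10.0), 10.0).value == 0.0

    def test_grid_with_linear_cost_and_argmax(self):
        # diminishing-returns EVSI vs linear cost: interior optimum
        ns = [10, 50, 100, 500]
        evsi = [vk.VoIEstimate("EVSI", 100 * n / (50 + n), meta={"n": n})
                for n in ns]
        res = vk.enbs(evsi, lambda n: 0.1 * n)
        expect = [100 * n / (50 + n) - 0.1 * n for n in ns]
        assert [r.value for r in res] == pytest.approx(expect)
        n_best, v_best = vk.optimal_sample_size(res)
        assert n_best == ns[int(np.argmax(expect))]
        assert v_best == pytest.approx(max(expect))


class TestPresentation:
    @pytest.mark.parametrize("var_y,evppi,expected", [
        (100.0, 0.0, 10.0), (100.0, 100.0, 0.0), (100.0, 36.0, 8.0)])
    def test_sd_remaining(self, var_y, evppi, expected):
        assert vk.sd_remaining(var_y, evppi) == expected

    def test_sd_remaining_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert vk.sd_remaining(1.0, 1.5) == 0.0

    @pytest.mark.parametrize("var_y,evppi,expected", [
        (4.0, 1.0, 0.25), (4.0, 0.0, 0.0), (4.0, 4.0, 1.0), (4.0, 5.0, 1.0)])
    def test_proportion_explained(self, var_y, evppi, expected):
        assert vk.proportion_explained(var_y, evppi) == expected
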