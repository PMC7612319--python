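"""EVPPI and EVSI by nonparametric regression; ENBS and presentation helpers.

EVPPI for a parameter subset phi is the expected gain from learning phi
exactly. For estimation problems it is the expected reduction in variance,

    EVPPI_phi = var(Y) - E_phi[ var_{Y|phi}(Y) ] = var_phi[ E_{Y|phi}(Y) ]

estimated (a) as the empirical variance of the fitted values of a flexible
regression of y on phi, or (b) as var(y) minus the residual variance of
that regression; the two agree under the law of total variance and their
discrepancy is a useful diagnostic. For decision problems each action's
net benefit is regressed on phi and

    EVPPI_phi = mean_r[ max_a fitted_a^(r) ] - max_a[ mean_r NB_a^(r) ].

EVSI replaces phi with a summary statistic T(Z^(r)) of data simulated from
the sampling distribution of a proposed study given each parameter draw:
the same regressions, with T(Z) as the predictor, price a *finite* study
rather than perfect information.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import OutputDraws, ParameterDraws, VoIEstimate, _current_best
from .designs import StudyDesign, simulate_summaries
from .regression import fit_flexible_mean

__all__ = [
    "evppi_estimation", "evppi_decision", "evsi_estimation", "evsi_decision",
    "enbs", "optimal_sample_size", "sd_remaining", "proportion_explained",
]

_MAX_JOINT = 15


def default_method(p: int) -> str:
    """Spline GAM up to 4 joint parameters, adaptive splines up to 15."""
    if p <= 4:
        return "spline_gam"
    if p <= _MAX_JOINT:
        return "adaptive_splines"
    raise ValueError(
        f"joint EVPPI for {p} parameters is not supported (limit {_MAX_JOINT}); "
        "nonparametric regression is unreliable at this dimension"
    )


def _resolve_pars(inputs: ParameterDraws, pars) -> pd.DataFrame:
    if isinstance(pars, str):
        pars = [pars]
    return inputs.subset(list(pars))


def _var_se(v: np.ndarray) -> float:
    """Large-sample SE of the sample variance of v (approximate)."""
    c = v - v.mean()
    m2 = float(np.mean(c**2))
    m4 = float(np.mean(c**4))
    return float(np.sqrt(max(m4 - m2**2, 0.0) / v.size))


def _estimation_value(y: np.ndarray, x: np.ndarray, method, options) -> VoIEstimate:
    var_y = float(np.var(y, ddof=1))
    fit = fit_flexible_mean(x, y, method=method, **options)
    est_a = fit.var_fitted
    est_b = var_y - fit.resid_var
    raw = est_a
    value = min(max(raw, 0.0), var_y)
    meta = {
        "method": fit.method,
        "estimator_a_var_fitted": est_a,
        "estimator_b_var_minus_resid": est_b,
        "estimator_discrepancy": est_a - est_b,
        "var_y": var_y,
        "diagnostics": fit.diagnostics,
    }
    if value != raw:
        meta["raw_value"] = raw
        meta["clipped"] = True
    return VoIEstimate("EVPPI", value, _var_se(fit.fitted), meta)


def _decision_value(nb: np.ndarray, x: np.ndarray, method, options) -> VoIEstimate:
    col_means = nb.mean(axis=0)
    a_star = _current_best(col_means)
    fits = [fit_flexible_mean(x, nb[:, a], method=method, **options)
            for a in range(nb.shape[1])]
    fitted = np.column_stack([f.fitted for f in fits])
    perfect = fitted.max(axis=1)
    value = float(perfect.mean()) - float(col_means[a_star])
    # SE of the mean of the per-draw regression-based opportunity benefit;
    # ignores emulator uncertainty (documented as approximate)
    ob = perfect - fitted[:, a_star]
    mc_se = float(ob.std(ddof=1) / np.sqrt(ob.size))
    meta = {
        "method": fits[0].method,
        "current_best_action": int(a_star),
        "diagnostics": [f.diagnostics for f in fits],
    }
    return VoIEstimate("EVPPI", value, mc_se, meta)


def evppi_estimation(
    y: OutputDraws,
    inputs: ParameterDraws,
    pars,
    method: str | None = None,
    **options,
) -> VoIEstimate:
    """EVPPI for an estimation problem: expected variance reduction from
    learning the parameters ``pars`` exactly.

    The primary estimate is the variance of the fitted regression values
    (estimator (a)); estimator (b) = var(y) - residual variance and their
    discrepancy are reported in ``meta``. The value is clipped to
    [0, var(y)].
    """
    if y.kind != "estimation":
        raise ValueError("evppi_estimation requires estimation outputs")
    y.check_aligned(inputs)
    x = _resolve_pars(inputs, pars)
    m = method or default_method(x.shape[1])
    est = _estimation_value(y.y, x.to_numpy(), m, options)
    est.meta["pars"] = list(x.columns)
    return est


def evppi_decision(
    nb: OutputDraws,
    inputs: ParameterDraws,
    pars,
    method: str | None = None,
    **options,
) -> VoIEstimate:
    """EVPPI for a decision problem: one emulator per action's net benefit."""
    if nb.kind != "decision":
        raise ValueError("evppi_decision requires decision outputs")
    nb.check_aligned(inputs)
    x = _resolve_pars(inputs, pars)
    m = method or default_method(x.shape[1])
    est = _decision_value(nb.values.to_numpy(dtype=float), x.to_numpy(), m, options)
    est.meta["pars"] = list(x.columns)
    return est


def _evsi_impl(outputs: OutputDraws, inputs: ParameterDraws, design: StudyDesign,
               n_values, seed: int, method, options) -> list[VoIEstimate]:
    outputs.check_aligned(inputs)
    n_values = [int(n) for n in n_values]
    if any(n < 0 for n in n_values):
        raise ValueError("study sample sizes must be non-negative")
    design.validate(inputs)
    results = []
    for i, n in enumerate(n_values):
        if n == 0:
            results.append(VoIEstimate("EVSI", 0.0, 0.0,
                                       meta={"n": 0, "design": design.name}))
            continue
        rng = np.random.default_rng([seed, i])
        t = simulate_summaries(design, inputs, n, rng)
        m = method or default_method(t.shape[1])
        if outputs.kind == "estimation":
            est = _estimation_value(outputs.y, t, m, options)
        else:
            est = _decision_value(outputs.values.to_numpy(dtype=float), t, m, options)
        est.measure = "EVSI"
        est.meta.update({"n": n, "design": design.name, "seed": seed})
        results.append(est)
    return results


def evsi_estimation(y: OutputDraws, inputs: ParameterDraws, design: StudyDesign,
                    n_values, seed: int = 0, method: str | None = None,
                    **options) -> list[VoIEstimate]:
    """EVSI for an estimation problem at each proposed sample size.

    For each n, data Z^(r) are simulated from the study's sampling
    distribution given each parameter draw, summarised as T(Z^(r)), and
    y is regressed on T; the variance of the fitted values estimates the
    expected variance reduction from running the study.
    """
    if y.kind != "estimation":
        raise ValueError("evsi_estimation requires estimation outputs")
    return _evsi_impl(y, inputs, design, n_values, seed, method, options)


def evsi_decision(nb: OutputDraws, inputs: ParameterDraws, design: StudyDesign,
                  n_values, seed: int = 0, method: str | None = None,
                  **options) -> list[VoIEstimate]:
    """EVSI for a decision problem at each proposed sample size."""
    if nb.kind != "decision":
        raise ValueError("evsi_decision requires decision outputs")
    return _evsi_impl(nb, inputs, design, n_values, seed, method, options)


def enbs(evsi, cost):
    """Expected net benefit of sampling: EVSI minus the cost of the study.

    Accepts a single ``VoIEstimate`` with a scalar cost, or a list of
    per-n estimates with a matching list of costs (or a callable n -> cost).
    ENBS may be negative: a study that costs more than its expected value.
    """
    if isinstance(evsi, VoIEstimate):
        value = evsi.value - float(cost)
        return VoIEstimate("ENBS", value, evsi.mc_se,
                           meta={**evsi.meta, "cost": float(cost)})
    evsi = list(evsi)
    if callable(cost):
        costs = [float(cost(e.meta.get("n"))) for e in evsi]
    elif np.isscalar(cost):
        costs = [float(cost)] * len(evsi)
    else:
        costs = [float(c) for c in cost]
        if len(costs) != len(evsi):
            raise ValueError("need one cost per EVSI estimate")
    return [enbs(e, c) for e, c in zip(evsi, costs)]


def optimal_sample_size(enbs_results) -> tuple[int | None, float]:
    """The study size with the greatest expected net benefit of sampling."""
    best = max(enbs_results, key=lambda e: e.value)
    return best.meta.get("n"), best.value


def sd_remaining(var_y: float, evppi_value: float) -> float:
    """sqrt(var(Y) - EVPPI_phi): an estimate of the output SD that would
    remain after learning phi.

    This plug-in quantity is not quite the same as the expectation of the
    remaining SD (the square root is taken after averaging the variance).
    """
    if evppi_value < 0 or var_y < 0:
        raise ValueError("variance and EVPPI must be non-negative")
    if evppi_value > var_y:
        warnings.warn(
            f"EVPPI {evppi_value} exceeds var(Y) {var_y}; clipping", stacklevel=2
        )
        evppi_value = var_y
    return float(np.sqrt(var_y - evppi_value))


def proportion_explained(var_y: float, evppi_value: float) -> float:
    """EVPPI_phi / var(Y): the proportion of output variance removable by
    learning phi, clipped to [0, 1]."""
    if var_y <= 0:
        raise ValueError("var(Y) must be positive")
    return float(np.clip(evppi_value / var_y, 0.0, 1.0))
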