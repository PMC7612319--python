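"""One-way tornado sensitivity analysis, non-probabilistic and probabilistic.

Each row of a tornado contrasts the model output with one parameter (or
jointly-varied parameter group) set to its lower and upper 95% credible
limits. In the non-probabilistic version the remaining parameters are
fixed at point estimates (medians); in the probabilistic version the
output is averaged over the Monte Carlo draws of the remaining
parameters, E(f(theta) | varied = limit), which requires the varied
parameter to be independent of the rest.

For a nonlinear model the two versions give different base cases:
f evaluated at the parameter medians is a biased estimate of E(f(theta)),
which the probabilistic base case estimates by the Monte Carlo mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import lognorm

from .core import ParameterDraws
from .impact_model import (
    D_COLS,
    HealthModelConfig,
    StrengthSpec,
    cases_averted,
    sample_inputs,
    strength_extremes,
)

__all__ = ["TornadoRow", "tornado_fixed", "tornado_probabilistic", "example_tornado"]


@dataclass
class TornadoRow:
    """One sensitivity contrast: a parameter (group) at its low/high limits."""

    parameter: str
    low_value: object
    high_value: object
    out_low: float
    out_high: float

    @property
    def span(self) -> float:
        return abs(self.out_high - self.out_low)


def _rows_to_frame(rows: list[TornadoRow], base: dict) -> pd.DataFrame:
    rows = sorted(rows, key=lambda r: -r.span)
    frame = pd.DataFrame([{
        "parameter": r.parameter,
        "low_value": str(r.low_value),
        "high_value": str(r.high_value),
        "out_low": r.out_low,
        "out_high": r.out_high,
        "span": r.span,
    } for r in rows])
    for k, v in base.items():
        frame.attrs[k] = v
    return frame


def tornado_fixed(model: Callable[[dict], float], medians: dict,
                  groups: dict[str, dict]) -> tuple[list[TornadoRow], float]:
    """Non-probabilistic tornado.

    ``model`` maps a {parameter: value} dict to a scalar output;
    ``medians`` holds the point estimate of every parameter; ``groups``
    maps a row label to {parameter: (low, high)} clamp values (several
    parameters per label are clamped jointly). Returns the rows and the
    all-medians base case.
    """
    base = float(model(dict(medians)))
    rows = []
    for label, clamps in groups.items():
        if len(clamps) == 1:  # joint group rows are two whole settings, not limits
            ((name, (lo, hi)),) = clamps.items()
            if not lo < hi:
                raise ValueError(f"{label}/{name}: low limit must be below high")
        out = []
        for which in (0, 1):
            setting = dict(medians)
            setting.update({name: lims[which] for name, lims in clamps.items()})
            out.append(float(model(setting)))
        lows = {n: lims[0] for n, lims in clamps.items()}
        highs = {n: lims[1] for n, lims in clamps.items()}
        rows.append(TornadoRow(label, lows, highs, out[0], out[1]))
    return sorted(rows, key=lambda r: -r.span), base


def tornado_probabilistic(model: Callable[[pd.DataFrame], np.ndarray],
                          draws: ParameterDraws,
                          groups: dict[str, dict],
                          interval: tuple[float, float] = (0.025, 0.975),
                          corr_limit: float = 0.9,
                          ) -> tuple[list[TornadoRow], dict]:
    """Probabilistic tornado: clamp each varied group, marginalise the rest
    over their Monte Carlo draws.

    ``model`` maps a draw table to a vector of outputs. Refuses to run if
    any clamped column is correlated (|r| > ``corr_limit``) with a column
    outside its group, since E(f | varied = limit) is then not estimable
    by simply substituting the clamp into the joint sample.

    Returns the rows and the base case: the Monte Carlo mean of the output
    with a 95% interval.
    """
    table = draws.values
    y0 = np.asarray(model(table), dtype=float)
    base = {
        "mean": float(y0.mean()),
        "lower": float(np.quantile(y0, interval[0])),
        "upper": float(np.quantile(y0, interval[1])),
    }
    corr = table.corr().abs()
    rows = []
    for label, clamps in groups.items():
        inside = set(clamps)
        outside = [c for c in table.columns if c not in inside]
        for name in clamps:
            bad = [o for o in outside if corr.loc[name, o] > corr_limit]
            if bad:
                raise ValueError(
                    f"cannot clamp {name!r}: it is correlated with {bad} "
                    f"(|r| > {corr_limit}); the probabilistic tornado assumes "
                    "the varied parameter is independent of the remainder"
                )
        out = []
        for which in (0, 1):
            clamped = table.copy()
            for name, lims in clamps.items():
                clamped[name] = lims[which]
            out.append(float(np.mean(model(clamped))))
        lows = {n: lims[0] for n, lims in clamps.items()}
        highs = {n: lims[1] for n, lims in clamps.items()}
        rows.append(TornadoRow(label, lows, highs, out[0], out[1]))
    return sorted(rows, key=lambda r: -r.span), base


def _example_groups(config: HealthModelConfig, d_draws: pd.DataFrame,
                    probs=(0.025, 0.975)) -> tuple[dict, dict]:
    """Clamp specs and medians for the example model's three tornado rows."""
    pi_rv = beta_dist(config.pi_alpha, config.pi_beta)
    mu_rv = lognorm(s=config.mu_sdlog, scale=np.exp(config.mu_meanlog))
    d_lo, d_hi = strength_extremes(d_draws, StrengthSpec(probs=probs))
    groups = {
        "transport_share": {"pi": (pi_rv.ppf(probs[0]), pi_rv.ppf(probs[1]))},
        "background_pm25": {"mu": (mu_rv.ppf(probs[0]), mu_rv.ppf(probs[1]))},
        "dose_response": {c: (getattr(d_lo, c), getattr(d_hi, c)) for c in D_COLS},
    }
    medians = {"pi": pi_rv.ppf(0.5), "mu": mu_rv.ppf(0.5),
               **{c: float(d_draws[c].median()) for c in D_COLS}}
    return groups, medians


def example_tornado(config: HealthModelConfig | None = None, R: int = 5000,
                    seed: int = 0, probabilistic: bool = True,
                    draws: ParameterDraws | None = None):
    """Tornado analysis of the PM2.5-stroke example model.

    Rows: transport share pi at its 95% credible limits; background PM2.5
    mu at its limits; and the dose-response curve varied jointly between
    its "weak" and "strong" extreme sampled curves (ranked by the
    relative-risk strength ratio), since the curve parameters are highly
    correlated and any new dose-response data would inform all four.
    """
    config = config or HealthModelConfig()
    if draws is None:
        draws = sample_inputs(config, R, seed)
    d_draws = draws.values[D_COLS]
    groups, medians = _example_groups(config, d_draws)

    def model_vec(table: pd.DataFrame) -> np.ndarray:
        d = tuple(np.asarray(table[c], dtype=float) for c in D_COLS)
        return cases_averted(np.asarray(table["mu"], dtype=float),
                             np.asarray(table["pi"], dtype=float), d, config)

    if probabilistic:
        rows, base = tornado_probabilistic(model_vec, draws, groups)
        return _rows_to_frame(rows, base)

    def model_point(setting: dict) -> float:
        d = tuple(np.array([setting[c]]) for c in D_COLS)
        return float(cases_averted(np.array([setting["mu"]]),
                                   np.array([setting["pi"]]), d, config)[0])

    rows, base = tornado_fixed(model_point, medians, groups)
    return _rows_to_frame(rows, {"point_estimate": base})
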