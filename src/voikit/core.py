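"""Draw containers, net benefit construction and EVPI.

The fundamental currency of the toolkit is a single Monte Carlo sample:
an R x P table of parameter draws ``theta^(r)`` and, aligned row by row,
either an R-vector of model outputs ``y^(r) = f(theta^(r))`` (estimation
problems) or an R x A table of net benefits ``NB_a(theta^(r))`` (decision
problems). Every value-of-information measure here is a functional of
that sample.

For decision problems the expected value of perfect information is

    EVPI = E_theta[ NB_{a(theta)}(theta) ] - max_a E_theta[ NB_a(theta) ]

i.e. the mean, over simulated "alternate realities", of the opportunity
benefit of switching to the decision that is optimal once theta is known.
For estimation problems under squared-error loss, the optimal "action" is
to report the posterior mean, the expected loss is the variance of Y, and
EVPI = var(Y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ParameterDraws", "OutputDraws", "DecisionSpec", "VoIEstimate",
    "net_benefit", "opportunity_benefit", "evpi_decision", "evpi_estimation",
]


class TieWarning(UserWarning):
    """Emitted when the current decision is resolved by an arbitrary tie-break."""


def _check_table(values: pd.DataFrame, what: str) -> pd.DataFrame:
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(values)
    if values.shape[0] < 2:
        raise ValueError(f"{what}: need at least 2 draws, got {values.shape[0]}")
    if values.isna().any().any():
        raise ValueError(f"{what}: missing values are not allowed")
    if values.columns.duplicated().any():
        dups = values.columns[values.columns.duplicated()].tolist()
        raise ValueError(f"{what}: duplicate column names {dups}")
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        raise ValueError(f"{what}: all columns must be numeric")
    return values


@dataclass
class ParameterDraws:
    """An R x P table of sampled model inputs, one named column per parameter."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = _check_table(self.values, "ParameterDraws")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def subset(self, names: list[str] | str) -> pd.DataFrame:
        """Columns for a parameter subset phi, validated against the table."""
        if isinstance(names, str):
            names = [names]
        if len(names) == 0:
            raise ValueError("parameter subset must be non-empty")
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"parameters not in draw table: {missing}")
        return self.values[names]


@dataclass
class OutputDraws:
    """Sampled model outputs: a vector y (estimation) or NB table (decision)."""

    kind: Literal["estimation", "decision"]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("estimation", "decision"):
            raise ValueError(f"kind must be 'estimation' or 'decision', got {self.kind!r}")
        if isinstance(self.values, (pd.Series, np.ndarray, list)):
            self.values = pd.DataFrame({"y": np.asarray(self.values)})
        self.values = _check_table(self.values, "OutputDraws")
        if self.kind == "estimation" and self.values.shape[1] != 1:
            raise ValueError("estimation outputs must be a single column")
        if self.kind == "decision" and self.values.shape[1] < 2:
            raise ValueError("decision outputs need at least 2 actions")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    @property
    def actions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def y(self) -> np.ndarray:
        """Estimation output vector."""
        if self.kind != "estimation":
            raise ValueError("y is defined for estimation outputs only")
        return self.values.iloc[:, 0].to_numpy()

    def check_aligned(self, inputs: ParameterDraws) -> None:
        if self.n_draws != inputs.n_draws:
            raise ValueError(
                f"outputs have {self.n_draws} draws but inputs have "
                f"{inputs.n_draws}; the tables must share rows"
            )


@dataclass
class DecisionSpec:
    """How per-action health benefits are converted to net benefit.

    Parameters
    ----------
    wtp:
        Willingness-to-pay lambda per unit of health benefit (used by the
        monetary and health forms).
    costs:
        Per-action costs C_a, keyed by action label.
    threshold:
        Decision threshold k for the two-action "policy vs status quo" form,
        where NB_2 = f(theta) - k and NB_1 = 0.
    form:
        "monetary" -> NB_a = wtp * Y_a - C_a;
        "health"   -> NB_a = Y_a - C_a / wtp;
        "threshold"-> NB_2 = Y - k, NB_1 = 0 (single-column effects).
    """

    form: Literal["monetary", "health", "threshold"]
    wtp: float | None = None
    costs: dict[str, float] | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.form in ("monetary", "health"):
            if self.wtp is None or self.costs is None:
                raise ValueError(f"{self.form} form requires wtp and costs")
            if self.threshold is not None:
                raise ValueError("threshold must not be set for wtp/costs forms")
            if self.wtp <= 0:
                raise ValueError(f"willingness-to-pay must be positive, got {self.wtp}")
        elif self.form == "threshold":
            if self.threshold is None:
                raise ValueError("threshold form requires threshold k")
            if self.wtp is not None or self.costs is not None:
                raise ValueError("wtp/costs must not be set for threshold form")


@dataclass
class VoIEstimate:
    """A value-of-information estimate with Monte Carlo standard error.

    ``value`` is in net-benefit units for decision problems and in variance
    units of the output for estimation problems. Negative Monte Carlo
    estimates of EVPI/EVPPI/EVSI are clipped to zero, with the raw value
    retained in ``meta["raw_value"]`` and ``meta["clipped"]`` set.
    """

    measure: Literal["EVPI", "EVPPI", "EVSI", "ENBS"]
    value: float
    mc_se: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.measure != "ENBS" and self.value < 0:
            self.meta.setdefault("raw_value", float(self.value))
            self.meta["clipped"] = True
            self.value = 0.0

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "measure": self.measure,
            "value": float(self.value),
            "mc_se": None if self.mc_se is None else float(self.mc_se),
            "meta": _jsonable(self.meta),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def net_benefit(effects: pd.DataFrame | np.ndarray, spec: DecisionSpec) -> OutputDraws:
    """Build decision net benefits NB_a from per-action benefit draws.

    ``effects`` has one column per action (a single column for the threshold
    form, where the status quo NB_1 = 0 column is added automatically).
    """
    effects = pd.DataFrame(effects)
    if effects.shape[1] < 1:
        raise ValueError("effects must have at least one action column")
    if spec.form == "threshold":
        if effects.shape[1] != 1:
            raise ValueError("threshold form expects a single effects column f(theta)")
        y = effects.iloc[:, 0].to_numpy(dtype=float)
        nb = pd.DataFrame({"status_quo": np.zeros(len(y)), "policy": y - spec.threshold})
        return OutputDraws("decision", nb)
    missing = [a for a in effects.columns if a not in spec.costs]
    if missing:
        raise ValueError(f"missing cost for actions: {missing}")
    nb = {}
    for a in effects.columns:
        ya = effects[a].to_numpy(dtype=float)
        if spec.form == "monetary":
            nb[a] = spec.wtp * ya - spec.costs[a]
        else:  # health
            nb[a] = ya - spec.costs[a] / spec.wtp
    return OutputDraws("decision", pd.DataFrame(nb))


def _current_best(col_means: np.ndarray) -> int:
    """Index of the action optimal under current information; ties -> lowest index."""
    best = int(np.argmax(col_means))
    near = np.flatnonzero(np.isclose(col_means, col_means[best], rtol=0, atol=0))
    if near.size > 1:
        warnings.warn(
            f"tie in expected net benefit among actions {near.tolist()}; "
            f"choosing the lowest index {best}",
            TieWarning,
            stacklevel=3,
        )
    return best


def opportunity_benefit(nb: OutputDraws) -> np.ndarray:
    """Per-draw opportunity benefit NB_{a(theta)}(theta) - NB_{a*}(theta).

    a* is the action with the best column mean (current information) and
    a(theta) the per-row argmax (perfect information). Every entry is >= 0;
    the mean of this vector is the EVPI.
    """
    if nb.kind != "decision":
        raise ValueError("opportunity benefit requires decision outputs")
    values = nb.values.to_numpy(dtype=float)
    a_star = _current_best(values.mean(axis=0))
    return values.max(axis=1) - values[:, a_star]


def evpi_decision(nb: OutputDraws) -> VoIEstimate:
    """EVPI for a decision problem: mean opportunity benefit over draws."""
    ob = opportunity_benefit(nb)
    r = ob.size
    value = float(ob.mean())
    mc_se = float(ob.std(ddof=1) / np.sqrt(r))
    return VoIEstimate("EVPI", value, mc_se, meta={"kind": "decision", "n_draws": r})


def evpi_estimation(y: OutputDraws) -> VoIEstimate:
    """EVPI for an estimation problem: the variance of the output sample.

    Uses the unbiased empirical variance (divisor R-1). The reported mc_se
    is the large-sample standard error of a sample variance,
    sqrt((m4 - m2^2)/R) with central moments m2, m4.
    """
    if y.kind != "estimation":
        raise ValueError("evpi_estimation requires estimation outputs")
    yv = y.y.astype(float)
    r = yv.size
    value = float(np.var(yv, ddof=1))
    c = yv - yv.mean()
    m2 = float(np.mean(c**2))
    m4 = float(np.mean(c**4))
    mc_se = float(np.sqrt(max(m4 - m2**2, 0.0) / r))
    return VoIEstimate("EVPI", value, mc_se, meta={"kind": "estimation", "n_draws": r})
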