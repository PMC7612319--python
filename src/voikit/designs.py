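"""Study-design simulators for EVSI, and the effective-sample-size conversion.

A :class:`StudyDesign` bundles a sampling model for the data Z a proposed
study would produce given the model parameters, together with a summary
statistic T(Z) carrying the information Z provides about the parameters of
interest. EVSI needs only the ability to simulate T(Z^(r)) for each
parameter draw theta^(r).

The effective-sample-size conversion prices *imperfect published
information*: an estimated proportion with mean m and standard error
sigma is approximately as informative as observing a binary outcome in

    n = m (1 - m) / sigma^2 - 1

individuals (the Beta posterior from a vague Beta(0, 0) prior and n
observations has that mean/SD relationship). The value of obtaining such
an estimate is then the EVSI of a binary study with n observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import ParameterDraws

__all__ = ["StudyDesign", "EssSpec", "binary_design", "custom_design",
           "ess_from_se", "simulate_summaries"]


@dataclass
class StudyDesign:
    """A proposed study: sampling model plus summary statistic.

    ``simulate(theta_row, n, rng)`` must be a pure function of its
    arguments returning a scalar or fixed-length vector summary
    T(Z) of data simulated from the study given one parameter draw.
    ``simulate_batch``, if provided, vectorises over the whole draw table
    and returns an (R, k) array.
    """

    name: str
    informs: list[str]
    simulate: Callable[[pd.Series, int, np.random.Generator], np.ndarray]
    simulate_batch: Callable[[pd.DataFrame, int, np.random.Generator], np.ndarray] | None = None
    _extra_check: Callable[[ParameterDraws], None] | None = field(default=None, repr=False)

    def validate(self, inputs: ParameterDraws, n: int = 5) -> None:
        """Probe the contract on 3 draws: determinism under a fixed rng
        state and a constant summary dimension."""
        missing = [p for p in self.informs if p not in inputs.names]
        if missing:
            raise ValueError(f"design informs unknown parameters: {missing}")
        if self._extra_check is not None:
            self._extra_check(inputs)
        probe = inputs.values.head(3)
        dims = set()
        for _, row in probe.iterrows():
            t1 = np.atleast_1d(self.simulate(row, n, np.random.default_rng(12345)))
            t2 = np.atleast_1d(self.simulate(row, n, np.random.default_rng(12345)))
            if not np.array_equal(t1, t2):
                raise ValueError(
                    f"design {self.name!r} is not deterministic given a fixed rng"
                )
            dims.add(t1.shape)
        if len(dims) != 1:
            raise ValueError(
                f"design {self.name!r} returns summaries of varying dimension: {dims}"
            )


def simulate_summaries(design: StudyDesign, inputs: ParameterDraws, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """T(Z^(r)) for every draw, as an (R, k) array."""
    if design.simulate_batch is not None:
        t = np.asarray(design.simulate_batch(inputs.values, n, rng), dtype=float)
    else:
        t = np.vstack([
            np.atleast_1d(design.simulate(row, n, rng)).astype(float)
            for _, row in inputs.values.iterrows()
        ])
    if t.ndim == 1:
        t = t[:, None]
    if t.shape[0] != inputs.n_draws:
        raise ValueError("design produced a summary per-draw count mismatch")
    return t


def binary_design(informs: str) -> StudyDesign:
    """A study observing Z successes out of n for a probability parameter.

    For each draw p^(r) of the named parameter, Z^(r) ~ Binomial(n, p^(r))
    and the summary statistic is T(Z) = Z.
    """

    def _check(inputs: ParameterDraws) -> None:
        p = inputs.subset(informs).to_numpy().ravel()
        if (p < 0).any() or (p > 1).any():
            raise ValueError(
                f"parameter {informs!r} has draws outside [0, 1]; "
                "a binary study requires a probability"
            )

    def simulate(row: pd.Series, n: int, rng: np.random.Generator):
        return np.array([rng.binomial(n, float(row[informs]))])

    def simulate_batch(values: pd.DataFrame, n: int, rng: np.random.Generator):
        return rng.binomial(n, values[informs].to_numpy())[:, None].astype(float)

    return StudyDesign("binary", [informs], simulate, simulate_batch,
                       _extra_check=_check)


def custom_design(name: str, simulate, informs: list[str],
                  simulate_batch=None) -> StudyDesign:
    """Wrap a user simulate-and-summarise function as a StudyDesign.

    The contract (purity given the rng, fixed summary dimension) is
    verified on probe draws the first time the design is used.
    """
    if not callable(simulate):
        raise TypeError("simulate must be callable(theta_row, n, rng)")
    return StudyDesign(name, list(informs), simulate, simulate_batch)


@dataclass
class EssSpec:
    """A published proportion estimate: posterior mean m and standard error."""

    m: float
    se: float

    def __post_init__(self) -> None:
        if not 0.0 < self.m < 1.0:
            raise ValueError(f"estimated proportion must be in (0, 1), got {self.m}")
        if self.se <= 0:
            raise ValueError(f"standard error must be positive, got {self.se}")
        if self.se >= np.sqrt(self.m * (1.0 - self.m)):
            raise ValueError(
                f"se={self.se} >= sqrt(m(1-m))={np.sqrt(self.m*(1-self.m)):.4g}: "
                "no Beta posterior has this mean/SD (implied n < 0)"
            )


def ess_from_se(m: float, se: float) -> int:
    """Effective sample size n = m(1-m)/se^2 - 1 of a proportion estimate.

    Rounds half-to-even to the nearest integer and floors at zero.

    >>> ess_from_se(0.2, 0.1)
    15
    >>> ess_from_se(0.2, 0.01)
    1599
    """
    spec = EssSpec(m, se)
    n = spec.m * (1.0 - spec.m) / spec.se**2 - 1.0
    return int(max(np.rint(n), 0))
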