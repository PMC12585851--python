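"""Torque-squared effort model and cost-rate integration.

The torque-squared effort rate for one stride of duration T is

    E_cost = (1/T) * ∫_0^T  Σ_j a_j τ_j(t)²  dt,

with τ_j the moment at joint j and a_j a dimensionless per-joint cost
coefficient, unity by default. The integrand is convex in the torques, which
is what makes the averaged gait pattern a systematic under-estimate of the
mean per-stride cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from stridecost.preprocess import StrideSeries

__all__ = [
    "TorqueCostParams",
    "TorqueSquaredCost",
    "torque_squared_cost",
    "integrate_cost_rate",
]


@dataclass
class TorqueCostParams:
    """Joint names and per-joint cost coefficients a_j (default all 1)."""

    joint_names: list[str]
    a_j: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.a_j is None:
            self.a_j = np.ones(len(self.joint_names))
        self.a_j = np.asarray(self.a_j, dtype=float)
        if self.a_j.size != len(self.joint_names):
            raise ValueError(
                f"{self.a_j.size} coefficients for {len(self.joint_names)} joints"
            )
        if np.any(self.a_j < 0):
            raise ValueError("cost coefficients a_j must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TorqueCostParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(joint_names=list(cfg["joint_names"]), a_j=cfg.get("a_j"))


def torque_squared_cost(stride: StrideSeries, params: TorqueCostParams) -> float:
    """Time-averaged sum of squared joint moments over one stride (trapezoid
    quadrature on the sampled torques)."""
    T = stride.duration
    t = stride.time
    integrand = np.zeros(stride.n_samples)
    for joint, a in zip(params.joint_names, params.a_j):
        if joint not in stride.channels:
            raise KeyError(f"stride is missing moment channel for joint {joint!r}")
        tau = stride.channel(joint).samples
        integrand += a * tau**2
    return float(np.trapezoid(integrand, t) / T)


class TorqueSquaredCost:
    """Torque-squared effort rate as a pluggable cost model (stride -> scalar).

    With no explicit joint list, every moment-kind channel of the stride is
    used with unit coefficient.
    """

    def __init__(self, params: TorqueCostParams | None = None):
        self.params = params

    def __call__(self, stride: StrideSeries) -> float:
        params = self.params
        if params is None:
            joints = [n for n, ch in stride.channels.items() if ch.kind == "moment"]
            if not joints:
                raise KeyError("stride has no moment channels")
            params = TorqueCostParams(joint_names=joints)
        return torque_squared_cost(stride, params)


def integrate_cost_rate(
    muscle_totals: np.ndarray,
    T: float,
    body_mass: float | None = None,
) -> float:
    """Sum per-muscle total-rate series, trapezoid-integrate over one stride
    and divide by its duration T.

    Parameters
    ----------
    muscle_totals
        Array (n_muscles, n_samples) of total metabolic rates in W, sampled
        uniformly over [0, T].
    body_mass
        If given, the result is divided by it (W kg⁻¹ reporting).
    """
    if isinstance(muscle_totals, np.ndarray):
        totals = np.atleast_2d(muscle_totals.astype(float))
    else:
        rows = [np.asarray(r, dtype=float).ravel() for r in muscle_totals]
        lengths = {r.size for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"muscle series have unequal lengths: {sorted(lengths)}")
        totals = np.vstack(rows)
    summed = totals.sum(axis=0)
    t = np.linspace(0.0, T, summed.size)
    rate = float(np.trapezoid(summed, t) / T)
    if body_mass is not None:
        rate /= body_mass
    return rate
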