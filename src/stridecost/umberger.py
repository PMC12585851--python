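"""Umberger-style muscle energetics: heat-rate decomposition and stride cost.

The total metabolic rate of a muscle is decomposed as

    Ė = Ẇ + ḣ_A + ḣ_m + ḣ_sl

(fiber mechanical work rate, activation heat, maintenance heat,
shortening/lengthening heat). Coefficients follow the 2003 formulation with
the 2010 modifications: activation + maintenance heat at full activation is
``128 f_FT + 25`` W per kg of muscle (f_FT the fast-twitch fraction), split
0.4/0.6 between the length-independent activation part and the maintenance
part which is modulated by the force–length factor for fibers longer than
optimal; the activation dependence enters as A^0.6 for activation/maintenance
and A² for shortening heat, with A = u when excitation exceeds activation and
(u + a)/2 otherwise. Shortening heat coefficients are 100/V̄_max(ST) for
slow-twitch and 153/V̄_max(FT) for fast-twitch fibers (V̄ in optimal lengths
per second, V̄_max(FT) = 2.5 V̄_max(ST)); lengthening heat uses four times
the slow-twitch shortening coefficient scaled by A. Heat rates are multiplied
by the aerobic scale S (1.5 for primarily aerobic activity). The work rate is
the fiber's mechanical power, −F·v, counted for the fiber only.

Muscle-state trajectories (activation, normalized fiber length/velocity,
active force) are *inputs* here; no excitation→activation or tendon dynamics
are solved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from stridecost.effort import integrate_cost_rate
from stridecost.preprocess import StrideSeries

__all__ = [
    "MuscleParams",
    "MuscleState",
    "HeatRates",
    "umberger_heat_rates",
    "umberger_rate_arrays",
    "UmbergerCost",
]

# Gaussian force-length factor width (Thelen-style active curve)
_FL_SHAPE = 0.45
# activation+maintenance heat at full activation, W/kg: 128*f_FT + 25
_H_AM_SLOW = 25.0
_H_AM_FAST_EXTRA = 128.0
_ACTIVATION_EXPONENT_AM = 0.6
_ACTIVATION_EXPONENT_S = 2.0
_ALPHA_SHORT_ST_NUM = 100.0
_ALPHA_SHORT_FT_NUM = 153.0
_LENGTHENING_FACTOR = 4.0
_VMAX_FT_OVER_ST = 2.5


@dataclass
class MuscleParams:
    """Muscle constants for the heat-rate model."""

    muscle_mass: float  # kg
    fast_twitch_fraction: float  # 0..1
    max_shortening_velocity: float = 12.0  # optimal lengths / s, fast fibers
    optimal_fiber_length: float = 0.1  # m
    max_isometric_force: float = 1000.0  # N
    aerobic_scale: float = 1.5
    clamp_total_nonnegative: bool = True
    include_basal: bool = False
    basal_rate_per_kg: float = 1.2  # W/kg, folded into maintenance when enabled

    def __post_init__(self) -> None:
        if self.muscle_mass <= 0:
            raise ValueError("muscle_mass must be > 0")
        if not 0.0 <= self.fast_twitch_fraction <= 1.0:
            raise ValueError("fast_twitch_fraction must be in [0, 1]")
        for name in ("max_shortening_velocity", "optimal_fiber_length",
                     "max_isometric_force", "aerobic_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MuscleParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class MuscleState:
    """Instantaneous muscle state: activation, excitation, normalized fiber
    length and velocity (optimal lengths/s, negative = shortening), active
    fiber force in N."""

    activation: float
    excitation: float
    fiber_length: float
    fiber_velocity: float
    active_force: float = 0.0

    def __post_init__(self) -> None:
        for name in ("activation", "excitation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class HeatRates:
    """The four rate components and their sum, in W.

    ``total`` is the plain sum unless non-negativity clamping was requested.
    """

    w_dot: float
    hA_dot: float
    hM_dot: float
    hSL_dot: float
    total: float


def force_length_factor(fiber_length: np.ndarray | float) -> np.ndarray | float:
    """Gaussian isometric force–length factor, 1 at optimal length."""
    return np.exp(-((np.asarray(fiber_length) - 1.0) ** 2) / _FL_SHAPE)


def umberger_rate_arrays(
    activation: np.ndarray,
    excitation: np.ndarray,
    fiber_length: np.ndarray,
    fiber_velocity: np.ndarray,
    active_force: np.ndarray,
    params: MuscleParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized heat-rate decomposition; returns (Ẇ, ḣ_A, ḣ_m, ḣ_sl, total)
    arrays in W."""
    a = np.asarray(activation, float)
    u = np.asarray(excitation, float)
    l = np.asarray(fiber_length, float)
    v = np.asarray(fiber_velocity, float)
    F = np.asarray(active_force, float)
    for arr, name in ((a, "activation"), (u, "excitation"), (l, "fiber_length"),
                      (v, "fiber_velocity"), (F, "active_force")):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")

    f_ft = params.fast_twitch_fraction
    S = params.aerobic_scale
    A = np.where(u > a, u, 0.5 * (u + a))
    A_am = A**_ACTIVATION_EXPONENT_AM
    A_s = A**_ACTIVATION_EXPONENT_S
    f_iso = force_length_factor(l)
    long_fiber = l > 1.0

    h_am0 = _H_AM_FAST_EXTRA * f_ft + _H_AM_SLOW
    hA = 0.4 * h_am0 * A_am * S
    hM = 0.6 * h_am0 * A_am * S * np.where(long_fiber, f_iso, 1.0)

    v_max_ft = params.max_shortening_velocity
    v_max_st = v_max_ft / _VMAX_FT_OVER_ST
    alpha_st = _ALPHA_SHORT_ST_NUM / v_max_st
    alpha_ft = _ALPHA_SHORT_FT_NUM / v_max_ft
    alpha_len = _LENGTHENING_FACTOR * alpha_st
    shortening = (-v) * (alpha_st * (1.0 - f_ft) + alpha_ft * f_ft) * A_s
    lengthening = v * alpha_len * A
    hSL = np.where(v <= 0.0, shortening, lengthening) * S
    hSL = hSL * np.where(long_fiber, f_iso, 1.0)

    if params.include_basal:
        hM = hM + params.basal_rate_per_kg

    m = params.muscle_mass
    hA = m * hA
    hM = m * hM
    hSL = m * hSL
    w_dot = -F * v * params.optimal_fiber_length
    total = w_dot + hA + hM + hSL
    if params.clamp_total_nonnegative:
        total = np.maximum(total, 0.0)
    return w_dot, hA, hM, hSL, total


def umberger_heat_rates(state: MuscleState, params: MuscleParams) -> HeatRates:
    """Heat-rate decomposition for one muscle state (see module docstring)."""
    w, hA, hM, hSL, total = umberger_rate_arrays(
        state.activation,
        state.excitation,
        state.fiber_length,
        state.fiber_velocity,
        state.active_force,
        params,
    )
    return HeatRates(float(w), float(hA), float(hM), float(hSL), float(total))


# channel-name suffixes of a per-muscle column block in a stride/trial
_MUSCLE_SUFFIXES = ("activation", "fiber_length", "fiber_velocity", "active_force")


class UmbergerCost:
    """Muscle heat-rate effort model as a pluggable cost model.

    Expects per-muscle channel blocks named ``<muscle>_activation``,
    ``<muscle>_fiber_length``, ``<muscle>_fiber_velocity``,
    ``<muscle>_active_force`` (and optionally ``<muscle>_excitation``;
    excitation defaults to activation). The stride cost is the per-muscle
    total rate summed over muscles, integrated over the stride and divided by
    its duration.
    """

    def __init__(
        self,
        params: MuscleParams | dict[str, MuscleParams],
        body_mass: float | None = None,
    ):
        self.params = params
        self.body_mass = body_mass

    def _params_for(self, muscle: str) -> MuscleParams:
        if isinstance(self.params, dict):
            return self.params[muscle]
        return self.params

    @staticmethod
    def muscle_names(channel_names) -> list[str]:
        names = set(channel_names)
        muscles = []
        for n in sorted(names):
            if n.endswith("_activation"):
                stem = n[: -len("_activation")]
                if all(f"{stem}_{sfx}" in names for sfx in _MUSCLE_SUFFIXES):
                    muscles.append(stem)
        return muscles

    def __call__(self, stride: StrideSeries) -> float:
        muscles = self.muscle_names(stride.channels)
        if not muscles:
            raise KeyError("stride has no complete muscle-state channel blocks")
        totals = []
        for m in muscles:
            p = self._params_for(m)
            act = np.clip(stride.channel(f"{m}_activation").samples, 0.0, 1.0)
            exc_name = f"{m}_excitation"
            exc = (
                np.clip(stride.channel(exc_name).samples, 0.0, 1.0)
                if exc_name in stride.channels
                else act
            )
            _, _, _, _, total = umberger_rate_arrays(
                act,
                exc,
                stride.channel(f"{m}_fiber_length").samples,
                stride.channel(f"{m}_fiber_velocity").samples,
                stride.channel(f"{m}_active_force").samples,
                p,
            )
            totals.append(total)
        return integrate_cost_rate(np.array(totals), stride.duration, self.body_mass)
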