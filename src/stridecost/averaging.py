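"""Gait-cycle time normalization, gait-pattern averaging, and the three
cost-estimation methods.

Method 1 estimates effort from a single randomly chosen stride, method 2 from
the averaged gait pattern (signals time-normalized to 0–100% of the gait
cycle, averaged pointwise across strides, remapped to the mean stride
period), and method 3 — the reference — as the arithmetic mean of the
per-stride effort rates. For effort models that are time-averages of a convex
pointwise function of the signals, Jensen's inequality makes method 2 a
systematic *under*-estimate of method 3.

All three methods evaluate the cost model on the same gait-cycle-grid
representation of a stride (normalize → remap, applied identically to every
stride), so method differences reflect stride-to-stride variability rather
than resampling artifacts; with zero variability the three estimates agree to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from stridecost.io import SignalChannel
from stridecost.preprocess import StrideSeries

__all__ = [
    "NormalizedStride",
    "AveragedStride",
    "MethodComparison",
    "CostModel",
    "time_normalize",
    "average_gait_pattern",
    "estimate_methods",
]

DEFAULT_N_GRID = 101

#: A cost model maps one stride's signals to a scalar effort rate.
CostModel = Callable[[StrideSeries], float]


@dataclass
class NormalizedStride:
    """One stride's channels resampled onto a uniform 0–100% gait-cycle grid."""

    grid: np.ndarray  # gait-cycle fractions in [0, 1]
    channels: dict[str, SignalChannel]
    original_duration: float
    sampling_rate: float
    side: str = "left"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        n = self.grid.size
        for name, ch in self.channels.items():
            if len(ch) != n:
                raise ValueError(f"channel {name!r} length {len(ch)} != grid {n}")

    @property
    def n_grid(self) -> int:
        return int(self.grid.size)

    def to_stride_series(self, duration: float | None = None) -> StrideSeries:
        """Map the gait-cycle pattern onto a stride of the given period,
        resampled at the original trial rate."""
        T = self.original_duration if duration is None else float(duration)
        rate = self.sampling_rate
        n = int(round(T * rate)) + 1
        frac = np.linspace(0.0, 1.0, n)
        channels = {
            name: ch.replace_samples(np.interp(frac, self.grid, ch.samples))
            for name, ch in self.channels.items()
        }
        return StrideSeries(
            channels=channels,
            t_start=0.0,
            duration=(n - 1) / rate,
            sampling_rate=rate,
            side=self.side,
        )


@dataclass
class AveragedStride:
    """Pointwise mean gait pattern across strides, carrying the mean period."""

    grid: np.ndarray
    channels: dict[str, SignalChannel]
    duration: float  # arithmetic mean of member durations, s
    n_members: int
    sampling_rate: float
    side: str = "left"

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError(f"need >= 2 member strides, got {self.n_members}")

    def as_normalized(self) -> NormalizedStride:
        return NormalizedStride(
            grid=self.grid,
            channels=self.channels,
            original_duration=self.duration,
            sampling_rate=self.sampling_rate,
            side=self.side,
        )

    def to_stride_series(self) -> StrideSeries:
        """The averaged pattern mapped to the mean stride period."""
        return self.as_normalized().to_stride_series(self.duration)


@dataclass
class MethodComparison:
    """Three method estimates and percent errors for one trial.

    Percent errors are against method 3, the mean of per-stride costs;
    method 1's error is also reported unsigned since a random stride may
    over- or under-estimate.
    """

    per_stride_costs: list[float]
    method1_index: int
    method1_cost: float
    method2_cost: float
    method3_cost: float
    percent_error_m1: float
    abs_percent_error_m1: float
    percent_error_m2: float

    @property
    def jensen_gap(self) -> float:
        """method3 − method2; non-negative for convex effort models on
        equal-duration strides."""
        return self.method3_cost - self.method2_cost


def time_normalize(stride: StrideSeries, n_grid: int = DEFAULT_N_GRID) -> NormalizedStride:
    """Resample one stride's channels onto a uniform 0–100% gait-cycle grid.

    Linear interpolation; endpoints equal the stride's first/last samples.
    """
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")
    grid = np.linspace(0.0, 1.0, n_grid)
    frac_orig = np.linspace(0.0, 1.0, stride.n_samples)
    channels = {
        name: ch.replace_samples(np.interp(grid, frac_orig, ch.samples))
        for name, ch in stride.channels.items()
    }
    return NormalizedStride(
        grid=grid,
        channels=channels,
        original_duration=stride.duration,
        sampling_rate=stride.sampling_rate,
        side=stride.side,
    )


def average_gait_pattern(strides: list[NormalizedStride]) -> AveragedStride:
    """Average time-normalized strides pointwise at each gait-cycle fraction.

    The result carries the mean stride period; mapping it back to a time
    series yields the single 'averaged gait pattern' stride of method 2.
    """
    if len(strides) < 2:
        raise ValueError(f"need >= 2 strides to average, got {len(strides)}")
    first = strides[0]
    names = set(first.channels)
    for k, s in enumerate(strides[1:], start=1):
        if s.n_grid != first.n_grid or not np.allclose(s.grid, first.grid):
            raise ValueError(f"stride {k} grid differs from stride 0")
        if set(s.channels) != names:
            raise ValueError(f"stride {k} channel names differ from stride 0")
    channels = {
        name: first.channels[name].replace_samples(
            np.mean([s.channels[name].samples for s in strides], axis=0)
        )
        for name in first.channels
    }
    return AveragedStride(
        grid=first.grid.copy(),
        channels=channels,
        duration=float(np.mean([s.original_duration for s in strides])),
        n_members=len(strides),
        sampling_rate=first.sampling_rate,
        side=first.side,
    )


def estimate_methods(
    strides: list[StrideSeries],
    cost_model: CostModel,
    rng_seed: int | None = None,
    n_grid: int = DEFAULT_N_GRID,
    duration_weighted: bool = False,
) -> MethodComparison:
    """Compare the three effort-averaging methods on one trial's strides.

    method 1: cost of one uniformly drawn stride (seeded);
    method 2: cost of the averaged gait pattern at the mean stride period;
    method 3: arithmetic mean of the per-stride cost rates (optionally
    weighted by stride duration; per-stride costs are already time-averaged
    rates, so the default is unweighted).
    """
    if len(strides) < 2:
        raise ValueError(f"need >= 2 strides, got {len(strides)}")
    normalized = [time_normalize(s, n_grid) for s in strides]
    per_stride_costs = []
    for k, ns in enumerate(normalized):
        try:
            per_stride_costs.append(float(cost_model(ns.to_stride_series())))
        except Exception as exc:
            raise RuntimeError(f"cost model failed on stride {k}: {exc}") from exc
    costs = np.asarray(per_stride_costs)
    if duration_weighted:
        w = np.array([s.duration for s in strides])
        method3 = float(np.sum(w * costs) / np.sum(w))
    else:
        method3 = float(np.mean(costs))
    averaged = average_gait_pattern(normalized)
    method2 = float(cost_model(averaged.to_stride_series()))
    rng = np.random.default_rng(rng_seed)
    idx = int(rng.integers(len(strides)))
    method1 = per_stride_costs[idx]
    pe_m1 = 100.0 * (method1 - method3) / method3
    pe_m2 = 100.0 * (method2 - method3) / method3
    return MethodComparison(
        per_stride_costs=per_stride_costs,
        method1_index=idx,
        method1_cost=method1,
        method2_cost=method2,
        method3_cost=method3,
        percent_error_m1=pe_m1,
        abs_percent_error_m1=abs(pe_m1),
        percent_error_m2=pe_m2,
    )
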