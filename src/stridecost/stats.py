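"""Comparison statistics, the Jensen-gap diagnostic and the 1/N
variance-scaling experiment.

The averaged-gait-pattern estimate (method 2) is compared against the mean of
per-stride costs (method 3) with a paired t-test across trials; percent
errors are regressed on walking speed with pooled ordinary least squares (no
mixed-effects structure and no multiple-testing correction). Because the mean
of N i.i.d. per-stride costs has variance Var(cost)/N, the variance of the
method-3 estimate shrinks like 1/N_strides — measured here empirically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from stridecost.averaging import CostModel, MethodComparison
from stridecost.synthetic import SyntheticGaitConfig, generate_stride_series

__all__ = [
    "TrialSummary",
    "ConvexProbe",
    "percent_error",
    "paired_method_test",
    "regress_error_on_speed",
    "jensen_gap",
    "variance_scaling_experiment",
]


@dataclass
class TrialSummary:
    """One trial's method estimates and percent errors, with labels."""

    participant: str
    speed: float
    model: str
    method1_cost: float
    method2_cost: float
    method3_cost: float
    percent_error_m1: float
    abs_percent_error_m1: float
    percent_error_m2: float

    @classmethod
    def from_comparison(
        cls, comparison: MethodComparison, participant: str, speed: float, model: str
    ) -> "TrialSummary":
        return cls(
            participant=participant,
            speed=speed,
            model=model,
            method1_cost=comparison.method1_cost,
            method2_cost=comparison.method2_cost,
            method3_cost=comparison.method3_cost,
            percent_error_m1=comparison.percent_error_m1,
            abs_percent_error_m1=comparison.abs_percent_error_m1,
            percent_error_m2=comparison.percent_error_m2,
        )


@dataclass
class ConvexProbe:
    """A scalar convex function and the input points to probe it at."""

    f: Callable[[float], float]
    p_values: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.p_values) < 2:
            raise ValueError("need >= 2 probe points")


def percent_error(estimate: float, reference: float, absolute: bool = False) -> float:
    """Signed (or absolute) percent error of an estimate against a reference."""
    if reference == 0:
        raise ZeroDivisionError("percent error undefined for zero reference")
    pe = 100.0 * (estimate - reference) / reference
    return abs(pe) if absolute else pe


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    mean_difference: float
    se_difference: float
    n: int


def paired_method_test(
    method2_costs: Sequence[float], method3_costs: Sequence[float]
) -> PairedTestResult:
    """Paired t-test of method-2 vs method-3 costs across trials.

    Reports the mean difference with its standard error (the field's
    mean ± s.e. convention). Raises on zero-variance differences, where the
    statistic is undefined.
    """
    m2 = np.asarray(method2_costs, float)
    m3 = np.asarray(method3_costs, float)
    if m2.size != m3.size:
        raise ValueError("paired lists must have equal length")
    if m2.size < 3:
        raise ValueError("need >= 3 pairs")
    d = m2 - m3
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences: t statistic undefined")
    res = sst.ttest_rel(m2, m3)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(d.mean()),
        se_difference=float(sd / np.sqrt(d.size)),
        n=int(d.size),
    )


@dataclass
class SpeedRegression:
    slope: float  # % per (m/s)
    intercept: float
    p_value: float  # two-sided, for the slope
    r_value: float


def regress_error_on_speed(
    summaries: Sequence[TrialSummary], error_field: str = "percent_error_m2"
) -> SpeedRegression:
    """Pooled OLS of percent error on trial speed across all summaries."""
    speeds = np.array([s.speed for s in summaries], float)
    errors = np.array([getattr(s, error_field) for s in summaries], float)
    if np.unique(speeds).size < 3:
        raise ValueError("need >= 3 distinct speeds for the regression")
    res = sst.linregress(speeds, errors)
    return SpeedRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_value=float(res.rvalue),
    )


def jensen_gap(probe: ConvexProbe) -> tuple[float, float, float]:
    """Evaluate f at the mean of the points vs the mean of f at the points.

    Returns (f_of_mean, mean_of_f, gap); for convex f the gap is >= 0, which
    is the mechanism by which the averaged gait pattern under-estimates the
    mean per-stride cost.
    """
    p = np.asarray(probe.p_values, float)
    f_of_mean = float(probe.f(float(p.mean())))
    mean_of_f = float(np.mean([probe.f(float(x)) for x in p]))
    return f_of_mean, mean_of_f, mean_of_f - f_of_mean


def variance_scaling_experiment(
    config: SyntheticGaitConfig,
    cost_model: CostModel,
    N_grid: Sequence[int],
    n_resamples: int = 2000,
    seed: int | None = None,
    n_bootstrap: int = 500,
) -> dict:
    """Empirical variance of the N-stride mean cost, for each N.

    For each N, draws ``n_resamples`` independent N-stride sets from the
    generator, computes the method-3 mean cost of each set and reports the
    variance across resamples; with i.i.d. strides this shrinks like 1/N.
    Also reports the slope of log-variance vs log-N and, when 1 and 5 are in
    the grid, a percentile bootstrap CI for var(5)/var(1).
    """
    if len(N_grid) < 3 or 1 not in N_grid:
        raise ValueError("N_grid must cover >= 3 values and include 1")
    rng = np.random.default_rng(seed)
    means: dict[int, np.ndarray] = {}
    for N in N_grid:
        vals = np.empty(n_resamples)
        for r in range(n_resamples):
            costs = [
                float(cost_model(generate_stride_series(config, rng))) for _ in range(N)
            ]
            vals[r] = np.mean(costs)
        means[int(N)] = vals
    table = pd.DataFrame(
        {
            "N": list(means),
            "variance": [float(np.var(v, ddof=1)) for v in means.values()],
        }
    )
    logN = np.log(table["N"].to_numpy(float))
    logV = np.log(table["variance"].to_numpy(float))
    slope = float(sst.linregress(logN, logV).slope)
    out = {"table": table, "loglog_slope": slope}
    if 5 in means:
        v1, v5 = means[1], means[5]
        ratios = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            i1 = rng.integers(v1.size, size=v1.size)
            i5 = rng.integers(v5.size, size=v5.size)
            ratios[b] = np.var(v5[i5], ddof=1) / np.var(v1[i1], ddof=1)
        out["ratio_5_1"] = float(np.var(v5, ddof=1) / np.var(v1, ddof=1))
        out["ratio_ci"] = (
            float(np.percentile(ratios, 2.5)),
            float(np.percentile(ratios, 97.5)),
        )
    return out
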