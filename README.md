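# stridecost

Humans never walk the same stride twice. When walking metabolic cost is
estimated from motion and force recordings through a model — a muscle
energetics model or a simple joint-torque effort measure — the usual practice
of averaging the gait signals across strides *before* evaluating the model
quietly removes that stride-to-stride variability, and with it part of the
cost. `stridecost` quantifies that bias and provides the tooling to avoid
it. It is aimed at movement scientists and biomechanists who estimate
walking energetics from multi-stride gait data.

## The three averaging methods

Given `N_stride` consecutive strides of a trial, an effort estimate can be
formed three ways:

1. **random stride** — evaluate the cost model on one randomly chosen stride;
2. **averaged gait pattern** — time-normalize every stride to 0–100% of the
   gait cycle, average the signals pointwise at each cycle fraction, map the
   averaged pattern to the mean stride period, and evaluate the model once;
3. **mean of per-stride costs** — evaluate the model on every stride and
   average the resulting cost rates (the reference).

For any cost model that is a time-average of a convex function of the
signals, Jensen's inequality `f(mean p) ≤ mean f(p)` forces method 2 to
*under*-estimate method 3; the gap is the metabolic cost of stride-to-stride
variability. For the torque-squared effort rate

    Ė_cost = (1/T) ∫₀ᵀ Σⱼ aⱼ τⱼ(t)² dt

(joint moments τⱼ, unit coefficients aⱼ by default) the integrand is exactly
convex, so the bias is guaranteed. The package also ships an Umberger-style
muscle energetics model, Ė = Ẇ + ḣ_A + ḣ_m + ḣ_sl (fiber work rate plus
activation, maintenance, and shortening/lengthening heat rates), evaluated
from muscle-state trajectories.

A feedback-controlled inverted-pendulum walker (point mass, impulsive
push-off and heel strike, energy-optimal nominal gait, speed feedback to
push-off and foot placement) closes the loop: Gaussian sensory or motor
noise creates stride-to-stride variability and raises both the mean
metabolic rate and its step-to-step spread above the no-noise baseline.

Because the original treadmill recordings feed an external musculoskeletal
toolchain, the package includes a synthetic-gait generator that emulates
their statistical structure (double-bump vertical GRF, stride-period jitter,
per-stride amplitude variability, measurement noise) with ground truth for
every stride.

## Worked example

```python
import numpy as np
from stridecost import (
    SyntheticGaitConfig, generate_gait_trial, detect_heel_strikes,
    segment_strides, estimate_methods, TorqueSquaredCost,
)

cfg = SyntheticGaitConfig(seed=1)                 # ~2 min at 100 Hz
trial, truth = generate_gait_trial(cfg)
events = detect_heel_strikes(trial.channel("grf_vertical"), sampling_rate=100.0)
strides = segment_strides(trial, events, n_strides=5, start_index="random", seed=7)
cmp = estimate_methods(strides, TorqueSquaredCost(), rng_seed=7)
print(f"m1={cmp.method1_cost:.2f} m2={cmp.method2_cost:.2f} "
      f"m3={cmp.method3_cost:.2f} pe2={cmp.percent_error_m2:+.3f}%")
```

prints

```
m1=2506.93 m2=2634.60 m3=2639.63 pe2=-0.191%
```

the averaged gait pattern (method 2) costs 0.19% less than the per-stride
mean (method 3) for this trial, and the randomly drawn stride misses the
reference by −5.0% — a single stride can be off in either direction, while
method 2 is systematically low.

The numbered scripts under `analysis/` run the full study: `01` generates
the synthetic dataset (8 participants × 3 speeds), `02` compares the three
methods under both cost models with paired t-tests and error-vs-speed
regressions, `03` sweeps sensory/motor noise in the pendulum walker, `04`
measures the 1/N shrinkage of the multi-stride estimate's variance. Small
result tables land in `results/`.

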