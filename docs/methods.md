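# Methods

## Scope and pipeline

The package estimates walking effort from multi-stride gait time-series and
quantifies the bias introduced by averaging signals across strides before
evaluating a cost model. The pipeline is: read/validate a trial → zero-phase
low-pass filtering → heel-strike detection from vertical GRF → stride
segmentation → gait-cycle time normalization → the three averaging methods →
comparison statistics. Muscle-state trajectories for the energetics model
and all gait trials used in tests and analyses come from the synthetic
generator; an inverted-pendulum walker provides the mechanistic counterpart
where noise is the *cause* of variability rather than an observed property.

## Signal conditioning and segmentation

Joint-angle and GRF channels are filtered with a Butterworth low-pass,
cut-off 6 Hz, order 4, applied forward–backward (`sosfiltfilt`). Zero-phase
application is chosen because a causal filter would delay the GRF onset and
bias heel-strike times; the order and pass direction are configuration
defaults, not claims about the source protocol. Moment channels are left
unfiltered by default since, in the workflow this mirrors, they are produced
by inverse dynamics from already-filtered inputs.

Heel strikes are upward crossings of a 30 N vertical-force threshold,
reported at the first at/above-threshold sample and debounced with a 0.4 s
minimum inter-event gap. The same 30 N threshold defines the swing phase, in
which all GRF components of a foot are zeroed. A stride spans one left heel
strike to the next; five consecutive strides starting at a uniformly drawn
heel strike form the default analysis unit.

## The three methods and why they share one representation

Strides are resampled by linear interpolation onto a uniform 101-point
gait-cycle grid (0, 1, …, 100%); linear interpolation is monotone and
artifact-free at this density, and 101 points make the endpoints explicit.
The averaged gait pattern is the pointwise mean at each cycle fraction,
carried at the mean stride period.

All three method estimates evaluate the cost model on the same
normalize-then-remap representation of a stride (method 2 additionally
averages before remapping). This is deliberate: resampling is a smoothing
operation whose effect on a convex cost is itself a Jensen-type bias of
order (grid spacing)², comparable to the small effects under study. Applying
the identical representation to every method makes the zero-variability case
collapse exactly (all methods agree to machine precision) and makes the
discrete Jensen inequality hold exactly for equal-duration strides. Method 3
averages per-stride cost *rates* unweighted — each per-stride cost is
already a time average — with a duration-weighted variant behind a flag.
Method 1's percent error is reported signed and unsigned; a random stride
can err in either direction.

## Cost models

**Torque-squared**: Ė = (1/T)∫ Σⱼ aⱼτⱼ² dt with aⱼ = 1 by default,
trapezoid quadrature on the sampled moments (O(h²) error, negligible at
100 Hz). Convex in the torque trajectory, hence the guaranteed
averaged-pattern under-estimate.

**Muscle energetics**: total rate Ẇ + ḣ_A + ḣ_m + ḣ_sl per muscle, summed
over muscles, trapezoid-integrated over the stride and divided by stride
time. Coefficients follow the 2003 formulation with the 2010 modifications:
activation+maintenance heat 128·f_FT + 25 W/kg at full activation, split
0.4/0.6 into a length-independent activation part and a maintenance part
scaled by a Gaussian force–length factor exp(−(l̃−1)²/0.45) for
longer-than-optimal fibers; activation scaling A^0.6 (A = u if u > a else
(u+a)/2) for these terms and A² for shortening heat; shortening coefficients
100/V̄_max(ST) and 153/V̄_max(FT) with V̄_max(FT) = 2.5·V̄_max(ST) =
12 l_opt/s by default; lengthening heat 4·(100/V̄_max(ST))·ṽ·A; fiber work
rate −F·ṽ·l_opt. Heats are multiplied by the aerobic scale (default 1.5)
and muscle mass. Variant flags: clamp the total at zero (default on —
eccentric work can otherwise drive it negative), fold a basal rate into
maintenance (default off). Muscle states are inputs; no
excitation→activation or tendon dynamics are solved.

A caveat the analyses surface honestly: this heat-rate total is *not*
globally convex in activation (A^0.6 is concave), so the averaged-pattern
under-estimate is guaranteed only for the torque model. In the synthetic
conditions the heat-rate model shows a small *over*-estimate
(≈ +0.1%), and convexity-based reasoning about it is model-regime dependent
— consistent with occasional reversals in practice.

## Synthetic generator

Defaults emulate a 2-minute treadmill trial: 109 strides of base period
1.1 s (scaled with belt speed in the analysis scripts) at 100 Hz; channel
templates are low-order Fourier series shaped like textbook gait waveforms
plus a dedicated double-bump vertical GRF that is exactly zero over the 40%
swing window and crosses 30 N once per stride. Per stride, the period is
jittered (SD 0.02 s, redrawn at/below 0.2 s) by uniform time dilation — the
kind of variability time normalization undoes — and the time-varying part of
every channel is scaled by a common 1 + γ factor (SD 0.05, offsets
preserved so swing GRF stays at 0 N). Additive measurement noise per channel
kind: 0.25° angles, 0.5 N·m moments, 2 N GRF. These magnitudes are
realistic for steady treadmill walking and are fixed study conditions, not
tuning knobs. The generator returns ground truth (continuous 30 N crossing
times, per-stride periods and amplitude factors).

What the generator does *not* emulate: within-cycle shape changes
uncorrelated across channels, drift/non-stationarity (e.g. a participant
slowing down), dynamically consistent moments/GRFs, and real measurement
artifacts. Passing tests therefore demonstrate the machinery and the
direction and scaling of the averaging bias under controlled variability —
not the magnitude of the bias in any real dataset, which depends on the
richer variability structure of actual gait. Under pure amplitude scaling
the relative Jensen gap is ≈ Var(γ), ~0.15% here; richer waveform
variability produces larger gaps.

Muscle-state trajectories use raised-cosine activation bursts (clipped to
[0, 1]), fiber lengths 1 + 0.05·sin(2πφ) with velocities computed as the
exact analytic derivative, and force–length-scaled active force; they carry
the same per-stride perturbation machinery but no additive noise (they stand
in for model outputs, not measurements).

## Inverted-pendulum walker

Nondimensional point-mass compass gait (m = g = ℓ = 1): stance obeys
θ̈ = sin θ, conserving E = ½θ̇² + cos θ; transitions apply a push-off
impulse P along the trailing leg then a heel-strike impulse along the new
leg, giving v⁺ = v⁻cos 2α + P sin 2α, push-off work P²/2 and collision loss
½(v⁻sin 2α − P cos 2α)² at inter-leg angle 2α (step length s = 2 sin α).
Step cost is push-off work plus a swing cost c_sw(1/T_step)^q with q = 3 and
c_sw = 0.0177, calibrated once so the energy-optimal gait at target speed
0.4 has a human-like step length of 0.6. The nominal gait is the cost-rate
minimizer over step angle among period-1 limit cycles meeting the speed
constraint (bounded scalar minimization with an inner root solve).

The controller senses mid-stance speed and commands
P = P* + k_P(v̂ − v*) + ε_P and s = s* + k_s(v̂ − v*) + ε_s. Default gains
cancel the linearized speed deviation in one step (deadbeat), computed
numerically at setup with the correction split equally between push-off and
foot placement. Sensory noise perturbs v̂; motor noise perturbs P and s; the
two modes are swept separately (grid 0, 0.005, 0.01, 0.02, 0.04 by default)
and normalized by the zero-noise run. Falls (insufficient energy to pass
mid-stance) are recorded, the walker is reset to the nominal state, and the
fall count is reported; at the default noise levels falls are rare.

Production stepping uses the conserved energy: speeds in closed form and
stance durations by 64-node Gauss–Legendre quadrature of ∫dθ/θ̇(θ), split at
mid-stance so the simulated zero-noise walk reproduces the nominal cost rate
to machine precision. The ODE/event-detection route (`integrate_stance`,
`solve_ivp` at rtol 1e-10) is retained and tested to agree with the
quadrature to 1e-7; energy bookkeeping per step closes to 1e-10.

## Statistics

Method 2 vs method 3 uses a two-sided paired t-test per speed, with the mean
percent difference ± standard error; zero-variance differences raise rather
than return a meaningless statistic. Error-vs-speed uses pooled two-sided
OLS (participants pooled — a documented simplification; no mixed effects,
no multiple-testing correction). The variance-scaling experiment draws
i.i.d. strides, computes N-stride mean costs over 2000 resamples per N ∈
{1, 2, 5, 10, 20}, and reports the variance per N, the log–log slope
(≈ −1 under the 1/N law) and a 500-rep percentile bootstrap CI for
var(5)/var(1).

## Problem sizes and numerical choices

Default problem sizes — 2-minute trials, 5 strides per comparison, 100
trials for direction checks, 2000 walker steps × 10 seeds × 5 noise levels
per sweep, 2000 resamples per N — were chosen as the smallest sets at which
the studied effects are statistically unambiguous on a single workstation
core. Tolerances: storage round-trip 1e-12 relative (15 significant digits);
time-axis uniformity 1e-6 s; heat-rate oracle agreement 1e-8; pendulum
energy bookkeeping 1e-10. Degenerate inputs fail loudly: NaN cells name row
and column, missing joint/muscle channels name the channel, too-few heel
strikes report both counts.

## Known limitations

- The averaging-bias magnitudes here reflect the generator's variability
  structure, not any real cohort; only directions, collapse properties and
  scaling laws transfer.
- The heat-rate model's convexity caveat above; stride-level reasoning via
  Jensen also assumes near-periodic gait.
- The walker is 2-D, massless-legged, with impulsive transitions; its noise
  levels and costs are nondimensional and only trends are meaningful.
- Heel-strike detection is sample-resolution by design; with additive
  measurement noise an event can occasionally slip one extra sample past the
  continuous crossing time.
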