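"""Synthetic multi-stride gait trials and muscle-state trajectories.

The generator emulates the statistical structure of treadmill gait
recordings: quasi-periodic strides (~1.1 s), a double-bump vertical ground
reaction force with near-zero swing phases, stride-duration jitter, per-stride
amplitude variability, and additive measurement noise. Channel templates are
low-order Fourier series shaped like textbook gait waveforms; they are
illustrative fixtures, not participant data.

Per stride k the period is T₀ + δ_k (δ ~ N(0, σ_period²), redrawn if the
period would fall at/below 0.2 s) and the time-varying part of every channel
is scaled by a common factor 1 + γ_k (γ ~ N(0, σ_amplitude²)); the offset is
preserved so GRF swing phases stay near 0 N. Period jitter dilates the
template uniformly in time, exactly the kind of variability gait-cycle time
normalization undoes. Ground-truth heel-strike times (the 30 N upward
crossing of the noise-free vertical GRF) are returned for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from stridecost.io import GaitTrial, SignalChannel
from stridecost.preprocess import StrideSeries
from stridecost.umberger import force_length_factor

__all__ = [
    "ChannelTemplate",
    "SyntheticGaitConfig",
    "GroundTruth",
    "default_templates",
    "generate_gait_trial",
    "generate_stride_series",
    "generate_muscle_states",
]

log = logging.getLogger(__name__)

MIN_STRIDE_PERIOD = 0.2  # s; shorter period draws are rejected and redrawn
HEEL_STRIKE_THRESHOLD = 30.0  # N; the swing/contact force threshold
STANCE_FRACTION = 0.6  # fraction of the gait cycle the foot is on the ground


@dataclass
class ChannelTemplate:
    """One channel's waveform over the gait cycle.

    ``harmonics`` is a list of (order, amplitude, phase) terms:
    value(φ) = offset + Σ amp · sin(2π·order·φ + phase). GRF channels use a
    dedicated stance-window shape instead (see :func:`grf_vertical_template`).
    """

    name: str
    offset: float = 0.0
    harmonics: list[tuple[int, float, float]] = field(default_factory=list)
    shape: str = "fourier"  # or "grf_vertical", "grf_fore_aft"
    scale: float = 1.0

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        if self.shape == "grf_vertical":
            return self.scale * grf_vertical_shape(phi)
        if self.shape == "grf_fore_aft":
            return self.scale * grf_fore_aft_shape(phi)
        out = np.full_like(phi, self.offset)
        for order, amp, phase in self.harmonics:
            out = out + amp * np.sin(2.0 * np.pi * order * phi + phase)
        return out


def grf_vertical_shape(phi: np.ndarray) -> np.ndarray:
    """Unit-scale double-bump vertical GRF: two maxima during stance
    (φ < 0.6), exactly zero during swing."""
    x = np.clip(phi / STANCE_FRACTION, 0.0, 1.0)
    stance = np.sin(np.pi * x) * (1.0 + 0.35 * np.cos(2.0 * np.pi * x))
    return np.where(phi < STANCE_FRACTION, np.maximum(stance, 0.0), 0.0)


def grf_fore_aft_shape(phi: np.ndarray) -> np.ndarray:
    """Unit-scale fore-aft GRF: braking then propulsion during stance,
    zero in swing."""
    x = np.clip(phi / STANCE_FRACTION, 0.0, 1.0)
    stance = -np.sin(2.0 * np.pi * x) * np.sin(np.pi * x)
    return np.where(phi < STANCE_FRACTION, stance, 0.0)


def default_templates(body_weight: float = 800.0) -> list[ChannelTemplate]:
    """Textbook-shaped channel templates: three joint angles (deg), three
    joint moments (N·m), vertical and fore-aft GRFs (N)."""
    return [
        ChannelTemplate("ankle_angle", 0.0, [(1, 8.0, 0.4), (2, 6.0, 1.9), (3, 2.5, 0.3)]),
        ChannelTemplate("knee_angle", 25.0, [(1, 22.0, -1.2), (2, 12.0, 0.7), (3, 3.0, -0.5)]),
        ChannelTemplate("hip_angle", 5.0, [(1, 20.0, 1.57), (2, 3.0, 0.2)]),
        ChannelTemplate("ankle_moment", 30.0, [(1, 35.0, -1.0), (2, 25.0, 0.9), (3, 8.0, 0.1)]),
        ChannelTemplate("knee_moment", 5.0, [(1, 18.0, 0.6), (2, 12.0, -0.8), (3, 5.0, 1.2)]),
        ChannelTemplate("hip_moment", 0.0, [(1, 30.0, 2.2), (2, 10.0, -0.3)]),
        ChannelTemplate("grf_vertical", shape="grf_vertical", scale=1.05 * body_weight),
        ChannelTemplate("grf_fore_aft", shape="grf_fore_aft", scale=0.2 * body_weight),
    ]


@dataclass
class SyntheticGaitConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a 2-minute treadmill trial sampled at 100 Hz with a
    ~1.1 s stride period; variability magnitudes are realistic for steady
    treadmill walking (stride-period SD ~20 ms, ~5% stride-to-stride
    amplitude variability, small additive measurement noise per channel
    kind).
    """

    n_strides: int = 109
    base_stride_period: float = 1.1  # s
    sampling_rate: float = 100.0  # Hz
    speed: float = 1.0  # m/s, trial label
    sigma_amplitude: float = 0.05  # fractional SD of per-stride amplitude scale
    sigma_period: float = 0.02  # s, SD of stride period
    sigma_meas: dict[str, float] = field(
        default_factory=lambda: {"angle": 0.25, "moment": 0.5, "grf_force": 2.0, "other": 0.0}
    )
    seed: int | None = None
    templates: list[ChannelTemplate] | None = None
    participant_id: str = "synthetic"
    body_mass: float = 72.7  # kg, dataset-typical

    def __post_init__(self) -> None:
        if self.base_stride_period <= 0:
            raise ValueError("base_stride_period must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.sigma_amplitude < 0 or self.sigma_period < 0:
            raise ValueError("variability SDs must be >= 0")
        if any(v < 0 for v in self.sigma_meas.values()):
            raise ValueError("measurement-noise SDs must be >= 0")
        if self.templates is None:
            self.templates = default_templates(body_weight=9.81 * self.body_mass)
        vert = [t for t in self.templates
                if t.shape == "grf_vertical" or t.name == "grf_vertical"]
        if vert:
            phi = np.linspace(0.0, 1.0, 2001)
            vals = vert[0](phi)
            swing = vals < HEEL_STRIKE_THRESHOLD
            # longest contiguous sub-threshold run must cover >= 25% of the cycle
            runs = np.diff(np.flatnonzero(np.diff(np.r_[0, swing.view(np.int8), 0])))[::2]
            if runs.size == 0 or runs.max() < 0.25 * phi.size:
                raise ValueError(
                    "vertical GRF template lacks a sub-30 N swing window covering "
                    ">= 25% of the cycle"
                )


@dataclass
class GroundTruth:
    """Generator-side truth for testing detectors and segmenters."""

    stride_start_times: np.ndarray  # s, start of each stride's template cycle
    heel_strike_times: np.ndarray  # s, 30 N upward crossing per stride
    durations: np.ndarray  # s, per-stride periods
    amplitude_factors: np.ndarray  # 1 + gamma_k per stride


def _draw_stride_params(
    config: SyntheticGaitConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    durations = np.empty(n)
    for k in range(n):
        T = config.base_stride_period + rng.normal(0.0, config.sigma_period)
        while T <= MIN_STRIDE_PERIOD:
            log.warning("redrawing stride period %.3f s <= %.1f s", T, MIN_STRIDE_PERIOD)
            T = config.base_stride_period + rng.normal(0.0, config.sigma_period)
        durations[k] = T
    factors = 1.0 + rng.normal(0.0, config.sigma_amplitude, size=n)
    return durations, factors


def _scaled_template(tpl: ChannelTemplate, phi: np.ndarray, factor: float) -> np.ndarray:
    """Amplitude factor applied to the time-varying part; offset preserved.
    GRF shapes have zero offset, so the whole waveform scales."""
    offset = tpl.offset if tpl.shape == "fourier" else 0.0
    return offset + factor * (tpl(phi) - offset)


def _crossing_fraction(tpl: ChannelTemplate, factor: float) -> float:
    """Gait-cycle fraction at which the scaled vertical GRF rises through the
    30 N contact threshold."""

    def f(phi: float) -> float:
        return factor * float(tpl(np.array([phi]))[0]) - HEEL_STRIKE_THRESHOLD

    return brentq(f, 1e-9, 0.25 * STANCE_FRACTION, xtol=1e-12)


def generate_gait_trial(
    config: SyntheticGaitConfig, seed: int | None = None
) -> tuple[GaitTrial, GroundTruth]:
    """Generate a quasi-periodic multi-stride trial plus its ground truth.

    The trial's channels sit on one uniform global time grid; sample times
    falling in stride k are evaluated at the stride's template phase
    φ = (t − t_k)/T_k. The vertical GRF crosses 30 N upward exactly once per
    stride.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    durations, factors = _draw_stride_params(config, config.n_strides, rng)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    total = starts[-1]
    fs = config.sampling_rate
    n_samples = int(np.floor(total * fs)) + 1
    t = np.arange(n_samples) / fs
    stride_of = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, config.n_strides - 1)
    phi = (t - starts[stride_of]) / durations[stride_of]
    phi = np.clip(phi, 0.0, 1.0)

    channels: dict[str, SignalChannel] = {}
    for tpl in config.templates:
        clean = np.empty(n_samples)
        for k in range(config.n_strides):
            sel = stride_of == k
            clean[sel] = _scaled_template(tpl, phi[sel], factors[k])
        ch = SignalChannel(tpl.name, clean)
        sd = config.sigma_meas.get(ch.kind, 0.0)
        if sd > 0:
            ch = ch.replace_samples(clean + rng.normal(0.0, sd, size=n_samples))
        channels[tpl.name] = ch

    vert = next(tpl for tpl in config.templates if tpl.shape == "grf_vertical")
    hs = np.array(
        [starts[k] + _crossing_fraction(vert, factors[k]) * durations[k]
         for k in range(config.n_strides)]
    )
    trial = GaitTrial(
        participant_id=config.participant_id,
        sampling_rate=fs,
        channels=channels,
        belt_speed=config.speed,
        body_mass=config.body_mass,
    )
    truth = GroundTruth(
        stride_start_times=starts[:-1],
        heel_strike_times=hs,
        durations=durations,
        amplitude_factors=factors,
    )
    return trial, truth


def generate_stride_series(
    config: SyntheticGaitConfig, rng: np.random.Generator
) -> StrideSeries:
    """Draw one independent stride as a stand-alone :class:`StrideSeries`
    (own local time grid); used for i.i.d. resampling experiments."""
    durations, factors = _draw_stride_params(config, 1, rng)
    T, factor = float(durations[0]), float(factors[0])
    fs = config.sampling_rate
    n = int(round(T * fs)) + 1
    phi = np.linspace(0.0, 1.0, n)
    channels = {}
    for tpl in config.templates:
        clean = _scaled_template(tpl, phi, factor)
        ch = SignalChannel(tpl.name, clean)
        sd = config.sigma_meas.get(ch.kind, 0.0)
        if sd > 0:
            ch = ch.replace_samples(clean + rng.normal(0.0, sd, size=n))
        channels[tpl.name] = ch
    return StrideSeries(
        channels=channels, t_start=0.0, duration=(n - 1) / fs, sampling_rate=fs
    )


def _activation_burst(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth periodic raised-cosine activation burst in [0, 1]."""
    d = np.angle(np.exp(2j * np.pi * (phi - center))) / (2.0 * np.pi)  # wrapped distance
    inside = np.abs(d) < width / 2.0
    return np.where(inside, 0.5 * (1.0 + np.cos(2.0 * np.pi * d / width)), 0.0)


def generate_muscle_states(
    config: SyntheticGaitConfig,
    n_muscles: int = 2,
    seed: int | None = None,
    max_isometric_force: float = 1000.0,
) -> list[StrideSeries]:
    """Per-stride muscle-state trajectories with the same per-stride
    amplitude/period perturbation machinery as the gait channels.

    Each stride carries, per muscle ``m{i}``, channels ``_activation`` (burst
    in [0, 1]), ``_fiber_length`` (around 1), ``_fiber_velocity`` (the exact
    time derivative of the length channel, optimal lengths/s) and
    ``_active_force`` (force-length-scaled). Muscle states are treated as
    model outputs, so no additive measurement noise is applied.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    durations, factors = _draw_stride_params(config, config.n_strides, rng)
    fs = config.sampling_rate
    strides = []
    for k in range(config.n_strides):
        T, factor = float(durations[k]), float(factors[k])
        n = int(round(T * fs)) + 1
        phi = np.linspace(0.0, 1.0, n)
        channels = {}
        for i in range(n_muscles):
            center = (i + 0.5) / n_muscles
            act = np.clip(factor * 0.6 * _activation_burst(phi, center, 0.4), 0.0, 1.0)
            amp = factor * 0.05
            l = 1.0 + amp * np.sin(2.0 * np.pi * (phi - center))
            v = amp * 2.0 * np.pi * np.cos(2.0 * np.pi * (phi - center)) / T
            force = max_isometric_force * act * force_length_factor(l)
            stem = f"m{i}"
            channels[f"{stem}_activation"] = SignalChannel(f"{stem}_activation", act, kind="other")
            channels[f"{stem}_fiber_length"] = SignalChannel(f"{stem}_fiber_length", l, kind="other")
            channels[f"{stem}_fiber_velocity"] = SignalChannel(f"{stem}_fiber_velocity", v, kind="other")
            channels[f"{stem}_active_force"] = SignalChannel(f"{stem}_active_force", force, kind="other")
        strides.append(
            StrideSeries(channels=channels, t_start=0.0, duration=(n - 1) / fs, sampling_rate=fs)
        )
    return strides
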