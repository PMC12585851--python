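"""Signal conditioning and stride segmentation.

Joint-angle and ground-reaction-force channels are low-pass filtered with a
zero-phase Butterworth filter (default 6 Hz cut-off, order 4, applied
forward–backward so the effective order is 8 with no phase lag — phase lag
would bias heel-strike times). Heel strikes are detected as upward crossings
of a 30 N vertical-force threshold; a stride runs from one heel strike of a
foot to the next heel strike of the same foot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from stridecost.io import GaitDataError, GaitTrial, SignalChannel

__all__ = [
    "GaitEvents",
    "StrideSeries",
    "SegmentationError",
    "lowpass_filter",
    "filter_trial",
    "detect_heel_strikes",
    "zero_swing_grf",
    "segment_strides",
]

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_THRESHOLD_N = 30.0
DEFAULT_MIN_GAP_S = 0.4
DEFAULT_N_STRIDES = 5


class SegmentationError(ValueError):
    """Too few gait events to cut the requested number of strides."""


@dataclass
class GaitEvents:
    """Heel-strike times for one side, strictly increasing."""

    heel_strike_times: np.ndarray
    side: str = "left"
    min_stride_period: float = DEFAULT_MIN_GAP_S

    def __post_init__(self) -> None:
        self.heel_strike_times = np.asarray(self.heel_strike_times, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.heel_strike_times.size >= 2:
            gaps = np.diff(self.heel_strike_times)
            if np.any(gaps < self.min_stride_period):
                raise ValueError(
                    f"heel-strike spacing below minimum stride period "
                    f"{self.min_stride_period} s (min gap {gaps.min():.3g} s)"
                )

    def __len__(self) -> int:
        return int(self.heel_strike_times.size)


@dataclass
class StrideSeries:
    """One stride's channels, sampled at the trial rate over its own span."""

    channels: dict[str, SignalChannel]
    t_start: float
    duration: float
    sampling_rate: float
    side: str = "left"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"stride duration must be > 0, got {self.duration}")
        lengths = {len(ch) for ch in self.channels.values()}
        if len(lengths) != 1:
            raise GaitDataError(f"stride channels unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time(self) -> np.ndarray:
        """Local time axis 0..duration."""
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> SignalChannel:
        return self.channels[name]


def lowpass_filter(
    channel: SignalChannel,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    zero_phase: bool = True,
    sampling_rate: float = 100.0,
) -> SignalChannel:
    """Butterworth low-pass filter a channel.

    Parameters
    ----------
    cutoff
        Cut-off frequency in Hz (must be below Nyquist).
    order
        Filter order of a single pass; zero-phase application doubles the
        effective order.
    zero_phase
        Apply forward–backward (``filtfilt``) so no phase lag is introduced.
    """
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist} Hz)")
    if len(channel) <= 3 * order:
        raise ValueError(
            f"channel {channel.name!r} too short ({len(channel)} samples) for order {order}"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, channel.samples)
    else:
        out = sps.sosfilt(sos, channel.samples)
    return channel.replace_samples(out)


def filter_trial(
    trial: GaitTrial,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    kinds: tuple[str, ...] = ("angle", "grf_force"),
) -> GaitTrial:
    """Low-pass filter the kinematic and GRF channels of a trial.

    Moment channels are left untouched by default: in the source workflow they
    come out of an inverse-dynamics step fed by already-filtered inputs.
    """
    channels = {}
    for name, ch in trial.channels.items():
        if ch.kind in kinds:
            channels[name] = lowpass_filter(
                ch, cutoff=cutoff, order=order, sampling_rate=trial.sampling_rate
            )
        else:
            channels[name] = ch
    return trial.with_channels(channels)


def detect_heel_strikes(
    vertical_grf: SignalChannel,
    threshold: float = DEFAULT_THRESHOLD_N,
    min_gap: float = DEFAULT_MIN_GAP_S,
    sampling_rate: float = 100.0,
    t0: float = 0.0,
    side: str = "left",
) -> GaitEvents:
    """Detect heel strikes as upward crossings of a vertical-force threshold.

    An event is reported at the first sample at/above ``threshold`` after
    being below it; events closer than ``min_gap`` to the previous accepted
    event are discarded (debouncing against noise-induced double crossings).
    An empty event list is returned when the force never crosses upward.
    """
    if vertical_grf.kind != "grf_force":
        raise TypeError(
            f"heel-strike detection needs a grf_force channel, got kind "
            f"{vertical_grf.kind!r} ({vertical_grf.name!r})"
        )
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0 N, got {threshold}")
    y = vertical_grf.samples
    above = y >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    for idx in crossings:
        t = t0 + idx / sampling_rate
        if times and t - times[-1] < min_gap:
            continue
        times.append(t)
    return GaitEvents(np.array(times), side=side, min_stride_period=min_gap)


def zero_swing_grf(
    grf_channels: dict[str, SignalChannel],
    vertical_name: str,
    threshold: float = DEFAULT_THRESHOLD_N,
) -> dict[str, SignalChannel]:
    """Zero all GRF components of a foot wherever its vertical force is below
    the swing threshold; the vertical trace itself is zeroed too."""
    if vertical_name not in grf_channels:
        raise KeyError(f"vertical channel {vertical_name!r} not among GRF channels")
    swing = grf_channels[vertical_name].samples < threshold
    return {
        name: ch.replace_samples(np.where(swing, 0.0, ch.samples))
        for name, ch in grf_channels.items()
    }


def segment_strides(
    trial: GaitTrial,
    events: GaitEvents,
    n_strides: int = DEFAULT_N_STRIDES,
    start_index: int | str = "random",
    seed: int | None = None,
) -> list[StrideSeries]:
    """Cut ``n_strides`` consecutive strides out of a trial.

    Stride ``k`` spans heel strike ``k`` to heel strike ``k+1`` (both boundary
    samples included). With ``start_index="random"`` the first heel strike is
    drawn uniformly from the valid starts using ``seed``; the source protocol
    randomly selects six consecutive heel strikes to produce five strides.
    """
    n_events = len(events)
    if n_events < n_strides + 1:
        raise SegmentationError(
            f"need >= {n_strides + 1} heel strikes for {n_strides} strides, "
            f"got {n_events}"
        )
    n_starts = n_events - n_strides
    if start_index == "random":
        rng = np.random.default_rng(seed)
        start = int(rng.integers(n_starts))
    else:
        start = int(start_index)
        if not 0 <= start < n_starts:
            raise SegmentationError(f"start_index {start} out of range [0, {n_starts})")
    hs = events.heel_strike_times[start : start + n_strides + 1]
    rate = trial.sampling_rate
    strides = []
    for k in range(n_strides):
        i0 = int(round((hs[k] - trial.t0) * rate))
        i1 = int(round((hs[k + 1] - trial.t0) * rate))
        channels = {
            name: ch.replace_samples(ch.samples[i0 : i1 + 1])
            for name, ch in trial.channels.items()
        }
        strides.append(
            StrideSeries(
                channels=channels,
                t_start=trial.t0 + i0 / rate,
                duration=(i1 - i0) / rate,
                sampling_rate=rate,
                side=events.side,
            )
        )
    return strides
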