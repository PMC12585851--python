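"""Reading/writing multi-stride gait time-series and assembling validated trials.

Two plain-text dialects are supported:

* a storage dialect with header lines (``name``, ``datacolumns``, ``datarows``,
  ``range``, optional trial metadata, ``endheader``), a tab-separated column
  label row starting with ``time``, then tab-delimited numeric rows — the
  layout common musculoskeletal tools export;
* CSV with a one-line header, first column ``time``.

Time is in seconds, angles in degrees, forces in N, moments in N·m. Missing
values are rejected, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SignalChannel",
    "GaitTrial",
    "GaitFormatError",
    "GaitDataError",
    "SamplingError",
    "read_gait_storage",
    "write_gait_storage",
]

#: absolute tolerance (s) for time-step uniformity
TIME_UNIFORMITY_TOL = 1e-6

CHANNEL_KINDS = ("angle", "moment", "grf_force", "grf_cop", "other")

_KIND_UNITS = {
    "angle": "deg",
    "moment": "N·m",
    "grf_force": "N",
    "grf_cop": "m",
    "other": "",
}


class GaitFormatError(ValueError):
    """Malformed storage header or inconsistent declared shape."""


class GaitDataError(ValueError):
    """Missing (NaN) cells or invariant-violating channel data."""


class SamplingError(ValueError):
    """Non-uniform or invalid time column."""


def infer_channel_kind(name: str) -> str:
    """Guess a channel's physical kind from its name.

    Convention: names containing ``angle`` are joint angles (deg), ``moment``
    joint moments (N·m), ``grf`` + ``cop`` centre-of-pressure positions (m),
    any other ``grf`` a ground-reaction force component (N).
    """
    low = name.lower()
    if "angle" in low:
        return "angle"
    if "moment" in low or "torque" in low:
        return "moment"
    if "cop" in low:
        return "grf_cop"
    if "grf" in low or "force" in low:
        return "grf_force"
    return "other"


@dataclass
class SignalChannel:
    """One named uniform-rate signal (a column of a gait recording)."""

    name: str
    samples: np.ndarray
    kind: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise GaitDataError(f"channel {self.name!r}: samples must be 1-D")
        if self.samples.size < 2:
            raise GaitDataError(
                f"channel {self.name!r}: needs >= 2 samples, got {self.samples.size}"
            )
        if np.isnan(self.samples).any():
            idx = int(np.flatnonzero(np.isnan(self.samples))[0])
            raise GaitDataError(f"channel {self.name!r}: NaN at sample {idx}")
        if not self.kind:
            self.kind = infer_channel_kind(self.name)
        if self.kind not in CHANNEL_KINDS:
            raise GaitDataError(f"channel {self.name!r}: unknown kind {self.kind!r}")
        if not self.units:
            self.units = _KIND_UNITS[self.kind]

    def __len__(self) -> int:
        return int(self.samples.size)

    def replace_samples(self, samples: np.ndarray) -> "SignalChannel":
        return SignalChannel(self.name, np.asarray(samples, float), self.kind, self.units)


@dataclass
class GaitTrial:
    """A multi-stride recording: equal-length uniform-rate channels + metadata.

    ``duration`` is derived, ``(n_samples - 1) / sampling_rate``.
    """

    participant_id: str
    sampling_rate: float
    channels: dict[str, SignalChannel]
    belt_speed: float | None = None
    body_mass: float | None = None
    body_height: float | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise GaitDataError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.channels:
            raise GaitDataError("trial has no channels")
        lengths = {len(ch) for ch in self.channels.values()}
        if len(lengths) != 1:
            raise GaitDataError(f"channels have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> SignalChannel:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"trial has no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def with_channels(self, channels: dict[str, SignalChannel]) -> "GaitTrial":
        return GaitTrial(
            participant_id=self.participant_id,
            sampling_rate=self.sampling_rate,
            channels=channels,
            belt_speed=self.belt_speed,
            body_mass=self.body_mass,
            body_height=self.body_height,
            t0=self.t0,
        )


_META_FIELDS = ("belt_speed", "body_mass", "body_height")


def _validate_time_column(time: np.ndarray) -> float:
    if time.size < 2:
        raise SamplingError("time column needs >= 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise SamplingError("time column must be strictly increasing")
    dt0 = (time[-1] - time[0]) / (time.size - 1)
    if np.max(np.abs(dt - dt0)) > TIME_UNIFORMITY_TOL:
        raise SamplingError(
            f"non-uniform time step: max deviation {np.max(np.abs(dt - dt0)):.3g} s "
            f"exceeds {TIME_UNIFORMITY_TOL} s"
        )
    return 1.0 / dt0


def _assemble_trial(
    names: list[str], data: np.ndarray, meta: dict[str, float | str]
) -> GaitTrial:
    if names[0].lower() != "time":
        raise GaitFormatError(f"first column must be 'time', got {names[0]!r}")
    bad = np.argwhere(np.isnan(data))
    if bad.size:
        r, c = bad[0]
        raise GaitDataError(f"NaN cell at row {int(r)}, column {names[int(c)]!r}")
    rate = _validate_time_column(data[:, 0])
    channels = {
        name: SignalChannel(name, data[:, j + 1]) for j, name in enumerate(names[1:])
    }
    return GaitTrial(
        participant_id=str(meta.get("name", "trial")),
        sampling_rate=rate,
        channels=channels,
        belt_speed=_opt_float(meta.get("belt_speed")),
        body_mass=_opt_float(meta.get("body_mass")),
        body_height=_opt_float(meta.get("body_height")),
        t0=float(data[0, 0]),
    )


def _opt_float(v) -> float | None:
    return None if v is None else float(v)


def read_gait_storage(path: str | Path) -> GaitTrial:
    """Read a gait trial from the storage dialect or CSV (by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    return _read_storage(path)


def _read_storage(path: Path) -> GaitTrial:
    meta: dict[str, float | str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise GaitFormatError(f"{path}: no 'endheader' line") from None
    for ln in lines[:end]:
        ln = ln.strip()
        if not ln:
            continue
        key, _, value = ln.partition(" ")
        meta[key.strip()] = value.strip()
    for required in ("datacolumns", "datarows", "range"):
        if required not in meta:
            raise GaitFormatError(f"{path}: header missing {required!r}")
    ncols = int(meta["datacolumns"])  # includes time
    nrows = int(meta["datarows"])
    t_lo, t_hi = (float(x) for x in str(meta["range"]).split())
    names = lines[end + 1].split("\t")
    if len(names) != ncols:
        raise GaitFormatError(
            f"{path}: header declares {ncols} columns, label row has {len(names)}"
        )
    body = [ln for ln in lines[end + 2 :] if ln.strip()]
    if len(body) != nrows:
        raise GaitFormatError(f"{path}: header declares {nrows} rows, found {len(body)}")
    try:
        data = np.array([[float(x) for x in ln.split("\t")] for ln in body])
    except ValueError as exc:
        raise GaitDataError(f"{path}: non-numeric cell ({exc})") from None
    if data.shape[1] != ncols:
        raise GaitFormatError(f"{path}: row width != declared {ncols} columns")
    if abs(data[0, 0] - t_lo) > TIME_UNIFORMITY_TOL or abs(data[-1, 0] - t_hi) > TIME_UNIFORMITY_TOL:
        raise GaitFormatError(
            f"{path}: declared range [{t_lo}, {t_hi}] does not match time column"
        )
    return _assemble_trial(names, data, meta)


def _read_csv(path: Path) -> GaitTrial:
    with open(path) as fh:
        header = fh.readline().strip()
        names = [s.strip() for s in header.split(",")]
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise GaitDataError(f"{path}: {exc}") from None
    if data.shape[1] != len(names):
        raise GaitFormatError(f"{path}: row width != header width {len(names)}")
    return _assemble_trial(names, data, {"name": path.stem})


def write_gait_storage(trial: GaitTrial, path: str | Path) -> None:
    """Write a trial; round-trips through :func:`read_gait_storage` losslessly
    at 15 significant digits. CSV is chosen for a ``.csv`` extension."""
    path = Path(path)
    time = trial.time
    cols = [time] + [ch.samples for ch in trial.channels.values()]
    names = ["time"] + list(trial.channels)
    data = np.column_stack(cols)
    if path.suffix.lower() == ".csv":
        with open(path, "w") as fh:
            fh.write(",".join(names) + "\n")
            for row in data:
                fh.write(",".join(_fmt(x) for x in row) + "\n")
        return
    with open(path, "w") as fh:
        fh.write(f"name {trial.participant_id}\n")
        fh.write(f"datacolumns {data.shape[1]}\n")
        fh.write(f"datarows {data.shape[0]}\n")
        fh.write(f"range {_fmt(time[0])} {_fmt(time[-1])}\n")
        for key in _META_FIELDS:
            val = getattr(trial, key)
            if val is not None:
                fh.write(f"{key} {_fmt(val)}\n")
        fh.write("endheader\n")
        fh.write("\t".join(names) + "\n")
        for row in data:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def _fmt(x: float) -> str:
    return format(float(x), ".15g")
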