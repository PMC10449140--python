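"""Domain containers and plain-text readers/writers.

A :class:`Recording` is a uniformly sampled single-channel scalp voltage
trace.  Samples are stored internally in **volts**; readers convert from
microvolts on request.  An :class:`EventSeries` holds oddball stimulus
onsets in seconds from the start of the recording.  All analysis
parameters live in :class:`AnalysisConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Recording",
    "EventSeries",
    "AnalysisConfig",
    "ParseError",
    "read_recording",
    "read_events",
    "write_recording",
    "write_events",
    "write_report",
]

#: recognised filter setups (see :mod:`bciwall.prefilter`)
FILTER_SETUPS = ("fullband", "delta", "wide", "alpha", "derivative")


class ParseError(ValueError):
    """Raised when a text input file cannot be parsed."""


@dataclass
class Recording:
    """A single-channel EEG voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in volts.
    fs : float
        Sampling rate in Hz.
    subject, task, channel : str
        Free-text labels (e.g. ``"s20"``, ``"jaw_clench"``, ``"Cz-A2"``).
    filtered_with : str or None
        Provenance flag: name of the filter setup already applied, or
        ``None`` for a raw trace.
    """

    samples: np.ndarray
    fs: float
    subject: str = ""
    task: str = ""
    channel: str = ""
    filtered_with: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs

    def replace(self, **kw) -> "Recording":
        return dataclasses.replace(self, **kw)


@dataclass
class EventSeries:
    """Strictly increasing stimulus-onset times in seconds."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("event times must be one-dimensional")
        if self.times.size and self.times[0] < 0:
            raise ValueError("event times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def validate_against(self, rec: Recording) -> None:
        """Check that every event lies inside the recording."""
        if self.times.size and self.times[-1] >= rec.duration_s:
            raise ValueError(
                f"event at {self.times[-1]:g} s lies beyond the recording "
                f"({rec.duration_s:g} s)"
            )


@dataclass
class AnalysisConfig:
    """All tunable parameters of the detectability analysis.

    The defaults follow the reference analysis: a 2 s sliding window for
    the noise-variance scan, 50 Hz mains, a 40 % conscious band-power
    reduction for frequency-domain (desynchronisation) BCIs, and a 0.05
    test level for the group statistics.
    """

    window_s: float = 2.0
    stride: int = 1
    filter_setup: str = "fullband"
    mains_hz: float = 50.0
    reduction_fraction: float = 0.40
    snr_mode: str = "time"  # "time" | "frequency"
    freq_power_convention: str = "power_scaled"  # | "amplitude_scaled"
    alpha_level: float = 0.05
    discard_startup_s: float = 2.0
    fs: float = 250.0
    # evoked-averaging parameters (ms relative to stimulus onset)
    epoch_pre_ms: float = 200.0
    epoch_post_ms: float = 600.0
    search_start_ms: float = 150.0
    search_stop_ms: float = 500.0
    peak_smooth_ms: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.reduction_fraction < 1:
            raise ValueError("reduction_fraction must be in (0, 1)")
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")
        if self.filter_setup not in FILTER_SETUPS:
            raise ValueError(
                f"unknown filter setup {self.filter_setup!r}; "
                f"expected one of {FILTER_SETUPS}"
            )
        if self.snr_mode not in ("time", "frequency"):
            raise ValueError("snr_mode must be 'time' or 'frequency'")
        if self.freq_power_convention not in ("power_scaled", "amplitude_scaled"):
            raise ValueError(
                "freq_power_convention must be 'power_scaled' or 'amplitude_scaled'"
            )
        if self.stride < 1:
            raise ValueError("stride must be >= 1 sample")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a flat key/value YAML file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_NUM_SPLIT = re.compile(r"[,\s]+")


def _parse_table(path: str | Path) -> tuple[list[list[float]], int]:
    """Parse a whitespace/comma delimited numeric table.

    Returns the rows and the (constant) column count.  Raises
    :class:`ParseError` naming the offending line on bad input.
    """
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _NUM_SPLIT.split(line) if p]
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if ncol is None:
                ncol = len(values)
            elif len(values) != ncol:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol} columns, "
                    f"got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no numeric data found")
    return rows, ncol or 0


def read_recording(
    path: str | Path,
    fs: float,
    unit: str = "V",
    column: int = 0,
    subject: str = "",
    task: str = "",
    channel: str = "",
) -> Recording:
    """Read a voltage trace from a delimited text table.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (the file itself carries no rate).
    unit : {"V", "uV"}
        Unit of the stored numbers; microvolt input is converted to volts.
    column : int
        Zero-based column holding the samples in a multi-column file.
    """
    if unit not in ("V", "uV"):
        raise ValueError(f"unit must be 'V' or 'uV', got {unit!r}")
    rows, ncol = _parse_table(path)
    if column >= ncol:
        raise ParseError(f"{path}: column {column} requested but file has {ncol}")
    samples = np.array([r[column] for r in rows])
    if unit == "uV":
        samples = samples / 1e6
    return Recording(samples, fs=fs, subject=subject, task=task, channel=channel)


def read_events(path: str | Path, recording: Recording | None = None) -> EventSeries:
    """Read stimulus onsets (seconds, one per line).

    Out-of-order input is an error, never silently sorted.  An empty file
    yields an empty series.  If *recording* is given, events beyond its
    duration are rejected.
    """
    times: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                t = float(line)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if t < 0:
                raise ParseError(f"{path}: line {lineno}: negative event time {t}")
            if times and t <= times[-1]:
                raise ParseError(
                    f"{path}: line {lineno}: events not strictly increasing "
                    f"({t} after {times[-1]})"
                )
            times.append(t)
    series = EventSeries(np.array(times))
    if recording is not None:
        series.validate_against(recording)
    return series


def write_recording(rec: Recording, path: str | Path, unit: str = "V") -> None:
    """Write samples one per line, in volts (default) or microvolts."""
    x = rec.samples if unit == "V" else rec.samples * 1e6
    np.savetxt(path, x, fmt="%.18e")


def write_events(events: EventSeries, path: str | Path) -> None:
    np.savetxt(path, events.times, fmt="%.6f")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if obj == float("inf"):
        return "inf"
    return obj


def write_report(results, path: str | Path) -> None:
    """Dump a result bundle (dataclass / dict) as JSON with stable key order."""
    payload = _jsonable(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
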