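"""Multichannel recording container, EO/EC condition schedules, and text I/O.

A :class:`Recording` is a channels x samples float matrix with a sampling
rate and a condition schedule (half-open ``[start, end)`` intervals in
seconds labelled ``"EO"`` or ``"EC"``).  Recordings round-trip through a
documented delimited text format: ``#``-prefixed header lines carry the
rate, channel names and schedule, then one whitespace-separated row of
samples per channel.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Interval",
    "Recording",
    "eo_ec_schedule",
    "write_recording",
    "read_recording_text",
    "HYDROCEL_TOTAL_CHANNELS",
    "HYDROCEL_CHIN_NECK_CHANNELS",
    "HYDROCEL_OCULAR_CHANNELS",
    "n_analysis_channels",
]

# 128-channel geodesic net accounting: a ring of 17 chin/neck electrodes is
# excluded at preprocessing, and the 4 periocular electrodes used for ocular
# regression are dropped afterwards, leaving the scalp analysis montage.
HYDROCEL_TOTAL_CHANNELS = 128
HYDROCEL_CHIN_NECK_CHANNELS = 17
HYDROCEL_OCULAR_CHANNELS = ("E8", "E14", "E21", "E25")


def n_analysis_channels(
    total: int = HYDROCEL_TOTAL_CHANNELS,
    n_chin_neck: int = HYDROCEL_CHIN_NECK_CHANNELS,
    n_ocular: int = len(HYDROCEL_OCULAR_CHANNELS),
) -> int:
    """Number of scalp channels entering analysis after montage exclusions."""
    n = total - n_chin_neck - n_ocular
    if n <= 0:
        raise ValueError("montage exclusions leave no analysis channels")
    return n


@dataclass(frozen=True)
class Interval:
    """Half-open condition interval [start, end) in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"interval end must exceed start: {self}")
        if self.label not in ("EO", "EC"):
            raise ValueError(f"condition label must be 'EO' or 'EC', got {self.label!r}")


def eo_ec_schedule(
    duration: float, eo_seconds: float = 20.0, ec_seconds: float = 40.0
) -> tuple[Interval, ...]:
    """Alternating eyes-open/eyes-closed block schedule starting with EO.

    The default 20 s EO / 40 s EC cycle over 300 s yields 100 s EO and
    200 s EC.  The final block is truncated at ``duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    out: list[Interval] = []
    t = 0.0
    while t < duration - 1e-12:
        for label, block in (("EO", eo_seconds), ("EC", ec_seconds)):
            if t >= duration - 1e-12:
                break
            end = min(t + block, duration)
            out.append(Interval(t, end, label))
            t = end
    return tuple(out)


@dataclass
class Recording:
    """channels x samples signal matrix with rate (Hz) and EO/EC schedule."""

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...] = ()
    schedule: tuple[Interval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i + 1:02d}" for i in range(self.data.shape[0])
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def condition_at(self, t: float) -> str:
        """Condition label at time ``t`` seconds (half-open interval lookup)."""
        for iv in self.schedule:
            if iv.start <= t < iv.end:
                return iv.label
        if self.schedule and abs(t - self.schedule[-1].end) < 1e-9:
            return self.schedule[-1].label
        raise ValueError(f"time {t} s is not covered by the schedule")


def _schedule_to_str(schedule: tuple[Interval, ...]) -> str:
    return ";".join(f"{iv.start:g}-{iv.end:g}:{iv.label}" for iv in schedule)


def _schedule_from_str(s: str) -> tuple[Interval, ...]:
    out = []
    for part in s.split(";"):
        if not part:
            continue
        span, label = part.rsplit(":", 1)
        start, end = span.split("-")
        out.append(Interval(float(start), float(end), label))
    return tuple(out)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the delimited text format (one channel per row)."""
    path = Path(path)
    with io.StringIO() as buf:
        buf.write(f"# rate: {rec.rate:g}\n")
        buf.write(f"# channels: {','.join(rec.channel_names)}\n")
        buf.write(f"# schedule: {_schedule_to_str(rec.schedule)}\n")
        np.savetxt(buf, rec.data, fmt="%.8g")
        path.write_text(buf.getvalue())


def read_recording_text(path: str | Path) -> Recording:
    """Read a recording from the delimited text format.

    Raises a :class:`ValueError` naming the offending line on ragged rows
    and on missing headers.
    """
    path = Path(path)
    rate = None
    names: tuple[str, ...] = ()
    schedule: tuple[Interval, ...] = ()
    rows: list[np.ndarray] = []
    row_len = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("rate:"):
                    rate = float(body.split(":", 1)[1])
                elif body.startswith("channels:"):
                    names = tuple(
                        n.strip() for n in body.split(":", 1)[1].split(",") if n.strip()
                    )
                elif body.startswith("schedule:"):
                    schedule = _schedule_from_str(body.split(":", 1)[1].strip())
                continue
            vals = np.fromstring(line, sep=" ")
            if row_len is None:
                row_len = vals.size
            elif vals.size != row_len:
                raise ValueError(
                    f"{path}:{lineno}: row has {vals.size} samples, expected {row_len}"
                )
            rows.append(vals)
    if rate is None:
        raise ValueError(f"{path}: missing '# rate:' header")
    if not rows:
        raise ValueError(f"{path}: no channel rows found")
    return Recording(np.vstack(rows), rate, names, schedule)


def read_recording_edf(path: str | Path, schedule_path: str | Path | None = None) -> Recording:
    """Read an EDF recording, taking the EO/EC schedule from a sidecar text file.

    The sidecar holds one ``start-end:LABEL`` interval specification (the same
    syntax used in the delimited format header).  EDF files rarely carry the
    block schedule, so a missing sidecar is an explicit error.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne present in supported envs
        raise ImportError("reading EDF requires the 'mne' package") from exc

    path = Path(path)
    if schedule_path is None:
        schedule_path = path.with_suffix(".schedule.txt")
    schedule_path = Path(schedule_path)
    if not schedule_path.exists():
        raise FileNotFoundError(
            f"EDF schedule sidecar not found: expected {schedule_path} with "
            "';'-separated 'start-end:EO|EC' intervals"
        )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    schedule = _schedule_from_str(schedule_path.read_text().strip())
    return Recording(
        raw.get_data(), float(raw.info["sfreq"]), tuple(raw.ch_names), schedule
    )
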