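"""Reading, writing and validation of sensor streams and activity-label tracks.

Sensor data arrive as CSV files with one row per sample: an epoch-millisecond
``timestamp`` column plus either tri-axial ``x``, ``y``, ``z`` columns or a
single ``magnitude`` column.  Accelerometer values are in g (1 g = 9.81 m/s^2,
gravity included), gyroscope values in radians/second, and the nominal
sampling rate is 10 Hz.  Ground-truth activity labels arrive as CSV interval
tracks (``start``, ``end``, ``activity``).

Timestamps are authoritative for aligning samples to labels; windowing
downstream is index-based at the declared nominal rate.  Irregular sampling is
detected and warned about, never resampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("movelets")

SENSOR_KINDS = ("accelerometer", "gyroscope")
PLACEMENTS = ("front_pocket", "back_pocket", "other")

#: Units carried as metadata, never converted.
SENSOR_UNITS = {"accelerometer": "g", "gyroscope": "rad/s"}


class MoveletsError(Exception):
    """Base class for all package errors."""


class FormatError(MoveletsError):
    """A file could not be parsed into the expected columns/types."""


class ValidationError(MoveletsError):
    """Parsed data violate a structural invariant."""


class InsufficientDataError(MoveletsError):
    """Fewer samples are available than an operation requires."""


class MissingActivityError(MoveletsError):
    """A requested activity has no labeled interval."""


# ---------------------------------------------------------------------------
# Sensor streams
# ---------------------------------------------------------------------------

@dataclass
class SensorStream:
    """A uniformly indexed, timestamped stream from one sensor/placement.

    Parameters
    ----------
    sensor_kind : {"accelerometer", "gyroscope"}
    placement : {"front_pocket", "back_pocket", "other"}
    rate_h : float
        Nominal sampling frequency h in samples/second (10 for the study
        protocol this package targets).
    timestamps : ndarray, shape (N,)
        Sample times in seconds (epoch-derived), strictly increasing.
    values : ndarray, shape (N, C)
        One row per sample; C = 3 for tri-axial data (x, y, z in the phone
        frame) or 1 for magnitude data.
    channels : tuple of str
        ``("x", "y", "z")`` or ``("magnitude",)``.
    gaps : list of (int, float, float)
        Sampling gaps detected on read: ``(left_index, t_left, t_right)``
        for each consecutive pair further apart than ``2 / rate_h``.
    """

    sensor_kind: str
    placement: str
    rate_h: float
    timestamps: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...] = ("x", "y", "z")
    gaps: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValidationError(f"unknown sensor_kind {self.sensor_kind!r}")
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"unknown placement {self.placement!r}")
        if not self.rate_h > 0:
            raise ValidationError(f"rate_h must be positive, got {self.rate_h}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValidationError(
                f"{self.timestamps.shape[0]} timestamps but "
                f"{self.values.shape[0]} sample rows"
            )
        if self.n_samples == 0:
            raise ValidationError("empty stream")
        if len(self.channels) not in (1, 3):
            raise ValidationError("channel count must be 1 or 3")
        if self.values.shape[1] != len(self.channels):
            raise ValidationError(
                f"values have {self.values.shape[1]} columns for "
                f"{len(self.channels)} channels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite sample values")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValidationError("non-finite timestamps")
        if self.n_samples > 1 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0))
            raise ValidationError(
                f"timestamps not strictly increasing at row {bad + 1}"
            )

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def data_type(self) -> str:
        """``"triaxial"`` or ``"magnitude"``, inferred from the channels."""
        return "magnitude" if self.channels == ("magnitude",) else "triaxial"

    @property
    def units(self) -> str:
        return SENSOR_UNITS[self.sensor_kind]

    def slice(self, start: int, stop: int) -> "SensorStream":
        """Contiguous sample-index slice ``[start, stop)`` as a new stream."""
        if not 0 <= start < stop <= self.n_samples:
            raise InsufficientDataError(
                f"slice [{start}, {stop}) outside stream of {self.n_samples}"
            )
        gaps = [
            (g[0] - start, g[1], g[2])
            for g in self.gaps
            if start <= g[0] < stop - 1
        ]
        return replace(
            self,
            timestamps=self.timestamps[start:stop].copy(),
            values=self.values[start:stop].copy(),
            gaps=gaps,
        )


def detect_gaps(
    timestamps: np.ndarray, rate_h: float
) -> list[tuple[int, float, float]]:
    """Find consecutive-sample spacings larger than ``2 / rate_h``.

    Returns ``(left_index, t_left, t_right)`` per gap.  At a nominal 10 Hz
    the tolerance is 0.2 s: anything beyond two nominal sample periods is
    treated as missing data rather than jitter.
    """
    dt = np.diff(timestamps)
    idx = np.nonzero(dt > 2.0 / rate_h)[0]
    return [(int(i), float(timestamps[i]), float(timestamps[i + 1])) for i in idx]


def read_stream(
    path: str | Path,
    sensor_kind: str,
    placement: str = "front_pocket",
    rate_h: float = 10.0,
    timestamp_col: str = "timestamp",
    channel_cols: Sequence[str] | None = None,
) -> SensorStream:
    """Read a sensor CSV into a validated :class:`SensorStream`.

    The timestamp column holds epoch milliseconds and is converted to
    seconds.  ``channel_cols`` defaults to ``("x", "y", "z")`` when present,
    else ``("magnitude",)``.  Sampling gaps larger than ``2 / rate_h`` are
    recorded on the stream and logged as warnings with their locations.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    if frame.empty:
        raise ValidationError(f"{path}: no sample rows")
    if timestamp_col not in frame.columns:
        raise FormatError(f"{path}: missing timestamp column {timestamp_col!r}")
    if channel_cols is None:
        if {"x", "y", "z"}.issubset(frame.columns):
            channel_cols = ("x", "y", "z")
        elif "magnitude" in frame.columns:
            channel_cols = ("magnitude",)
        else:
            raise FormatError(f"{path}: expected columns x,y,z or magnitude")
    missing = [c for c in channel_cols if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing channel columns {missing}")
    try:
        ts = frame[timestamp_col].to_numpy(dtype=float) / 1000.0
        vals = frame[list(channel_cols)].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric data ({exc})") from exc

    gaps = detect_gaps(ts, rate_h)
    stream = SensorStream(
        sensor_kind=sensor_kind,
        placement=placement,
        rate_h=rate_h,
        timestamps=ts,
        values=vals,
        channels=tuple(channel_cols),
        gaps=gaps,
    )
    for _, t0, t1 in gaps:
        msg = f"{path}: sampling gap ({t0:.3f} s, {t1:.3f} s) exceeds 2/h"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    return stream


def write_stream(stream: SensorStream, path: str | Path) -> None:
    """Write a stream back to the sensor CSV format (epoch-ms timestamps)."""
    frame = pd.DataFrame(
        {"timestamp": np.round(stream.timestamps * 1000.0).astype(np.int64)}
    )
    for j, name in enumerate(stream.channels):
        frame[name] = stream.values[:, j]
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Label tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelInterval:
    start: float
    end: float
    activity: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"interval start {self.start} must precede end {self.end}"
            )


@dataclass
class LabelTrack:
    """Ground-truth activity labels as non-overlapping [start, end) intervals."""

    intervals: list[LabelInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping intervals: ({a.start}, {a.end}, {a.activity!r})"
                    f" and ({b.start}, {b.end}, {b.activity!r})"
                )
        self.intervals = ordered

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def activities(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.activity, None)
        return list(seen)

    def label_at(self, t: float) -> str | None:
        """Label of the interval containing ``t`` under [start, end); None if
        ``t`` is uncovered."""
        for iv in self.intervals:
            if iv.start <= t < iv.end:
                return iv.activity
        return None

    def intervals_for(self, activity: str) -> list[LabelInterval]:
        return [iv for iv in self.intervals if iv.activity == activity]


def label_at(track: LabelTrack, t: float) -> str | None:
    """Functional alias for :meth:`LabelTrack.label_at`."""
    return track.label_at(t)


def read_labels(path: str | Path, time_unit: str = "s") -> LabelTrack:
    """Read a label CSV (columns start, end, activity) into a LabelTrack.

    ``time_unit`` is ``"s"`` (default) or ``"ms"`` for epoch-millisecond
    interval bounds.  An empty file yields an empty track with a warning.
    """
    path = Path(path)
    if time_unit not in ("s", "ms"):
        raise ValueError(f"time_unit must be 's' or 'ms', got {time_unit!r}")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty label file", stacklevel=2)
        return LabelTrack([])
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = {"start", "end", "activity"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        warnings.warn(f"{path}: no label rows", stacklevel=2)
        return LabelTrack([])
    scale = 1000.0 if time_unit == "ms" else 1.0
    intervals = [
        LabelInterval(float(r.start) / scale, float(r.end) / scale, str(r.activity))
        for r in frame.itertuples()
    ]
    return LabelTrack(intervals)


def write_labels(track: LabelTrack, path: str | Path) -> None:
    pd.DataFrame(
        [(iv.start, iv.end, iv.activity) for iv in track.intervals],
        columns=["start", "end", "activity"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Classification results
# ---------------------------------------------------------------------------

CLASSIFICATION_COLUMNS = ["t", "predicted_label", "vote_proportion", "n_votes"]


def write_classification(result, path: str | Path) -> None:
    """Write a classification to CSV.

    Columns: ``t, predicted_label, vote_proportion, n_votes`` plus, when
    uncertainty quantification has been applied, ``correct_probability`` and
    ``excluded``.  Exclusion is a flag, not a deletion: excluded rows keep
    their predicted label.

    ``result`` is anything exposing ``to_frame()`` with those columns
    (a :class:`movelets.classifier.Classification`) or a DataFrame.
    """
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    for col in CLASSIFICATION_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"classification frame missing column {col!r}")
    frame.to_csv(path, index=False)


def read_classification(path: str | Path) -> pd.DataFrame:
    """Read a classification CSV back as a DataFrame (inverse of write)."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
    missing = [c for c in CLASSIFICATION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return frame
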