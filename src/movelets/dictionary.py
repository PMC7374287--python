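"""Per-subject movelet dictionaries built from brief training bouts.

A dictionary maps each activity to the movelets extracted from a short
training segment of that activity — four seconds per activity suffices, and
when a labeled bout is longer its middle four seconds are used.  The
dictionary carries enough provenance (subject, sensor, placement, data type,
sampling rate, window length, activity order) to make classification and
tie-breaking fully deterministic and reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    InsufficientDataError,
    LabelTrack,
    MissingActivityError,
    SensorStream,
    ValidationError,
)
from .transforms import Movelet, extract_movelets, window_samples

__all__ = [
    "DEFAULT_ACTIVITIES",
    "Dictionary",
    "select_training_segment",
    "build_dictionary",
    "save_dictionary",
    "load_dictionary",
]

#: The seven study activities; a chair stand decomposes into standToSit,
#: sit and sitToStand.
DEFAULT_ACTIVITIES = (
    "stand",
    "walk",
    "stairsUp",
    "stairsDown",
    "standToSit",
    "sit",
    "sitToStand",
)


@dataclass
class Dictionary:
    """Ordered map activity -> dictionary movelets, plus provenance."""

    subject_id: str
    sensor_kind: str
    placement: str
    data_type: str  # "triaxial" | "magnitude"
    rate_h: float
    window_seconds: float
    entries: dict[str, list[Movelet]] = field(default_factory=dict)
    activity_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("dictionary needs at least one activity entry")
        if not self.activity_order:
            self.activity_order = list(self.entries)
        if set(self.activity_order) != set(self.entries):
            raise ValidationError("activity_order must match entry keys")
        n = self.n
        c = 3 if self.data_type == "triaxial" else 1
        for activity, movelets in self.entries.items():
            if not movelets:
                raise ValidationError(f"empty entry for {activity!r}")
            for m in movelets:
                if m.n != n or m.n_channels != c:
                    raise ValidationError(
                        f"movelet shape {(m.n, m.n_channels)} in {activity!r} "
                        f"inconsistent with dictionary ({n}, {c})"
                    )

    @property
    def n(self) -> int:
        """Samples per movelet window."""
        first = next(iter(self.entries.values()))
        return first[0].n

    @property
    def n_movelets(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def entry_sizes(self) -> dict[str, int]:
        return {a: len(self.entries[a]) for a in self.activity_order}


def select_training_segment(
    stream: SensorStream,
    track: LabelTrack,
    activity: str,
    duration_seconds: float = 4.0,
    window_seconds: float = 1.0,
) -> SensorStream:
    """Slice the training segment for one activity out of a labeled stream.

    When the activity has several labeled intervals the longest is used
    (ties: earliest).  When more than ``duration_seconds`` of data are
    available the middle ``duration_seconds`` are used; shorter bouts (e.g.
    posture transitions) are used whole, with a warning.  The returned slice
    must still fit at least one movelet window.
    """
    intervals = track.intervals_for(activity)
    if not intervals:
        raise MissingActivityError(f"no labeled interval for {activity!r}")
    chosen = max(intervals, key=lambda iv: (iv.end - iv.start, -iv.start))

    inside = np.nonzero(
        (stream.timestamps >= chosen.start) & (stream.timestamps < chosen.end)
    )[0]
    if inside.size == 0:
        raise InsufficientDataError(
            f"no samples inside interval for {activity!r}"
        )
    seg_start, seg_stop = int(inside[0]), int(inside[-1]) + 1
    n_seg = seg_stop - seg_start

    n_target = int(round(duration_seconds * stream.rate_h))
    n_window = window_samples(window_seconds, stream.rate_h)
    if n_seg < n_window:
        raise InsufficientDataError(
            f"{activity!r}: segment of {n_seg} samples cannot fit one "
            f"{n_window}-sample window"
        )
    if n_seg <= n_target:
        if n_seg < n_target:
            warnings.warn(
                f"{activity!r}: only {n_seg / stream.rate_h:.1f} s available "
                f"of the requested {duration_seconds:.1f} s; using all of it",
                stacklevel=2,
            )
        return stream.slice(seg_start, seg_stop)
    offset = (n_seg - n_target) // 2
    return stream.slice(seg_start + offset, seg_start + offset + n_target)


def build_dictionary(
    stream: SensorStream,
    track: LabelTrack,
    activities: tuple[str, ...] | list[str] = DEFAULT_ACTIVITIES,
    duration_seconds: float = 4.0,
    window_seconds: float = 1.0,
    subject_id: str = "subject",
) -> Dictionary:
    """Build a per-subject dictionary from a labeled training stream.

    Entry sizes follow the sliding-window count law: a selected segment of
    N_a samples yields N_a - n + 1 movelets.  The input order of
    ``activities`` becomes the canonical tie-breaking order.
    """
    entries: dict[str, list[Movelet]] = {}
    for activity in activities:
        segment = select_training_segment(
            stream, track, activity, duration_seconds, window_seconds
        )
        entries[activity] = extract_movelets(segment, window_seconds)
    return Dictionary(
        subject_id=subject_id,
        sensor_kind=stream.sensor_kind,
        placement=stream.placement,
        data_type=stream.data_type,
        rate_h=stream.rate_h,
        window_seconds=window_seconds,
        entries=entries,
        activity_order=list(activities),
    )


# ---------------------------------------------------------------------------
# Serialization: a directory with metadata.json plus one CSV per activity of
# stacked movelet rows (columns: movelet, start_time, start_index, channels).
# ---------------------------------------------------------------------------

def save_dictionary(dictionary: Dictionary, dirpath: str | Path) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": dictionary.subject_id,
        "sensor_kind": dictionary.sensor_kind,
        "placement": dictionary.placement,
        "data_type": dictionary.data_type,
        "rate_h": dictionary.rate_h,
        "window_seconds": dictionary.window_seconds,
        "activity_order": dictionary.activity_order,
        "channels": list(next(iter(dictionary.entries.values()))[0].channels),
    }
    (dirpath / "metadata.json").write_text(json.dumps(meta, indent=2))
    for activity in dictionary.activity_order:
        rows = []
        for k, m in enumerate(dictionary.entries[activity]):
            for i in range(m.n):
                rows.append(
                    (k, m.start_time, m.start_index, *m.values[i])
                )
        channels = dictionary.entries[activity][0].channels
        frame = pd.DataFrame(
            rows, columns=["movelet", "start_time", "start_index", *channels]
        )
        frame.to_csv(dirpath / f"{activity}.csv", index=False)


def load_dictionary(dirpath: str | Path) -> Dictionary:
    dirpath = Path(dirpath)
    meta_path = dirpath / "metadata.json"
    if not meta_path.exists():
        raise ValidationError(f"{dirpath}: not a dictionary (no metadata.json)")
    meta = json.loads(meta_path.read_text())
    channels = tuple(meta["channels"])
    entries: dict[str, list[Movelet]] = {}
    for activity in meta["activity_order"]:
        frame = pd.read_csv(dirpath / f"{activity}.csv")
        movelets = []
        for k, group in frame.groupby("movelet", sort=True):
            movelets.append(
                Movelet(
                    start_time=float(group["start_time"].iloc[0]),
                    start_index=int(group["start_index"].iloc[0]),
                    values=group[list(channels)].to_numpy(dtype=float),
                    channels=channels,
                )
            )
        entries[activity] = movelets
    return Dictionary(
        subject_id=meta["subject_id"],
        sensor_kind=meta["sensor_kind"],
        placement=meta["placement"],
        data_type=meta["data_type"],
        rate_h=float(meta["rate_h"]),
        window_seconds=float(meta["window_seconds"]),
        entries=entries,
        activity_order=list(meta["activity_order"]),
    )
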