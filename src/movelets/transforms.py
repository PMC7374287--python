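"""Data transforms: vector magnitude, pocket-orientation sign flips, and
movelet (sliding window) extraction.

A movelet is a fixed-length window of consecutive samples — by default one
second, so n = h samples at sampling rate h — and is the atomic unit matched
between incoming data and a subject's dictionary.  The magnitude transform
collapses the tri-axial channels to sqrt(x^2 + y^2 + z^2), which discards the
phone's orientation; the reorientation transform maps data between the four
ways a phone can sit in a pants pocket, each pair of orientations related by
a rigid 180-degree rotation that negates exactly two of the three axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import InsufficientDataError, SensorStream

__all__ = [
    "Movelet",
    "Orientation",
    "REFERENCE_ORIENTATION",
    "ALL_ORIENTATIONS",
    "magnitude",
    "reorient",
    "orientation_signs",
    "extract_movelets",
    "window_samples",
]


@dataclass(frozen=True)
class Movelet:
    """One fixed-length window of a stream.

    ``values`` has shape (n, C): n consecutive samples over the window,
    C channels matching the source stream (3 tri-axial or 1 magnitude).
    """

    start_time: float
    start_index: int
    values: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.atleast_2d(np.asarray(self.values, dtype=float))
        )
        if self.n < 2:
            raise ValueError(f"movelet needs >= 2 samples, got {self.n}")
        if self.values.shape[1] != len(self.channels):
            raise TypeError(
                f"{self.values.shape[1]} value columns for "
                f"{len(self.channels)} channels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite movelet values")

    @property
    def n(self) -> int:
        """Samples per window (n = window_seconds * h)."""
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Orientation:
    """One of the four ways a phone sits in a front pants pocket.

    The reference orientation — upside down with the screen against the
    leg — is how training data are collected.
    """

    upside_down: bool = True
    screen_to_leg: bool = True

    def __str__(self) -> str:
        ud = "upside_down" if self.upside_down else "right_side_up"
        st = "screen_to_leg" if self.screen_to_leg else "screen_out"
        return f"{ud}/{st}"


REFERENCE_ORIENTATION = Orientation(upside_down=True, screen_to_leg=True)
ALL_ORIENTATIONS = (
    Orientation(True, True),
    Orientation(True, False),
    Orientation(False, True),
    Orientation(False, False),
)


def orientation_signs(frm: Orientation, to: Orientation) -> np.ndarray:
    """Axis sign pattern mapping data in frame ``frm`` into frame ``to``.

    Each single change of orientation is a 180-degree rotation of the phone
    that negates exactly two axes in its (x, y, z) frame:

    * flipping which side the screen faces = rotation about the phone's
      y-axis -> negate x and z;
    * flipping upside-down/right-side-up while keeping the screen side =
      rotation about the z-axis -> negate x and y;
    * flipping both = rotation about the x-axis -> negate y and z.

    Every pattern is self-inverse, so the same signs map in either direction.
    """
    flip_ud = frm.upside_down != to.upside_down
    flip_screen = frm.screen_to_leg != to.screen_to_leg
    if not flip_ud and not flip_screen:
        return np.array([1.0, 1.0, 1.0])
    if flip_screen and not flip_ud:
        return np.array([-1.0, 1.0, -1.0])
    if flip_ud and not flip_screen:
        return np.array([-1.0, -1.0, 1.0])
    return np.array([1.0, -1.0, -1.0])


def reorient(stream: SensorStream, frm: Orientation, to: Orientation) -> SensorStream:
    """Map a tri-axial stream recorded in orientation ``frm`` into ``to``.

    Timestamps are unchanged.  Magnitude streams cannot be reoriented
    (orientation information is already gone).
    """
    if stream.n_channels != 3:
        raise TypeError("reorient requires a 3-channel (tri-axial) stream")
    signs = orientation_signs(frm, to)
    return replace(stream, values=stream.values * signs)


def magnitude(stream: SensorStream) -> SensorStream:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) as a 1-channel stream.

    Standing accelerometer data with gravity on the y-axis, (0, 1, 0) g,
    map to a constant 1 g.
    """
    if stream.n_channels != 3:
        raise TypeError("magnitude requires a 3-channel (tri-axial) stream")
    mag = np.linalg.norm(stream.values, axis=1)
    return replace(stream, values=mag[:, None], channels=("magnitude",))


def window_samples(window_seconds: float, rate_h: float) -> int:
    """Samples per movelet: n = round(window_seconds * rate_h), minimum 2."""
    n = int(round(window_seconds * rate_h))
    if n < 2:
        raise ValueError(
            f"window of {window_seconds} s at {rate_h} Hz gives n={n} < 2"
        )
    return n


def extract_movelets(
    stream: SensorStream, window_seconds: float = 1.0
) -> list[Movelet]:
    """Slide an n-sample window one sample at a time along the stream.

    The left edge starts at the first sample and the last window ends at the
    final sample, yielding exactly N - n + 1 movelets for N samples.  Windows
    spanning a flagged sampling gap are not one contiguous second of data and
    are dropped with a warning.
    """
    n = window_samples(window_seconds, stream.rate_h)
    N = stream.n_samples
    if N < n:
        raise InsufficientDataError(
            f"need at least {n} samples for a {window_seconds} s window, "
            f"have {N}"
        )
    sw = np.lib.stride_tricks.sliding_window_view(stream.values, n, axis=0)
    # sliding_window_view gives (N-n+1, C, n); movelets store (n, C)
    gap_lefts = [g[0] for g in stream.gaps]
    movelets: list[Movelet] = []
    dropped = 0
    for i in range(N - n + 1):
        # window covers samples i .. i+n-1; a gap at left-index j sits inside
        # when i <= j <= i+n-2
        if any(i <= j <= i + n - 2 for j in gap_lefts):
            dropped += 1
            continue
        movelets.append(
            Movelet(
                start_time=float(stream.timestamps[i]),
                start_index=i,
                values=sw[i].T.copy(),
                channels=stream.channels,
            )
        )
    if dropped:
        warnings.warn(
            f"dropped {dropped} movelet(s) spanning sampling gaps", stacklevel=2
        )
    return movelets
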