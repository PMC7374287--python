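"""Seeded generator of labeled tri-axial accelerometer + gyroscope streams.

The generator emulates the structure of a pocket-phone activity study at a
nominal 10 Hz: stationary postures carry a gravity-bearing accelerometer
baseline (+1 g on the phone's y-axis while standing, gravity tilted toward
the z-axis while sitting) and near-zero gyroscope output; locomotion
activities add activity-specific sinusoidal components (walking ~1.8 Hz
fundamental, stair climbing slower and with larger rotation about the
leg axis); posture transitions are half-cosine ramps between the posture
baselines with a brief gyroscope pulse; and Gaussian sensor noise is
superimposed on everything.  Streams can be emitted in any of the four
front-pocket orientations, which are two-axis sign flips of the reference
frame.

Signature defaults are free choices calibrated only for separability between
activities; they mimic the qualitative structure of real pocket-phone data
(amplitude and frequency contrasts, gravity orientation) but make no claim
of biomechanical fidelity.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .io import LabelInterval, LabelTrack, SensorStream, ValidationError
from .transforms import REFERENCE_ORIENTATION, ALL_ORIENTATIONS, Orientation, reorient

__all__ = [
    "Wave",
    "ActivitySignature",
    "Segment",
    "ProtocolSpec",
    "SensorBundle",
    "StudyFixture",
    "default_signatures",
    "scaled_walk",
    "gen_stream",
    "gen_study_fixture",
]


@dataclass(frozen=True)
class Wave:
    """One sinusoidal component on one axis: amplitude * sin(2*pi*f*t + phase)."""

    axis: int  # 0=x, 1=y, 2=z
    amplitude: float
    freq_hz: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValidationError("wave axis must be 0, 1 or 2")
        if self.amplitude < 0:
            raise ValidationError("wave amplitude must be >= 0")
        if self.freq_hz <= 0:
            raise ValidationError("wave frequency must be positive")


@dataclass(frozen=True)
class ActivitySignature:
    """Generative description of one activity's sensor output.

    ``accel_baseline`` is the gravity projection in the reference
    orientation (units g); ``gyro_baseline`` is rad/s (zero for stationary
    postures).  ``accel_ramp_to``, when set, turns the segment into a
    posture transition: the accelerometer baseline follows a half-cosine
    ramp from ``accel_baseline`` to ``accel_ramp_to`` over the segment,
    and ``gyro_pulse`` (per-axis amplitudes) adds a half-sine rotation
    pulse spanning the segment.
    """

    name: str
    accel_baseline: tuple[float, float, float]
    gyro_baseline: tuple[float, float, float] = (0.0, 0.0, 0.0)
    accel_waves: tuple[Wave, ...] = ()
    gyro_waves: tuple[Wave, ...] = ()
    accel_noise_sd: float = 0.02
    gyro_noise_sd: float = 0.02
    accel_ramp_to: tuple[float, float, float] | None = None
    gyro_pulse: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def check_rate(self, rate_h: float) -> None:
        for w in (*self.accel_waves, *self.gyro_waves):
            if w.freq_hz >= rate_h / 2:
                raise ValidationError(
                    f"{self.name}: wave at {w.freq_hz} Hz violates the "
                    f"Nyquist limit {rate_h / 2} Hz"
                )


# Gravity while sitting: rotated toward the z-axis with some tilt.
_SIT_GRAVITY = (0.0, 0.2, 0.98)
_STAND_GRAVITY = (0.0, 1.0, 0.0)


def default_signatures() -> dict[str, ActivitySignature]:
    """Well-separated defaults for the seven study activities."""
    return {
        "stand": ActivitySignature("stand", _STAND_GRAVITY),
        "sit": ActivitySignature("sit", _SIT_GRAVITY),
        "walk": ActivitySignature(
            "walk",
            _STAND_GRAVITY,
            accel_waves=(
                Wave(1, 0.35, 1.8, 0.0),
                Wave(0, 0.15, 1.8, 1.0),
                Wave(2, 0.20, 0.9, 0.5),
            ),
            gyro_waves=(
                Wave(1, 1.50, 1.8, 0.0),
                Wave(0, 0.60, 1.8, 1.57),
                Wave(2, 0.40, 0.9, 0.0),
            ),
            accel_noise_sd=0.05,
            gyro_noise_sd=0.08,
        ),
        "stairsUp": ActivitySignature(
            "stairsUp",
            _STAND_GRAVITY,
            accel_waves=(Wave(1, 0.45, 1.3, 0.0), Wave(2, 0.25, 1.3, 1.2)),
            gyro_waves=(
                Wave(1, 1.00, 1.3, 0.0),
                Wave(0, 0.90, 1.3, 0.8),
                Wave(2, 0.50, 0.65, 0.0),
            ),
            accel_noise_sd=0.05,
            gyro_noise_sd=0.08,
        ),
        "stairsDown": ActivitySignature(
            "stairsDown",
            _STAND_GRAVITY,
            accel_waves=(Wave(1, 0.55, 1.6, 0.0), Wave(0, 0.20, 1.6, 0.6)),
            gyro_waves=(
                Wave(1, 1.30, 1.6, 0.0),
                Wave(0, 0.50, 1.6, 1.8),
                Wave(2, 0.70, 0.8, 0.0),
            ),
            accel_noise_sd=0.05,
            gyro_noise_sd=0.08,
        ),
        "standToSit": ActivitySignature(
            "standToSit",
            _STAND_GRAVITY,
            accel_ramp_to=_SIT_GRAVITY,
            gyro_pulse=(1.3, 0.3, 0.2),
            accel_noise_sd=0.03,
            gyro_noise_sd=0.05,
        ),
        "sitToStand": ActivitySignature(
            "sitToStand",
            _SIT_GRAVITY,
            accel_ramp_to=_STAND_GRAVITY,
            gyro_pulse=(1.5, 0.25, 0.2),
            accel_noise_sd=0.03,
            gyro_noise_sd=0.05,
        ),
    }


def scaled_walk(
    freq_scale: float, amp_scale: float, name: str = "walk"
) -> ActivitySignature:
    """Walking at a different speed: every sinusoid's frequency scaled by
    ``freq_scale`` and amplitude by ``amp_scale`` (slow walk: 0.6 / 0.7)."""
    base = default_signatures()["walk"]
    scale = lambda waves: tuple(
        replace(w, amplitude=w.amplitude * amp_scale, freq_hz=w.freq_hz * freq_scale)
        for w in waves
    )
    return replace(
        base,
        name=name,
        accel_waves=scale(base.accel_waves),
        gyro_waves=scale(base.gyro_waves),
    )


@dataclass(frozen=True)
class Segment:
    """One protocol step: perform ``activity`` for ``duration`` seconds.

    ``label`` overrides the emitted ground-truth label (e.g. slow walking
    generated from a scaled signature but labeled plain "walk").
    """

    activity: str
    duration: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("segment duration must be positive")

    @property
    def emitted_label(self) -> str:
        return self.label or self.activity


@dataclass
class ProtocolSpec:
    """An ordered activity sequence with rate, orientation and seed."""

    segments: list[Segment]
    rate_h: float = 10.0
    orientation: Orientation = REFERENCE_ORIENTATION
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("protocol needs at least one segment")
        if self.rate_h <= 0:
            raise ValidationError("rate_h must be positive")


@dataclass
class SensorBundle:
    """Matched accelerometer + gyroscope streams with their label track."""

    accel: SensorStream
    gyro: SensorStream
    track: LabelTrack


def _segment_arrays(
    sig: ActivitySignature, t_local: np.ndarray, duration: float
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free accel and gyro arrays (len(t_local), 3) for one segment."""
    cnt = t_local.shape[0]
    accel = np.tile(np.asarray(sig.accel_baseline, dtype=float), (cnt, 1))
    gyro = np.tile(np.asarray(sig.gyro_baseline, dtype=float), (cnt, 1))
    if sig.accel_ramp_to is not None:
        u = t_local / duration  # in [0, 1)
        ramp = 0.5 * (1.0 - np.cos(np.pi * u))
        delta = np.asarray(sig.accel_ramp_to) - np.asarray(sig.accel_baseline)
        accel = accel + ramp[:, None] * delta[None, :]
        if sig.gyro_pulse is not None:
            gyro = gyro + np.sin(np.pi * u)[:, None] * np.asarray(sig.gyro_pulse)
    for w in sig.accel_waves:
        accel[:, w.axis] += w.amplitude * np.sin(2 * np.pi * w.freq_hz * t_local + w.phase)
    for w in sig.gyro_waves:
        gyro[:, w.axis] += w.amplitude * np.sin(2 * np.pi * w.freq_hz * t_local + w.phase)
    return accel, gyro


def gen_stream(
    spec: ProtocolSpec,
    signatures: Mapping[str, ActivitySignature] | None = None,
    placement: str = "front_pocket",
    t0: float = 0.0,
) -> SensorBundle:
    """Generate matched accelerometer/gyroscope streams plus labels.

    Per segment: samples = baseline + sinusoids (+ transition ramp/pulse)
    + Gaussian noise, all seeded from ``spec.seed``.  The label track
    partitions the stream exactly.  Streams are emitted in
    ``spec.orientation`` (generated in the reference frame, then reoriented).
    """
    signatures = dict(signatures) if signatures is not None else default_signatures()
    h = spec.rate_h
    rng = np.random.default_rng(spec.seed)

    accel_parts, gyro_parts, intervals = [], [], []
    cursor = 0  # global sample index
    for seg in spec.segments:
        if seg.activity not in signatures:
            raise ValidationError(f"no signature for activity {seg.activity!r}")
        sig = signatures[seg.activity]
        sig.check_rate(h)
        cnt = int(round(seg.duration * h))
        if cnt < 1:
            raise ValidationError(f"segment {seg.activity!r} shorter than one sample")
        t_local = np.arange(cnt) / h
        accel, gyro = _segment_arrays(sig, t_local, seg.duration)
        accel = accel + rng.normal(0.0, sig.accel_noise_sd, size=accel.shape)
        gyro = gyro + rng.normal(0.0, sig.gyro_noise_sd, size=gyro.shape)
        accel_parts.append(accel)
        gyro_parts.append(gyro)
        intervals.append(
            LabelInterval(t0 + cursor / h, t0 + (cursor + cnt) / h, seg.emitted_label)
        )
        cursor += cnt

    timestamps = t0 + np.arange(cursor) / h
    accel_stream = SensorStream(
        sensor_kind="accelerometer",
        placement=placement,
        rate_h=h,
        timestamps=timestamps,
        values=np.vstack(accel_parts),
        channels=("x", "y", "z"),
    )
    gyro_stream = SensorStream(
        sensor_kind="gyroscope",
        placement=placement,
        rate_h=h,
        timestamps=timestamps.copy(),
        values=np.vstack(gyro_parts),
        channels=("x", "y", "z"),
    )
    if spec.orientation != REFERENCE_ORIENTATION:
        accel_stream = reorient(accel_stream, REFERENCE_ORIENTATION, spec.orientation)
        gyro_stream = reorient(gyro_stream, REFERENCE_ORIENTATION, spec.orientation)
    return SensorBundle(accel_stream, gyro_stream, LabelTrack(intervals))


# ---------------------------------------------------------------------------
# Study fixture
# ---------------------------------------------------------------------------

#: Training bouts: brief routine activities, two chair-stand cycles.
TRAINING_SEGMENTS = (
    Segment("stand", 10.0),
    Segment("walk", 15.0),
    Segment("stairsUp", 8.0),
    Segment("stairsDown", 8.0),
    Segment("standToSit", 1.5),
    Segment("sit", 10.0),
    Segment("sitToStand", 1.5),
    Segment("stand", 3.0),
    Segment("standToSit", 1.5),
    Segment("sit", 10.0),
    Segment("sitToStand", 1.5),
)

#: Test course: a campus-loop-like mix of the dictionary activities.
COURSE_SEGMENTS = (
    Segment("stand", 10.0),
    Segment("walk", 40.0),
    Segment("stairsUp", 25.0),
    Segment("stairsDown", 25.0),
    Segment("walk", 20.0),
    Segment("standToSit", 1.5),
    Segment("sit", 20.0),
    Segment("sitToStand", 1.5),
    Segment("stand", 5.0),
)

#: Walking at three speeds, all truly "walk".
SPEED_SEGMENTS = (
    Segment("walk", 30.0),
    Segment("walk_fast", 30.0, label="walk"),
    Segment("walk_slow", 30.0, label="walk"),
)


@dataclass
class StudyFixture:
    """A complete synthetic study for one subject.

    ``training`` feeds dictionary construction; ``course`` is the primary
    test segment; ``speeds`` walks at normal/fast/slow pace (all labeled
    "walk"; ``speed_track`` records which pace when); ``orientations`` holds
    four independent replicates of the course, one per front-pocket
    orientation, each emitted as the phone would record it.
    """

    training: SensorBundle
    course: SensorBundle
    speeds: SensorBundle
    speed_track: LabelTrack
    orientations: dict[Orientation, SensorBundle]
    seed: int


def gen_study_fixture(seed: int = 1, rate_h: float = 10.0) -> StudyFixture:
    """Generate the full study-shaped bundle deterministically from a seed."""
    signatures = default_signatures()
    signatures["walk_slow"] = scaled_walk(0.6, 0.7, "walk_slow")
    signatures["walk_fast"] = scaled_walk(1.25, 1.15, "walk_fast")

    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(seed).spawn(7)]

    training = gen_stream(
        ProtocolSpec(list(TRAINING_SEGMENTS), rate_h, seed=seeds[0]), signatures
    )
    course = gen_stream(
        ProtocolSpec(list(COURSE_SEGMENTS), rate_h, seed=seeds[1]), signatures
    )
    speeds = gen_stream(
        ProtocolSpec(list(SPEED_SEGMENTS), rate_h, seed=seeds[2]), signatures
    )
    speed_track = LabelTrack(
        [
            LabelInterval(iv.start, iv.end, seg.activity)
            for iv, seg in zip(speeds.track.intervals, SPEED_SEGMENTS)
        ]
    )
    orientations = {
        o: gen_stream(
            ProtocolSpec(list(COURSE_SEGMENTS), rate_h, orientation=o, seed=s),
            signatures,
        )
        for o, s in zip(ALL_ORIENTATIONS, seeds[3:])
    }
    return StudyFixture(training, course, speeds, speed_track, orientations, seed)
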