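"""Tracker-stream data model, coordinate conventions, and stream I/O.

A consumer eye-and-head tracker reports timestamped samples with gaze in
normalized screen coordinates (bottom-left ``(0, 0)``, top-right ``(1, 1)``)
and head orientation as Euler angles in degrees, ``(0, 0, 0)`` when the user
faces the screen straight ahead.  All angles are degrees and all times are
seconds throughout this package; nothing is ever expressed in radians at the
API surface.

Sign convention: positive yaw is a rightward head turn (clockwise viewed
from above); positive pitch is upward.  Sample rate is a property of the
stream — every algorithm uses the actual timestamps and never assumes a
constant rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazeHeadSample",
    "ScreenGeometry",
    "VelocitySample",
    "STREAM_COLUMNS",
    "instantaneous_velocity",
    "velocity_series",
    "screen_offset_to_angle",
    "angle_to_screen_offset",
    "read_stream",
    "write_stream",
]

#: Exact CSV header for stream files (UTF-8, '.' decimal separator).
STREAM_COLUMNS = (
    "t_s",
    "gaze_x",
    "gaze_y",
    "gaze_valid",
    "head_pitch_deg",
    "head_yaw_deg",
    "head_roll_deg",
)

_AXES = ("yaw", "pitch")


@dataclass(frozen=True)
class GazeHeadSample:
    """One timestamped eye-and-head tracker record.

    Parameters
    ----------
    t : float
        Timestamp in seconds, strictly increasing within a stream.
    gaze_x, gaze_y : float
        Normalized screen coordinates; in [0, 1] whenever ``gaze_valid``.
    gaze_valid : bool
        False when the eyes are closed or eye tracking is lost.  Gaze
        coordinates of invalid samples are ignored by all gaze logic.
    head_pitch, head_yaw, head_roll : float
        Head Euler angles in degrees.
    """

    t: float
    gaze_x: float
    gaze_y: float
    gaze_valid: bool
    head_pitch: float
    head_yaw: float
    head_roll: float

    def angle(self, axis: str) -> float:
        """Head angle in degrees on the requested axis ('yaw' or 'pitch')."""
        if axis == "yaw":
            return self.head_yaw
        if axis == "pitch":
            return self.head_pitch
        raise ValueError(f"unknown axis {axis!r}; expected one of {_AXES}")


def _default_mm(diagonal_inch: float, width_px: int, height_px: int) -> tuple:
    diag_mm = diagonal_inch * 25.4
    aspect = width_px / height_px
    height_mm = diag_mm / math.hypot(aspect, 1.0)
    return aspect * height_mm, height_mm


_DEF_W_MM, _DEF_H_MM = _default_mm(15.6, 1920, 1080)


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used to convert normalized offsets to visual angle.

    Defaults model the validation hardware: a 15.6-inch 1920x1080 laptop
    viewed from about 30 inches (762 mm).
    """

    width_px: int = 1920
    height_px: int = 1080
    width_mm: float = _DEF_W_MM
    height_mm: float = _DEF_H_MM
    viewing_distance_mm: float = 762.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm", "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    @property
    def aspect(self) -> float:
        """Physical width/height ratio (1920x1080 -> 16/9)."""
        return self.width_mm / self.height_mm

    def extent_mm(self, axis: str) -> float:
        if axis in ("x", "horizontal", "yaw"):
            return self.width_mm
        if axis in ("y", "vertical", "pitch"):
            return self.height_mm
        raise ValueError(f"unknown screen axis {axis!r}")


@dataclass(frozen=True)
class VelocitySample:
    """Instantaneous angular head velocity between two consecutive samples.

    ``value`` is signed degrees/second: positive yaw velocity is a rightward
    (clockwise from above) turn, positive pitch velocity is upward.
    ``t_mid`` sits midway between the two source timestamps.
    """

    t_mid: float
    axis: str
    value: float
    dt: float


def instantaneous_velocity(s1: GazeHeadSample, s2: GazeHeadSample, axis: str = "yaw") -> VelocitySample:
    """Angular velocity from two consecutive samples.

    The velocity is the difference in head angle divided by the difference
    in time between the two samples, sign preserved.
    """
    dt = s2.t - s1.t
    if dt <= 0:
        raise ValueError(
            f"non-increasing timestamps: t1={s1.t!r} >= t2={s2.t!r} (dt must be > 0)"
        )
    value = (s2.angle(axis) - s1.angle(axis)) / dt
    return VelocitySample(t_mid=0.5 * (s1.t + s2.t), axis=axis, value=value, dt=dt)


def velocity_series(stream: Sequence[GazeHeadSample], axis: str = "yaw") -> List[VelocitySample]:
    """Instantaneous velocity between every consecutive sample pair.

    Returns ``len(stream) - 1`` samples; element ``i`` is derived from
    stream samples ``i`` and ``i + 1``.
    """
    if len(stream) < 2:
        raise ValueError("velocity_series requires at least 2 samples")
    t = np.array([s.t for s in stream], dtype=float)
    theta = np.array([s.angle(axis) for s in stream], dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"non-increasing timestamps between samples {i} and {i + 1}")
    values = np.diff(theta) / dt
    t_mid = 0.5 * (t[:-1] + t[1:])
    return [
        VelocitySample(t_mid=float(tm), axis=axis, value=float(v), dt=float(d))
        for tm, v, d in zip(t_mid, values, dt)
    ]


def screen_offset_to_angle(offset_norm: float, axis: str, geometry: ScreenGeometry | None = None) -> float:
    """Visual angle (degrees) subtended by a normalized screen offset.

    This small-target helper assumes the offset is measured from the screen
    point directly in front of the eye: ``atan(offset_mm / distance)``.  It is
    an approximation — the tracker itself reports head Euler angles, which
    all head algorithms take as given.
    """
    geometry = geometry or ScreenGeometry()
    offset_mm = offset_norm * geometry.extent_mm(axis)
    return math.degrees(math.atan2(offset_mm, geometry.viewing_distance_mm))


def angle_to_screen_offset(angle_deg: float, axis: str, geometry: ScreenGeometry | None = None) -> float:
    """Inverse of :func:`screen_offset_to_angle`."""
    geometry = geometry or ScreenGeometry()
    if abs(angle_deg) >= 90.0:
        raise ValueError("visual angle must be inside (-90, 90) degrees")
    offset_mm = math.tan(math.radians(angle_deg)) * geometry.viewing_distance_mm
    return offset_mm / geometry.extent_mm(axis)


_TRUE = {"1", "true", "True", "TRUE", 1, True, 1.0}
_FALSE = {"0", "false", "False", "FALSE", 0, False, 0.0}


def _parse_valid(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot parse gaze_valid value {v!r}; expected one of 0/1/true/false")


def read_stream(path) -> List[GazeHeadSample]:
    """Read a tracker stream from CSV.

    The header must be exactly ``t_s,gaze_x,gaze_y,gaze_valid,
    head_pitch_deg,head_yaw_deg,head_roll_deg``.  ``gaze_valid`` accepts the
    dialects 0/1/true/false (any case).  Timestamps must be strictly
    increasing.
    """
    df = pd.read_csv(path, dtype={"gaze_valid": object})
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stream file {path} is missing column(s): {', '.join(missing)}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(f"non-monotonic timestamps between rows {i} and {i + 1}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            GazeHeadSample(
                t=float(row.t_s),
                gaze_x=float(row.gaze_x),
                gaze_y=float(row.gaze_y),
                gaze_valid=_parse_valid(row.gaze_valid),
                head_pitch=float(row.head_pitch_deg),
                head_yaw=float(row.head_yaw_deg),
                head_roll=float(row.head_roll_deg),
            )
        )
    return samples


def write_stream(samples: Iterable[GazeHeadSample], path) -> None:
    """Write samples to CSV with the canonical stream header."""
    samples = list(samples)
    df = pd.DataFrame(
        {
            "t_s": [s.t for s in samples],
            "gaze_x": [s.gaze_x for s in samples],
            "gaze_y": [s.gaze_y for s in samples],
            "gaze_valid": [int(s.gaze_valid) for s in samples],
            "head_pitch_deg": [s.head_pitch for s in samples],
            "head_yaw_deg": [s.head_yaw for s in samples],
            "head_roll_deg": [s.head_roll for s in samples],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
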