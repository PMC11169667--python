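"""Per-frame state machines and session metrics for the gamified exercises.

Four gaze-stabilization exercises are scored from a tracker stream:

* ``vorx1`` / ``vorx2`` — gaze at a target (stationary for x1, moving
  anti-phase to the head for x2) while turning the head above a threshold
  speed; correct performance grows a plant.
* ``gaze_shift`` — a large eye movement to a side target followed by a head
  turn toward it; repetitions are counted.
* ``remembered_target`` — fixate, close the eyes, turn the head while
  holding gaze on the remembered location, reopen; damage dealt per trial is
  proportional to reopening accuracy.

Sessions are single continuous blocks.  Processing starts after a short
warm-up equal to the estimator window so the head-speed estimate is defined
from the first scored frame, and ends on the first frame at or past the
configured duration.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, asdict
from typing import List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .gaze import (
    DEFAULT_SIZE_RATIOS,
    OnTargetState,
    TargetSpec,
    gaze_on_target,
    target_radius,
    update_on_target_state,
)
from .streams import GazeHeadSample, ScreenGeometry, velocity_series
from .velocity import EstimatorParams, classify_speed, estimate_motion

__all__ = [
    "SPEED_PRESETS",
    "ExerciseConfig",
    "FrameRecord",
    "SessionMetrics",
    "speed_preset_value",
    "run_session",
    "run_vorx_session",
    "run_gaze_shift_session",
    "run_remembered_target_session",
    "compute_session_metrics",
    "compute_adherence",
    "write_frame_log",
    "read_frame_log",
]

GAMES = ("vorx1", "vorx2", "gaze_shift", "remembered_target")

#: Clinician-selectable target head speeds (deg/s) per axis and preset.
SPEED_PRESETS: Mapping[str, Mapping[str, float]] = {
    "horizontal": {"slow": 60.0, "medium": 120.0, "fast": 180.0, "fastest": 240.0},
    "vertical": {"slow": 45.0, "medium": 78.0, "fast": 88.0, "fastest": 95.0},
}


def speed_preset_value(axis: str, preset: str) -> float:
    """Target head speed in deg/s for an (axis, preset) pair."""
    try:
        table = SPEED_PRESETS[axis]
    except KeyError:
        raise ValueError(f"unknown axis {axis!r}; expected 'horizontal' or 'vertical'") from None
    try:
        return table[preset]
    except KeyError:
        raise ValueError(
            f"unknown speed preset {preset!r} for axis {axis!r}; valid: {sorted(table)}"
        ) from None


@dataclass
class ExerciseConfig:
    """Clinician-facing session configuration.

    ``background_complexity`` is cosmetic clutter only: it is echoed into
    reports but never affects scoring.
    """

    game: str = "vorx1"
    duration_s: float = 60.0
    axis: str = "horizontal"  # 'horizontal' (yaw) or 'vertical' (pitch)
    speed_preset: str = "slow"
    target_size: str = "medium"
    background_complexity: int = 0
    estimator: EstimatorParams = field(default_factory=EstimatorParams)
    size_ratios: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_RATIOS))
    grace_s: float = 0.5
    region: str = "circle"
    warmup_s: float = 0.25
    # vorx2: target offset (normalized units) per 30 deg of head angle, anti-phase
    vorx2_gain: float = 1.0
    # gaze_shift
    target_offset_norm: float = 0.3
    head_face_tolerance_deg: float = 15.0
    # remembered_target
    eye_closed_min_s: float = 0.3
    d_max_radii: float = 3.0

    def __post_init__(self) -> None:
        if self.game not in GAMES:
            raise ValueError(f"unknown game {self.game!r}; valid: {GAMES}")
        if not 30.0 <= self.duration_s <= 120.0:
            raise ValueError("duration_s must be within [30, 120] seconds")
        # resolve early so bad axis/preset combinations fail at config time
        speed_preset_value(self.axis, self.speed_preset)
        target_radius(self.target_size, self.size_ratios)

    @property
    def head_axis(self) -> str:
        return "yaw" if self.axis == "horizontal" else "pitch"

    @property
    def screen_axis(self) -> str:
        return "x" if self.axis == "horizontal" else "y"

    @property
    def threshold_dps(self) -> float:
        return speed_preset_value(self.axis, self.speed_preset)

    def target(self, center: Tuple[float, float] = (0.5, 0.5)) -> TargetSpec:
        return TargetSpec.from_size_class(
            self.target_size, center=center, ratios=self.size_ratios, region=self.region
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["estimator"] = asdict(self.estimator)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExerciseConfig":
        d = dict(d)
        est = d.pop("estimator", None)
        if est is not None and not isinstance(est, EstimatorParams):
            est = EstimatorParams(**est)
        return cls(estimator=est or EstimatorParams(), **d)


@dataclass(frozen=True)
class FrameRecord:
    """One scored frame, mirroring the platform's logged per-frame output."""

    t: float
    gaze_x: float
    gaze_y: float
    head_pitch: float
    head_yaw: float
    head_roll: float
    head_velocity: float  # estimated speed, deg/s
    eyes_on_target: bool
    head_on_target: bool
    plant_size: float


@dataclass
class SessionMetrics:
    """Time-weighted aggregates of a session's frame log."""

    pct_time_eyes_on_target: float
    pct_time_head_above_threshold: float
    pct_time_both: float
    mean_speed: float
    peak_speed: float
    final_plant_size: float
    reps: Optional[int] = None
    median_eye_head_latency_s: Optional[float] = None
    n_trials: Optional[int] = None
    damage_per_trial: Optional[float] = None
    total_damage: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


class _SessionFrames:
    """Shared per-frame iteration: window bookkeeping + velocity estimates."""

    def __init__(self, config: ExerciseConfig, stream: Sequence[GazeHeadSample],
                 geometry: ScreenGeometry | None = None):
        if len(stream) < 2:
            raise ValueError("stream must contain at least 2 samples")
        self.config = config
        self.geometry = geometry or ScreenGeometry()
        self.t0 = stream[0].t + config.warmup_s
        self.t_end = self.t0 + config.duration_s
        if stream[-1].t < self.t_end:
            raise ValueError(
                f"stream ends at {stream[-1].t:.3f} s but the session needs "
                f"{self.t_end:.3f} s (warm-up {config.warmup_s} s + duration {config.duration_s} s)"
            )
        self.stream = stream
        self.vels = velocity_series(stream, axis=config.head_axis)

    def frames(self):
        """Yield (sample, motion_estimate) for each scored frame."""
        cfg = self.config
        lo = 0
        vels = self.vels
        n = len(vels)
        threshold = cfg.threshold_dps
        for sample in self.stream:
            if sample.t < self.t0:
                continue
            while lo < n and vels[lo].t_mid <= sample.t - cfg.estimator.window_s:
                lo += 1
            hi = lo
            while hi < n and vels[hi].t_mid <= sample.t:
                hi += 1
            est = estimate_motion(vels[lo:hi], sample.t, cfg.estimator)
            est = classify_speed(est, threshold)
            yield sample, est
            if sample.t >= self.t_end:
                break


def run_vorx_session(
    config: ExerciseConfig,
    stream: Sequence[GazeHeadSample],
    geometry: ScreenGeometry | None = None,
) -> Tuple[List[FrameRecord], SessionMetrics]:
    """Score a VORx1/VORx2 session.

    The plant grows by ``dt / duration`` over every frame interval in which
    the eyes are on target (within the grace period) and the head moves at
    or above the threshold speed; otherwise it holds.  VORx1 keeps the
    target at screen center; VORx2 moves it anti-phase to the head by
    ``vorx2_gain`` normalized units per 30 degrees of head angle.
    """
    if config.game not in ("vorx1", "vorx2"):
        raise ValueError(f"run_vorx_session expects game vorx1/vorx2, got {config.game!r}")
    runner = _SessionFrames(config, stream, geometry)
    state = OnTargetState(grace_s=config.grace_s)
    plant = 0.0
    rate = 1.0 / config.duration_s
    frames: List[FrameRecord] = []
    prev_t: Optional[float] = None
    for sample, est in runner.frames():
        if config.game == "vorx1":
            center = (0.5, 0.5)
        else:
            offset = config.vorx2_gain * sample.angle(config.head_axis) / 30.0
            pos = min(1.0, max(0.0, 0.5 - offset))
            center = (pos, 0.5) if config.axis == "horizontal" else (0.5, pos)
        target = config.target(center)
        eyes_on = gaze_on_target(sample, target, runner.geometry)
        state = update_on_target_state(state, sample, target, sample.t, runner.geometry)
        head_on = est.classification == "above_threshold"
        dt = 0.0 if prev_t is None else sample.t - prev_t
        if state.within_grace(sample.t) and head_on:
            plant = min(1.0, plant + rate * dt)
        frames.append(_frame(sample, est, eyes_on, head_on, plant))
        prev_t = sample.t
    metrics = compute_session_metrics(frames)
    return frames, metrics


def run_gaze_shift_session(
    config: ExerciseConfig,
    stream: Sequence[GazeHeadSample],
    geometry: ScreenGeometry | None = None,
) -> Tuple[List[FrameRecord], SessionMetrics]:
    """Score a gaze-shift ("kitty catch") session.

    A repetition completes when the gaze first enters the side target's
    region and the head then turns toward that side past
    ``head_face_tolerance_deg``.  The target then switches sides.
    """
    if config.game != "gaze_shift":
        raise ValueError(f"run_gaze_shift_session expects game gaze_shift, got {config.game!r}")
    runner = _SessionFrames(config, stream, geometry)
    side = 1  # +1: target on the positive-angle side (right / up)
    awaiting_head = False
    t_gaze = 0.0
    reps = 0
    latencies: List[float] = []
    frames: List[FrameRecord] = []
    for sample, est in runner.frames():
        pos = 0.5 + side * config.target_offset_norm
        center = (pos, 0.5) if config.axis == "horizontal" else (0.5, pos)
        target = config.target(center)
        eyes_on = gaze_on_target(sample, target, runner.geometry)
        head_on = est.classification == "above_threshold"
        if not awaiting_head:
            if eyes_on:
                awaiting_head = True
                t_gaze = sample.t
        else:
            if side * sample.angle(config.head_axis) >= config.head_face_tolerance_deg:
                reps += 1
                latencies.append(sample.t - t_gaze)
                side = -side
                awaiting_head = False
        frames.append(_frame(sample, est, eyes_on, head_on, 0.0))
    metrics = compute_session_metrics(frames)
    metrics.reps = reps
    metrics.median_eye_head_latency_s = statistics.median(latencies) if latencies else None
    return frames, metrics


def run_remembered_target_session(
    config: ExerciseConfig,
    stream: Sequence[GazeHeadSample],
    geometry: ScreenGeometry | None = None,
) -> Tuple[List[FrameRecord], SessionMetrics]:
    """Score a remembered-target ("smashy castles") session.

    In this game an invalid-gaze epoch is the eyes-closed signal.  A trial
    is: fixate the target, keep the eyes closed for at least
    ``eye_closed_min_s``, then reopen.  Damage is ``max(0, 1 - error/d_max)``
    where ``error`` is the reopening gaze-to-target distance (screen-height
    units, aspect-corrected) and ``d_max = d_max_radii * target radius``.
    Cumulative damage per castle is capped at 1.
    """
    if config.game != "remembered_target":
        raise ValueError(
            f"run_remembered_target_session expects game remembered_target, got {config.game!r}"
        )
    runner = _SessionFrames(config, stream, geometry)
    target = config.target((0.5, 0.5))
    d_max = config.d_max_radii * target.radius_norm
    fixated = False
    closed_since: Optional[float] = None
    damages: List[float] = []
    total = 0.0
    frames: List[FrameRecord] = []
    for sample, est in runner.frames():
        eyes_on = gaze_on_target(sample, target, runner.geometry)
        head_on = est.classification == "above_threshold"
        if not sample.gaze_valid:
            if closed_since is None:
                closed_since = sample.t
        else:
            if closed_since is not None:
                if sample.t - closed_since >= config.eye_closed_min_s and fixated:
                    dx = (sample.gaze_x - target.center[0]) * runner.geometry.aspect
                    dy = sample.gaze_y - target.center[1]
                    error = (dx * dx + dy * dy) ** 0.5
                    damages.append(max(0.0, 1.0 - error / d_max))
                    total = min(1.0, sum(damages))
                    fixated = False
                closed_since = None
            if eyes_on:
                fixated = True
        frames.append(_frame(sample, est, eyes_on, head_on, 0.0))
    metrics = compute_session_metrics(frames)
    metrics.n_trials = len(damages)
    metrics.damage_per_trial = statistics.fmean(damages) if damages else None
    metrics.total_damage = total
    return frames, metrics


def run_session(
    config: ExerciseConfig,
    stream: Sequence[GazeHeadSample],
    geometry: ScreenGeometry | None = None,
) -> Tuple[List[FrameRecord], SessionMetrics]:
    """Dispatch to the engine for ``config.game``."""
    if config.game in ("vorx1", "vorx2"):
        return run_vorx_session(config, stream, geometry)
    if config.game == "gaze_shift":
        return run_gaze_shift_session(config, stream, geometry)
    return run_remembered_target_session(config, stream, geometry)


def _frame(sample: GazeHeadSample, est, eyes_on: bool, head_on: bool, plant: float) -> FrameRecord:
    return FrameRecord(
        t=sample.t,
        gaze_x=sample.gaze_x,
        gaze_y=sample.gaze_y,
        head_pitch=sample.head_pitch,
        head_yaw=sample.head_yaw,
        head_roll=sample.head_roll,
        head_velocity=est.speed,
        eyes_on_target=eyes_on,
        head_on_target=head_on,
        plant_size=plant,
    )


def compute_session_metrics(frames: Sequence[FrameRecord]) -> SessionMetrics:
    """Time-weighted aggregation of a frame log.

    Each frame's state is weighted by the interval since the previous frame
    (matching how the live engines accrue time), so replaying a stored frame
    log reproduces the metrics emitted live.  A single-frame log falls back
    to unweighted flags.
    """
    if not frames:
        raise ValueError("cannot compute metrics of an empty frame log")
    dts = [0.0] + [b.t - a.t for a, b in zip(frames, frames[1:])]
    total = sum(dts)
    if total <= 0:
        w = [1.0 / len(frames)] * len(frames)
    else:
        w = [d / total for d in dts]
    eyes = sum(wi for wi, f in zip(w, frames) if f.eyes_on_target)
    head = sum(wi for wi, f in zip(w, frames) if f.head_on_target)
    both = sum(wi for wi, f in zip(w, frames) if f.eyes_on_target and f.head_on_target)
    mean_speed = sum(wi * f.head_velocity for wi, f in zip(w, frames))
    return SessionMetrics(
        pct_time_eyes_on_target=100.0 * eyes,
        pct_time_head_above_threshold=100.0 * head,
        pct_time_both=100.0 * both,
        mean_speed=mean_speed,
        peak_speed=max(f.head_velocity for f in frames),
        final_plant_size=frames[-1].plant_size,
    )


def compute_adherence(
    completed_per_week: Sequence[float], assigned_per_week: Sequence[float]
) -> dict:
    """Weekly and overall adherence percentages.

    Adherence is the number of exercises completed divided by the number
    assigned, per week; the overall figure pools counts across weeks.
    Values above 100% are permitted (patient over-performed) and flagged.
    """
    if len(completed_per_week) != len(assigned_per_week):
        raise ValueError("completed and assigned lists must have equal length")
    if not completed_per_week:
        raise ValueError("at least one week is required")
    weekly = []
    for i, (c, a) in enumerate(zip(completed_per_week, assigned_per_week)):
        if a <= 0:
            raise ValueError(f"week {i + 1}: assigned count must be positive")
        weekly.append(100.0 * c / a)
    overall = 100.0 * sum(completed_per_week) / sum(assigned_per_week)
    return {
        "weekly_pct": weekly,
        "overall_pct": overall,
        "weeks_over_100": [i + 1 for i, p in enumerate(weekly) if p > 100.0],
    }


_FRAME_COLUMNS = (
    "t_s", "gaze_x", "gaze_y", "head_pitch_deg", "head_yaw_deg", "head_roll_deg",
    "head_velocity_dps", "eyes_on_target", "head_on_target", "plant_size",
)


def write_frame_log(frames: Sequence[FrameRecord], path) -> None:
    df = pd.DataFrame(
        {
            "t_s": [f.t for f in frames],
            "gaze_x": [f.gaze_x for f in frames],
            "gaze_y": [f.gaze_y for f in frames],
            "head_pitch_deg": [f.head_pitch for f in frames],
            "head_yaw_deg": [f.head_yaw for f in frames],
            "head_roll_deg": [f.head_roll for f in frames],
            "head_velocity_dps": [f.head_velocity for f in frames],
            "eyes_on_target": [int(f.eyes_on_target) for f in frames],
            "head_on_target": [int(f.head_on_target) for f in frames],
            "plant_size": [f.plant_size for f in frames],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_frame_log(path) -> List[FrameRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frame log {path} is missing column(s): {', '.join(missing)}")
    return [
        FrameRecord(
            t=float(r.t_s),
            gaze_x=float(r.gaze_x),
            gaze_y=float(r.gaze_y),
            head_pitch=float(r.head_pitch_deg),
            head_yaw=float(r.head_yaw_deg),
            head_roll=float(r.head_roll_deg),
            head_velocity=float(r.head_velocity_dps),
            eyes_on_target=bool(r.eyes_on_target),
            head_on_target=bool(r.head_on_target),
            plant_size=float(r.plant_size),
        )
        for r in df.itertuples(index=False)
    ]
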