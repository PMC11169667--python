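"""Synthetic tracker streams, psychophysical observers, and PRO respondents.

The simulators stand in for hardware and patients so every algorithm in the
package can be exercised end to end:

* head motion is a metronome-paced sinusoid ``theta(t) = A sin(2 pi f t)``
  on the chosen axis (sinusoids, not triangles, model paced head turns —
  their peak velocity ``2 pi f A`` maps beats per minute to deg/s);
* gaze error follows a VOR-gain model: a gain of 1 means perfect gaze
  stabilization (gaze pinned to the target), gain ``g`` leaves a retinal
  error of ``(1 - g) * theta`` projected onto the screen;
* the tracker's end-to-end reporting latency (~130 ms for the consumer
  device emulated here) delays every reported value;
* white Gaussian noise is added to head angles (degrees) and gaze
  coordinates (normalized units) — a stand-in for the real sensor's
  unpublished noise spectrum.

All randomness flows from one explicit seed per generator call; there is no
global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import expit

from .dva import ORIENTATIONS
from .instruments import InstrumentResponse
from .streams import GazeHeadSample, ScreenGeometry, angle_to_screen_offset

__all__ = [
    "MotionSimParams",
    "ObserverParams",
    "DEFAULT_AMPLITUDE_BY_BPM",
    "simulate_vorx_stream",
    "simulate_gaze_shift_stream",
    "simulate_remembered_target_stream",
    "head_positions",
    "true_zero_crossings",
    "make_observer",
    "simulate_respondent",
]

#: Amplitudes (deg) used with metronome pacing so that the sinusoid's peak
#: velocity 2*pi*f*A lands at the peak speeds observed on the validation
#: rig: ~100 deg/s at 60 bpm, >=120 at 90 bpm, >=140 at 120 bpm.
DEFAULT_AMPLITUDE_BY_BPM: Dict[int, float] = {60: 31.8, 90: 25.5, 120: 22.3}


@dataclass(frozen=True)
class MotionSimParams:
    """Conditions for one simulated tracker stream.

    ``seed`` is mandatory: identical parameters always produce bit-identical
    streams.  ``latency_ms`` delays every reported value relative to the
    true head state, emulating the tracker-to-software reporting lag.
    """

    seed: int
    amplitude_deg: float = 30.0
    cycle_hz: Optional[float] = 0.5
    bpm: Optional[float] = None
    axis: str = "horizontal"
    vor_gain: float = 1.0
    noise_sd_deg: float = 0.5
    noise_sd_norm: float = 0.01
    sample_rate_hz: float = 90.0
    latency_ms: float = 130.0
    duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.amplitude_deg <= 0:
            raise ValueError("amplitude_deg must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.vor_gain < 0:
            raise ValueError("vor_gain must be >= 0")
        if self.noise_sd_deg < 0 or self.noise_sd_norm < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError("axis must be 'horizontal' or 'vertical'")
        if self.cycle_hz is None and self.bpm is None:
            raise ValueError("one of cycle_hz or bpm is required")

    @property
    def frequency_hz(self) -> float:
        """Full head-turn cycles per second (bpm / 120 when paced by beats)."""
        return self.cycle_hz if self.cycle_hz is not None else self.bpm / 120.0

    @property
    def peak_velocity_dps(self) -> float:
        return 2.0 * math.pi * self.frequency_hz * self.amplitude_deg


def _times(params: MotionSimParams) -> np.ndarray:
    n = int(round(params.duration_s * params.sample_rate_hz)) + 1
    return np.arange(n) / params.sample_rate_hz


def _assemble(
    params: MotionSimParams,
    t: np.ndarray,
    head: np.ndarray,
    gaze_main: np.ndarray,
    gaze_valid: np.ndarray,
    rng: np.random.Generator,
) -> List[GazeHeadSample]:
    head_noisy = head + rng.normal(0.0, params.noise_sd_deg, size=t.shape)
    cross = rng.normal(0.0, params.noise_sd_deg, size=t.shape)  # off-axis head jitter
    gaze_main_n = np.clip(gaze_main + rng.normal(0.0, params.noise_sd_norm, size=t.shape), 0.0, 1.0)
    gaze_other = np.clip(0.5 + rng.normal(0.0, params.noise_sd_norm, size=t.shape), 0.0, 1.0)
    horizontal = params.axis == "horizontal"
    samples = []
    for i in range(len(t)):
        gx, gy = (gaze_main_n[i], gaze_other[i]) if horizontal else (gaze_other[i], gaze_main_n[i])
        yaw, pitch = (head_noisy[i], cross[i]) if horizontal else (cross[i], head_noisy[i])
        samples.append(
            GazeHeadSample(
                t=float(t[i]), gaze_x=float(gx), gaze_y=float(gy),
                gaze_valid=bool(gaze_valid[i]),
                head_pitch=float(pitch), head_yaw=float(yaw), head_roll=0.0,
            )
        )
    return samples


def simulate_vorx_stream(
    params: MotionSimParams,
    geometry: ScreenGeometry | None = None,
    target_center: float = 0.5,
) -> List[GazeHeadSample]:
    """Sinusoidal paced head motion with a VOR-gain gaze-error model.

    The reported head angle at timestamp ``t`` is the true angle at
    ``t - latency``; the gaze coordinate on the moving axis carries the
    residual error ``(1 - vor_gain) * theta`` projected to normalized
    screen units.
    """
    geometry = geometry or ScreenGeometry()
    rng = np.random.default_rng(params.seed)
    t = _times(params)
    f = params.frequency_hz
    t_lag = t - params.latency_ms / 1000.0
    head = params.amplitude_deg * np.sin(2.0 * math.pi * f * t_lag)
    err_deg = (1.0 - params.vor_gain) * head
    screen_axis = "x" if params.axis == "horizontal" else "y"
    gaze = target_center + np.array(
        [angle_to_screen_offset(a, screen_axis, geometry) for a in err_deg]
    )
    valid = np.ones(t.shape, dtype=bool)
    return _assemble(params, t, head, gaze, valid, rng)


def simulate_gaze_shift_stream(
    params: MotionSimParams,
    side_switch_hz: float = 0.5,
    target_offset_norm: float = 0.3,
    reaction_s: float = 0.15,
    head_ramp: Tuple[float, float] = (0.2, 0.6),
) -> List[GazeHeadSample]:
    """Scripted gaze-shift exercise: eye jump to a side target, head follows.

    The target alternates sides once per ``1 / side_switch_hz`` seconds.
    Within each period the gaze jumps to the new side after ``reaction_s``
    and the head ramps to ``amplitude_deg`` on that side between the
    ``head_ramp`` offsets, then holds.
    """
    if side_switch_hz <= 0:
        raise ValueError("side_switch_hz must be positive")
    rng = np.random.default_rng(params.seed)
    t = _times(params)
    period = 1.0 / side_switch_hz
    head = np.empty_like(t)
    gaze = np.empty_like(t)
    a, b = head_ramp
    for i, ti in enumerate(t):
        k = int(ti // period)
        phase = ti - k * period
        side = 1 if k % 2 == 0 else -1
        prev_side = -side if k > 0 else 0
        gaze[i] = 0.5 + (side if phase >= reaction_s else prev_side) * target_offset_norm
        if phase < a:
            frac = 0.0
        elif phase >= b:
            frac = 1.0
        else:
            frac = (phase - a) / (b - a)
        head[i] = (prev_side + (side - prev_side) * frac) * params.amplitude_deg
    valid = np.ones(t.shape, dtype=bool)
    return _assemble(params, t, head, gaze, valid, rng)


def simulate_remembered_target_stream(
    params: MotionSimParams,
    trials: int = 5,
    reopen_error_norm: float = 0.0,
    fixate_s: float = 1.0,
    closed_s: float = 0.6,
    target_center: float = 0.5,
) -> List[GazeHeadSample]:
    """Scripted remembered-target trials: fixate, eyes closed + head turn, reopen.

    Each trial occupies ``duration_s / trials`` seconds: the subject fixates
    the center target, closes the eyes (gaze invalid) for ``closed_s`` while
    the head turns to ``amplitude_deg``, then reopens with the gaze landing
    ``reopen_error_norm`` normalized units from the target.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    block = params.duration_s / trials
    if block < fixate_s + closed_s + 0.2:
        raise ValueError("duration too short for the requested number of trials")
    rng = np.random.default_rng(params.seed)
    t = _times(params)
    head = np.empty_like(t)
    gaze = np.empty_like(t)
    valid = np.ones(t.shape, dtype=bool)
    for i, ti in enumerate(t):
        k = min(int(ti // block), trials - 1)
        phase = ti - k * block
        if phase < fixate_s:
            head[i], gaze[i] = 0.0, target_center
        elif phase < fixate_s + closed_s:
            frac = (phase - fixate_s) / closed_s
            head[i] = frac * params.amplitude_deg
            gaze[i] = target_center
            valid[i] = False
        else:
            head[i] = max(0.0, params.amplitude_deg * (1.0 - (phase - fixate_s - closed_s) / 0.3))
            gaze[i] = target_center + reopen_error_norm
    return _assemble(params, t, head, gaze, valid, rng)


def head_positions(stream, axis: str = "yaw") -> List[Tuple[float, float]]:
    """Extract a ``(t, angle_deg)`` trace from a stream for the DVA trigger."""
    return [(s.t, s.angle(axis)) for s in stream]


def true_zero_crossings(params: MotionSimParams) -> List[float]:
    """Times at which the *true* (undelayed, noiseless) head angle crosses zero.

    For ``A sin(2 pi f t)`` these are multiples of the half period,
    including the crossing at t = 0 where the motion starts.
    """
    f = params.frequency_hz
    half = 0.5 / f
    out = []
    k = 0
    while k * half <= params.duration_s:
        out.append(k * half)
        k += 1
    return out


# --------------------------------------------------------------------------
# Psychophysical observer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverParams:
    """Logistic 4-alternative observer for the tumbling-E task.

    ``P(correct | size s) = chance + (1 - chance - lapse) *
    logistic((s - threshold) / slope)`` — larger optotypes are easier.
    Incorrect responses pick uniformly among the three wrong orientations.
    """

    threshold_logmar: float = 0.4
    slope_logmar: float = 0.05
    chance_rate: float = 0.25
    lapse_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chance_rate < 1.0:
            raise ValueError("chance_rate must be in [0, 1)")
        if self.slope_logmar <= 0:
            raise ValueError("slope_logmar must be positive")
        if not 0.0 <= self.lapse_rate < 1.0 - self.chance_rate:
            raise ValueError("lapse_rate must be in [0, 1 - chance_rate)")

    def p_correct(self, logmar: float) -> float:
        x = (logmar - self.threshold_logmar) / self.slope_logmar
        return self.chance_rate + (1.0 - self.chance_rate - self.lapse_rate) * float(expit(x))


def make_observer(params: ObserverParams):
    """Build a seeded observer callable ``(logmar, true_orientation) -> reported``."""
    rng = np.random.default_rng(params.seed)

    def observer(logmar: float, true_orientation: str) -> str:
        if rng.random() < params.p_correct(logmar):
            return true_orientation
        wrong = [o for o in ORIENTATIONS if o != true_orientation]
        return wrong[int(rng.integers(0, 3))]

    return observer


# --------------------------------------------------------------------------
# PRO respondent
# --------------------------------------------------------------------------

def simulate_respondent(severity: float, seed: int) -> Dict[str, InstrumentResponse]:
    """Draw a full PRO response set for a respondent of given severity.

    ``severity`` in [0, 1] monotonically drives expected symptom scores:
    handicap (DHI), disability (DRS), symptom VAS, and motion sensitivity
    rise with severity while balance confidence (mABC) falls.  Usability
    (SUS) is independent of symptom severity.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be within [0, 1]")
    rng = np.random.default_rng(seed)

    mabc = tuple(25 * int(rng.binomial(4, 1.0 - severity)) for _ in range(16))

    dhi_levels = ("no", "sometimes", "yes")
    dhi = []
    for _ in range(25):
        x = severity + rng.normal(0.0, 0.15)
        dhi.append(dhi_levels[0] if x <= 1 / 3 else dhi_levels[1] if x <= 2 / 3 else dhi_levels[2])

    drs = int(np.clip(round(5 * severity + rng.normal(0.0, 0.5)), 0, 5))

    def vas_mark(scale: float = 10.0) -> float:
        return float(np.clip(scale * severity + rng.normal(0.0, 0.5), 0.0, scale))

    baseline = float(np.clip(10 * severity * 0.3 + rng.normal(0.0, 0.3), 0.0, 10.0))
    movements = tuple(
        (
            float(np.clip(baseline + 10 * severity * rng.random(), 0.0, 10.0)),
            float(40.0 * severity * rng.random()),
        )
        for _ in range(10)
    )

    sus = tuple(
        int(np.clip(round(4.5 + rng.normal(0, 0.5)), 1, 5)) if (i + 1) % 2 == 1
        else int(np.clip(round(1.5 + rng.normal(0, 0.5)), 1, 5))
        for i in range(10)
    )

    return {
        "mabc": InstrumentResponse("mabc", mabc),
        "dhi": InstrumentResponse("dhi", tuple(dhi)),
        "drs": InstrumentResponse("drs", (drs,)),
        "vas_dizziness": InstrumentResponse("vas_dizziness", (vas_mark() * 0.4, vas_mark())),
        "vas_interference": InstrumentResponse("vas_interference", (vas_mark(),)),
        "mmst": InstrumentResponse("mmst", (baseline,) + movements),
        "sus": InstrumentResponse("sus", sus),
    }
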