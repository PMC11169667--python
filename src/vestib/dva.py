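"""Digital static/dynamic visual acuity testing.

The dynamic test flashes a tumbling-E optotype exactly while the head —
paced by a metronome — sweeps through the straight-ahead position, where
angular velocity peaks.  Because the tracker-to-display pipeline has a
substantial latency (~130 ms end to end), the trigger extrapolates a short
line fit through recent head-position samples and anticipates the zero
crossing that far in advance, issuing the flash so that it lands on the
crossing rather than 130 ms after it.

Acuity is measured with a descending staircase: the optotype shrinks by
0.1 logMAR after every correct response and the test terminates once the
participant makes three consecutive incorrect responses at one size.  The
reported acuity is the smallest size answered correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ORIENTATIONS",
    "PacingSpec",
    "TriggerParams",
    "StaircaseState",
    "OptotypeTrial",
    "AcuityResult",
    "StreamExhaustedError",
    "pacing_from_bpm",
    "predict_zero_crossing",
    "should_display_optotype",
    "find_optotype_onsets",
    "staircase_update",
    "run_sva",
    "run_dva",
    "write_trial_log",
]

ORIENTATIONS = ("up", "down", "left", "right")

#: An observer maps (logmar, true orientation) -> reported orientation.
Observer = Callable[[float, str], str]


@dataclass(frozen=True)
class PacingSpec:
    """Metronome pacing: one beat = one single-direction head turn.

    At 60 bpm a left-to-right turn takes 1 s, so a full cycle takes 2 s
    (0.5 Hz, 30 cycles per minute).
    """

    bpm: float
    half_cycle_s: float
    cycle_hz: float


def pacing_from_bpm(bpm: float) -> PacingSpec:
    if bpm <= 0:
        raise ValueError("bpm must be positive")
    return PacingSpec(bpm=bpm, half_cycle_s=60.0 / bpm, cycle_hz=bpm / 120.0)


@dataclass(frozen=True)
class TriggerParams:
    """Latency-compensated optotype trigger parameters.

    horizon_ms : how far ahead the zero crossing is anticipated; equals the
        assumed end-to-end system latency (default 130 ms).
    center_limit_deg : the head must be within this angle of straight ahead.
    min_speed_dps : minimum speed toward center for a flash to be allowed.
    fit_window_samples : recent samples in the least-squares line fit.
    """

    horizon_ms: float = 130.0
    center_limit_deg: float = 20.0
    min_speed_dps: float = 60.0
    fit_window_samples: int = 5

    def __post_init__(self) -> None:
        for name in ("horizon_ms", "center_limit_deg", "min_speed_dps", "fit_window_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TriggerParams.{name} must be positive")


def _line_fit(history: Sequence[Tuple[float, float]], k: int) -> Tuple[float, float, float]:
    """LS line through the last ``k`` points; returns (t_now, theta_fit, slope)."""
    pts = history[-k:]
    t_now = pts[-1][0]
    t = np.array([p[0] for p in pts], dtype=float) - t_now
    th = np.array([p[1] for p in pts], dtype=float)
    if len(pts) == 2:
        slope = (th[1] - th[0]) / (t[1] - t[0])
        return t_now, th[1], float(slope)
    tm, thm = t.mean(), th.mean()
    denom = float(((t - tm) ** 2).sum())
    slope = float(((t - tm) * (th - thm)).sum() / denom)
    intercept = float(thm - slope * tm)  # fitted position at t_now
    return t_now, intercept, slope


def predict_zero_crossing(
    position_history: Sequence[Tuple[float, float]],
    horizon_ms: float = 130.0,
    fit_window_samples: int = 5,
) -> Tuple[bool, Optional[float]]:
    """Will the head cross straight-ahead within the horizon, and when?

    Fits a least-squares line through the most recent
    ``fit_window_samples`` points of ``position_history`` (pairs of
    ``(t_seconds, angle_deg)``) and extrapolates it forward.  Returns
    ``(True, t_cross)`` when the line's root lies within ``horizon_ms`` of
    the newest sample, otherwise ``(False, None)``.
    """
    if len(position_history) < 2:
        raise ValueError("predict_zero_crossing needs at least 2 history points")
    t_now, theta, slope = _line_fit(position_history, fit_window_samples)
    if slope == 0.0:
        return False, None
    dt_cross = -theta / slope
    if 0.0 <= dt_cross <= horizon_ms / 1000.0:
        return True, t_now + dt_cross
    return False, None


def should_display_optotype(
    position_history: Sequence[Tuple[float, float]],
    velocity_now: float,
    params: TriggerParams | None = None,
) -> bool:
    """Gate deciding whether the optotype may flash right now.

    True iff the head is within ``center_limit_deg`` of straight ahead,
    moving toward center faster than ``min_speed_dps``, and the predicted
    zero crossing falls within the anticipation horizon.
    """
    params = params or TriggerParams()
    if len(position_history) < 2:
        return False
    theta_now = position_history[-1][1]
    if abs(theta_now) >= params.center_limit_deg:
        return False
    if abs(velocity_now) <= params.min_speed_dps:
        return False
    if theta_now * velocity_now >= 0:  # not moving toward center
        return False
    will_cross, _ = predict_zero_crossing(
        position_history, params.horizon_ms, params.fit_window_samples
    )
    return will_cross


@dataclass(frozen=True)
class _Onset:
    t_on: float
    head_speed_at_on: float
    direction_at_on: str  # side the head is moving toward: 'rightward'/'leftward'


def find_optotype_onsets(
    positions: Sequence[Tuple[float, float]],
    params: TriggerParams | None = None,
) -> List[_Onset]:
    """Scan a head-position trace and schedule optotype onsets.

    At each sample the trigger fits a line through the recent history and,
    once all display gates pass and the compensated flash time
    ``t_cross - horizon`` falls before the next sample arrives, schedules
    the onset at ``max(t_now, t_cross - horizon)``.  Scheduling at the
    predicted instant (rather than on the next frame) keeps onset timing
    free of sample-grid quantization.  One onset is issued per zero
    crossing: the trigger re-arms only after the observed position changes
    sign.
    """
    params = params or TriggerParams()
    horizon_s = params.horizon_ms / 1000.0
    onsets: List[_Onset] = []
    hist: List[Tuple[float, float]] = []
    armed = True
    sign_at_fire = 0
    prev_dt = None
    for i, (t, th) in enumerate(positions):
        hist.append((t, th))
        if len(hist) > params.fit_window_samples:
            hist.pop(0)
        if not armed:
            if sign_at_fire != 0 and th * sign_at_fire < 0:
                armed = True
            else:
                continue
        if len(hist) < 2:
            continue
        t_now, theta, slope = _line_fit(hist, params.fit_window_samples)
        if i + 1 < len(positions):
            dt_next = positions[i + 1][0] - t
        else:
            dt_next = prev_dt if prev_dt is not None else 0.0
        prev_dt = t - positions[i - 1][0] if i > 0 else dt_next
        if abs(th) >= params.center_limit_deg:
            continue
        if abs(slope) <= params.min_speed_dps:
            continue
        if th * slope >= 0:
            continue
        if slope == 0.0:
            continue
        dt_cross = -theta / slope
        if dt_cross < 0:
            continue
        # fire when the compensated flash time lands before the next sample
        t_flash = t + dt_cross - horizon_s
        if t_flash > t + dt_next:
            continue
        onsets.append(
            _Onset(
                t_on=max(t, t_flash),
                head_speed_at_on=abs(slope),
                direction_at_on="rightward" if slope > 0 else "leftward",
            )
        )
        armed = False
        sign_at_fire = 1 if th > 0 else (-1 if th < 0 else (1 if slope < 0 else -1))
    return onsets


# --------------------------------------------------------------------------
# logMAR staircase
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseState:
    """Descending staircase over optotype size (logMAR).

    A correct response shrinks the optotype by ``step_logmar`` and resets
    the consecutive-incorrect counter; an incorrect response re-presents
    the same size.  Three consecutive incorrect responses terminate the
    test with acuity = the smallest size answered correctly
    (``current + step``).  A correct answer at the configured floor
    terminates with acuity = floor.
    """

    current_logmar: float = 1.0
    step_logmar: float = 0.1
    floor_logmar: float = 0.0
    consecutive_incorrect: int = 0
    history: tuple = ()
    terminated: bool = False
    acuity_logmar: Optional[float] = None

    MAX_CONSECUTIVE_INCORRECT = 3


def staircase_update(
    state: StaircaseState,
    correct: bool,
    orientation: Optional[str] = None,
    response: Optional[str] = None,
) -> StaircaseState:
    """Advance the staircase by one response."""
    if state.terminated:
        raise ValueError("staircase already terminated; no further updates allowed")
    history = state.history + ((state.current_logmar, orientation, response, bool(correct)),)
    if correct:
        if state.current_logmar <= state.floor_logmar + 1e-9:
            return replace(
                state, history=history, consecutive_incorrect=0,
                terminated=True, acuity_logmar=state.floor_logmar,
            )
        return replace(
            state,
            history=history,
            consecutive_incorrect=0,
            current_logmar=round(state.current_logmar - state.step_logmar, 10),
        )
    n_bad = state.consecutive_incorrect + 1
    if n_bad >= StaircaseState.MAX_CONSECUTIVE_INCORRECT:
        return replace(
            state,
            history=history,
            consecutive_incorrect=n_bad,
            terminated=True,
            acuity_logmar=round(state.current_logmar + state.step_logmar, 10),
        )
    return replace(state, history=history, consecutive_incorrect=n_bad)


@dataclass(frozen=True)
class OptotypeTrial:
    """One optotype presentation and the participant's response."""

    trial_idx: int
    t_on: float
    logmar: float
    orientation: str
    response: str
    correct: bool
    head_speed_at_on: float
    direction_at_on: str


@dataclass(frozen=True)
class AcuityResult:
    """Outcome of a staircase run."""

    acuity_logmar: float
    trials: Tuple[OptotypeTrial, ...]
    mode: str  # 'sva' or 'dva'
    acuity_by_direction: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


class StreamExhaustedError(RuntimeError):
    """The motion stream ended before the staircase terminated."""

    def __init__(self, message: str, trials: Sequence[OptotypeTrial]):
        super().__init__(message)
        self.trials = tuple(trials)


def _draw_orientation(rng: np.random.Generator) -> str:
    return ORIENTATIONS[int(rng.integers(0, 4))]


def run_sva(
    observer: Observer,
    start_logmar: float = 1.0,
    floor_logmar: float = 0.0,
    step_logmar: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> AcuityResult:
    """Static visual acuity: the staircase runs with the head still."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = StaircaseState(
        current_logmar=start_logmar, step_logmar=step_logmar, floor_logmar=floor_logmar
    )
    trials: List[OptotypeTrial] = []
    t = 0.0
    while not state.terminated:
        orientation = _draw_orientation(rng)
        response = observer(state.current_logmar, orientation)
        correct = response == orientation
        trials.append(
            OptotypeTrial(
                trial_idx=len(trials), t_on=t, logmar=state.current_logmar,
                orientation=orientation, response=response, correct=correct,
                head_speed_at_on=0.0, direction_at_on="none",
            )
        )
        state = staircase_update(state, correct, orientation, response)
        t += 1.0
    return AcuityResult(acuity_logmar=state.acuity_logmar, trials=tuple(trials), mode="sva")


def run_dva(
    observer: Observer,
    positions: Sequence[Tuple[float, float]],
    trigger_params: TriggerParams | None = None,
    start_logmar: float = 1.0,
    floor_logmar: float = 0.0,
    step_logmar: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> AcuityResult:
    """Dynamic visual acuity over a paced head-motion trace.

    ``positions`` is the reported head-position trace ``(t_s, angle_deg)``.
    Optotypes are presented only at trigger-scheduled onsets (near head
    zero crossings); the staircase advances one response per onset.  Raises
    :class:`StreamExhaustedError` (carrying the partial trial log) when the
    trace ends before the staircase terminates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = find_optotype_onsets(positions, trigger_params)
    state = StaircaseState(
        current_logmar=start_logmar, step_logmar=step_logmar, floor_logmar=floor_logmar
    )
    trials: List[OptotypeTrial] = []
    for onset in onsets:
        orientation = _draw_orientation(rng)
        response = observer(state.current_logmar, orientation)
        correct = response == orientation
        trials.append(
            OptotypeTrial(
                trial_idx=len(trials), t_on=onset.t_on, logmar=state.current_logmar,
                orientation=orientation, response=response, correct=correct,
                head_speed_at_on=onset.head_speed_at_on,
                direction_at_on=onset.direction_at_on,
            )
        )
        state = staircase_update(state, correct, orientation, response)
        if state.terminated:
            break
    if not state.terminated:
        raise StreamExhaustedError(
            f"motion trace ended after {len(onsets)} onsets, before staircase termination",
            trials,
        )
    by_dir = {}
    for d in ("leftward", "rightward"):
        correct_sizes = [tr.logmar for tr in trials if tr.direction_at_on == d and tr.correct]
        if correct_sizes:
            by_dir[d] = min(correct_sizes)
    return AcuityResult(
        acuity_logmar=state.acuity_logmar, trials=tuple(trials), mode="dva",
        acuity_by_direction=by_dir,
    )


def write_trial_log(trials: Sequence[OptotypeTrial], path) -> None:
    pd.DataFrame(
        {
            "trial_idx": [tr.trial_idx for tr in trials],
            "t_on": [tr.t_on for tr in trials],
            "logmar": [tr.logmar for tr in trials],
            "orientation": [tr.orientation for tr in trials],
            "response": [tr.response for tr in trials],
            "correct": [int(tr.correct) for tr in trials],
            "head_speed_at_on": [tr.head_speed_at_on for tr in trials],
            "direction": [tr.direction_at_on for tr in trials],
        }
    ).to_csv(path, index=False, float_format="%.12g")
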