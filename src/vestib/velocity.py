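"""Chain-based estimation of current head direction and rotation speed.

The estimator groups instantaneous angular velocity samples into *chains*
of samples moving in the same direction (clockwise or counterclockwise).
Because consumer tracker data is noisy, one sample moving opposite to the
chain's direction is tolerated inside a chain, and at least two samples
moving in the same direction are required to form a chain at all.  Only
samples inside a trailing window (default 0.25 s) enter the calculation.

The direction of the longest chain is reported as the current movement
direction, and the speed is the mean of the absolute values of all
velocity samples belonging to any retained chain.  If the speed drops
below a clinician-set threshold, the movement is classified as too slow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence

from .streams import VelocitySample

__all__ = [
    "EstimatorParams",
    "Chain",
    "MotionEstimate",
    "assemble_chains",
    "estimate_motion",
    "classify_speed",
]

#: direction labels
CW = "cw"  # positive velocity: rightward yaw / upward pitch
CCW = "ccw"
NONE = "none"


@dataclass(frozen=True)
class EstimatorParams:
    """Tuning knobs of the chain estimator.

    window_s : trailing window length in seconds (samples with
        ``t in (t_now - window_s, t_now]`` are used).
    opposite_tolerance : opposite-sign samples tolerated per chain.
    min_chain_len : minimum members for a chain to count.
    """

    window_s: float = 0.25
    opposite_tolerance: int = 1
    min_chain_len: int = 2

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.opposite_tolerance < 0:
            raise ValueError("opposite_tolerance must be >= 0")
        if self.min_chain_len < 2:
            raise ValueError("min_chain_len must be >= 2")


@dataclass(frozen=True)
class Chain:
    """A run of velocity samples moving in the same direction."""

    direction: str  # 'cw' or 'ccw'
    member_indices: tuple  # indices into the velocity window

    @property
    def length(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class MotionEstimate:
    """Windowed direction + speed estimate.

    ``direction`` is ``'none'`` exactly when no chain formed, in which case
    ``classification`` is ``'no_chain'`` and ``speed`` is 0.
    """

    t: float
    direction: str
    speed: float
    n_samples_used: int
    classification: str  # 'above_threshold' | 'too_slow' | 'no_chain'


def _sign(v: float) -> int:
    if v > 0:
        return 1
    if v < 0:
        return -1
    return 0


def assemble_chains(values: Sequence[float], params: EstimatorParams | None = None) -> List[Chain]:
    """Greedy left-to-right chain assembly over signed velocity values.

    A chain opens at the first sample with a definite sign and extends while
    the next sample shares the chain's sign, or is an opposite-sign sample
    and the chain still has tolerance budget left.  Exactly-zero samples
    carry no direction: they terminate the current chain and belong to no
    chain.  Chains shorter than ``min_chain_len`` are discarded.

    ``values`` may be raw floats or :class:`VelocitySample` objects.
    """
    params = params or EstimatorParams()
    vals = [v.value if isinstance(v, VelocitySample) else float(v) for v in values]
    chains: List[Chain] = []
    members: List[int] = []
    direction = 0
    opposites = 0

    def close() -> None:
        nonlocal members, direction, opposites
        if direction != 0 and len(members) >= params.min_chain_len:
            chains.append(
                Chain(direction=CW if direction > 0 else CCW, member_indices=tuple(members))
            )
        members = []
        direction = 0
        opposites = 0

    for i, v in enumerate(vals):
        s = _sign(v)
        if s == 0:
            close()
            continue
        if direction == 0:
            direction, members, opposites = s, [i], 0
        elif s == direction:
            members.append(i)
        elif opposites < params.opposite_tolerance:
            members.append(i)
            opposites += 1
        else:
            close()
            direction, members, opposites = s, [i], 0
    close()
    return chains


def estimate_motion(
    vel_series: Sequence[VelocitySample],
    t_now: float,
    params: EstimatorParams | None = None,
) -> MotionEstimate:
    """Estimate current head movement from a trailing window of velocities.

    Uses only samples with ``t_mid in (t_now - window_s, t_now]``.  The
    direction comes from the longest chain (ties go to the most recent
    chain); the speed is the mean absolute velocity over the members of all
    retained chains.  Degenerate input yields a ``no_chain`` estimate rather
    than an error.
    """
    params = params or EstimatorParams()
    window = [v for v in vel_series if t_now - params.window_s < v.t_mid <= t_now]
    chains = assemble_chains(window, params)
    if not chains:
        return MotionEstimate(t=t_now, direction=NONE, speed=0.0, n_samples_used=0, classification="no_chain")
    # longest chain wins; on ties the later (more recent) chain wins, which
    # max() with plain key already gives if we scan in reverse order.
    best = max(reversed(chains), key=lambda c: c.length)
    member_values = [abs(window[i].value) for c in chains for i in c.member_indices]
    speed = sum(member_values) / len(member_values)
    return MotionEstimate(
        t=t_now,
        direction=best.direction,
        speed=speed,
        n_samples_used=len(member_values),
        classification="above_threshold",  # provisional; refined by classify_speed
    )


def classify_speed(estimate: MotionEstimate, threshold_dps: float) -> MotionEstimate:
    """Classify an estimate against the minimum head-speed threshold.

    The comparison is inclusive: a head held exactly at the target speed
    passes.  A ``no_chain`` estimate is preserved untouched.
    """
    if threshold_dps <= 0:
        raise ValueError("threshold_dps must be positive")
    if estimate.classification == "no_chain":
        return estimate
    label = "above_threshold" if estimate.speed >= threshold_dps else "too_slow"
    return replace(estimate, classification=label)
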