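"""Target geometry and gaze-on-target determination.

The eye is considered on target when gaze falls within the radius of the
visible target image.  Target radii are specified as a ratio of screen
height (small/medium/large presets).  Feedback logic additionally applies a
short grace period so that a brief off-target excursion does not
immediately stop the exercise reward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .streams import GazeHeadSample, ScreenGeometry

__all__ = [
    "DEFAULT_SIZE_RATIOS",
    "TargetSpec",
    "OnTargetState",
    "target_radius",
    "gaze_on_target",
    "update_on_target_state",
]

#: Target radius as a fraction of screen height per size class.  The medium
#: radius is anchored to the platform's logged +/-0.1 normalized on-target
#: band; small and large are stand-ins pending the vendor's exact ratio
#: table and are configurable per session.
DEFAULT_SIZE_RATIOS: Mapping[str, float] = {"small": 0.05, "medium": 0.10, "large": 0.15}


def target_radius(size_class: str, ratios: Mapping[str, float] | None = None) -> float:
    """Radius (screen-height units) for a size class, from a ratio table."""
    table = dict(ratios) if ratios is not None else dict(DEFAULT_SIZE_RATIOS)
    try:
        return float(table[size_class])
    except KeyError:
        raise ValueError(
            f"unknown target size {size_class!r}; valid classes: {sorted(table)}"
        ) from None


@dataclass(frozen=True)
class TargetSpec:
    """An on-screen target: center in normalized coordinates plus radius.

    ``radius_norm`` is in screen-height units.  ``region`` selects the
    acceptance test: ``'circle'`` (distance aspect-corrected so the region
    is circular on the physical screen) or ``'band'`` (independent per-axis
    limits, the raw +/-radius band the platform logs use).
    """

    center: tuple = (0.5, 0.5)
    size_class: str = "medium"
    radius_norm: float = DEFAULT_SIZE_RATIOS["medium"]
    region: str = "circle"

    def __post_init__(self) -> None:
        if self.radius_norm <= 0:
            raise ValueError("radius_norm must be positive")
        if self.region not in ("circle", "band"):
            raise ValueError("region must be 'circle' or 'band'")

    @classmethod
    def from_size_class(
        cls,
        size_class: str,
        center: tuple = (0.5, 0.5),
        ratios: Mapping[str, float] | None = None,
        region: str = "circle",
    ) -> "TargetSpec":
        return cls(center=center, size_class=size_class,
                   radius_norm=target_radius(size_class, ratios), region=region)


def gaze_on_target(
    sample: GazeHeadSample,
    target: TargetSpec,
    geometry: ScreenGeometry | None = None,
) -> bool:
    """True iff gaze is valid and inside the target's acceptance region.

    Invalid gaze (eyes closed, tracking lost) is never on target.  For the
    circular region, the x offset is scaled by the physical aspect ratio so
    distances are isotropic in screen-height units.
    """
    if not sample.gaze_valid:
        return False
    geometry = geometry or ScreenGeometry()
    dx = sample.gaze_x - target.center[0]
    dy = sample.gaze_y - target.center[1]
    if target.region == "band":
        return abs(dx) <= target.radius_norm and abs(dy) <= target.radius_norm
    dx_h = dx * geometry.aspect  # width units -> height units
    return (dx_h * dx_h + dy * dy) ** 0.5 <= target.radius_norm


@dataclass(frozen=True)
class OnTargetState:
    """Gaze-on-target state with an off-target grace period.

    ``off_since`` is set exactly while gaze is off target.  The feedback
    predicate :meth:`within_grace` stays true until the gaze has been off
    target for longer than ``grace_s``.
    """

    on_target: bool = True
    off_since: Optional[float] = None
    grace_s: float = 0.5
    t: float = float("-inf")

    def within_grace(self, t: Optional[float] = None) -> bool:
        if self.on_target:
            return True
        t = self.t if t is None else t
        return (t - self.off_since) <= self.grace_s


def update_on_target_state(
    state: OnTargetState,
    sample: GazeHeadSample,
    target: TargetSpec,
    t: float,
    geometry: ScreenGeometry | None = None,
) -> OnTargetState:
    """Advance the grace-period state machine by one sample."""
    if t < state.t:
        raise ValueError(f"time regression: {t} < {state.t}")
    if gaze_on_target(sample, target, geometry):
        return replace(state, on_target=True, off_since=None, t=t)
    off_since = state.off_since if state.off_since is not None else t
    return replace(state, on_target=False, off_since=off_since, t=t)
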