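"""Digital scoring of vestibular patient-reported outcome measures.

Instruments are defined declaratively in ``data/instruments.json`` (item
counts, answer domains, weights, scales, interpretation bands, minimal
detectable change), so revisions of questionnaire text or weight tables do
not touch scoring code.  The digital forms forbid skipped items, so every
scorer requires a complete response set.

Covered instruments:

* mABC — modified Activities-specific Balance Confidence scale: 16 items
  rated 0/25/50/75/100 %, scored as the mean (higher = more confident).
* DHI — Dizziness Handicap Inventory: 25 items answered yes/sometimes/no,
  weighted 4/2/0 and summed to 0–100 (higher = greater handicap).
* DRS — Disability Rating Scale: one integer 0–5 with None/Mild/Moderate/
  Severe interpretation bands.
* VAS — 10-cm visual analog scales for symptom intensity; a score is the
  distance from 0 to the mark, and baseline-to-post differences may be
  negative.
* mMST — modified Motion Sensitivity Test: intensity change and symptom
  duration after each of 10 movements combine into the Motion Sensitivity
  Quotient.  The published instrument defines the quotient; this package
  reconstructs it with all constants in the data table.
* SUS — System Usability Scale, standard 0–100 scoring plus the curved
  letter-grade interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Mapping, Optional, Sequence

__all__ = [
    "InstrumentResponse",
    "ScoreResult",
    "instrument_definitions",
    "score_mabc",
    "score_dhi",
    "score_drs",
    "score_vas",
    "vas_difference",
    "score_mmst",
    "score_sus",
    "score_response",
]

VAS_VARIANTS = ("vas_interference", "vas_oscillopsia", "vas_disequilibrium", "vas_dizziness")


def instrument_definitions() -> dict:
    """The declarative instrument table (parsed once per call)."""
    with resources.files("vestib.data").joinpath("instruments.json").open("r") as fh:
        return json.load(fh)


_DEFS = instrument_definitions()


@dataclass(frozen=True)
class InstrumentResponse:
    """A complete answer set for one instrument.

    ``items`` layout per instrument: mabc — 16 numbers on the 0..100 grid;
    dhi — 25 strings yes/sometimes/no; drs — [int]; vas_* — [mark_cm] or
    [baseline, post]; mmst — [baseline, [intensity, duration_s] * 10];
    sus — 10 integers 1..5.
    """

    instrument: str
    items: tuple
    timestamp: Optional[str] = None


@dataclass(frozen=True)
class ScoreResult:
    """A scalar instrument score with scale, interpretation, and MDC."""

    instrument: str
    value: float
    scale_min: float
    scale_max: float
    category: Optional[str] = None
    mdc: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.scale_min <= self.value <= self.scale_max:
            raise ValueError(
                f"{self.instrument} score {self.value} outside "
                f"[{self.scale_min}, {self.scale_max}]"
            )


def score_mabc(items: Sequence[float]) -> ScoreResult:
    """Balance-confidence score: the mean of 16 items rated on the
    0/25/50/75/100 % grid."""
    spec = _DEFS["mabc"]
    if len(items) != spec["n_items"]:
        raise ValueError(f"mABC requires {spec['n_items']} items, got {len(items)}")
    grid = set(spec["answer_grid"])
    for i, v in enumerate(items):
        if v not in grid:
            raise ValueError(f"mABC item {i + 1} value {v!r} not on the grid {sorted(grid)}")
    lo, hi = spec["scale"]
    return ScoreResult("mabc", sum(items) / len(items), lo, hi)


def score_dhi(items: Sequence[str], weights: Mapping[str, float] | None = None) -> ScoreResult:
    """Dizziness-handicap total: yes/sometimes/no weighted 4/2/0, range 0–100."""
    spec = _DEFS["dhi"]
    if len(items) != spec["n_items"]:
        raise ValueError(f"DHI requires {spec['n_items']} items, got {len(items)}")
    w = dict(weights) if weights is not None else spec["weights"]
    total = 0.0
    for i, ans in enumerate(items):
        if ans not in w:
            raise ValueError(f"DHI item {i + 1} answer {ans!r} not in {sorted(w)}")
        total += w[ans]
    lo, hi = spec["scale"]
    return ScoreResult("dhi", total, lo, hi, mdc=spec["mdc"])


def score_drs(value: int) -> ScoreResult:
    """Disability rating 0–5 with None/Mild/Moderate/Severe banding."""
    spec = _DEFS["drs"]
    lo, hi = spec["scale"]
    if not (isinstance(value, int) and lo <= value <= hi):
        raise ValueError(f"DRS value must be an integer in [{lo}, {hi}], got {value!r}")
    category = next(
        c["label"] for c in spec["categories"] if c["min"] <= value <= c["max"]
    )
    return ScoreResult("drs", float(value), lo, hi, category=category, mdc=spec["mdc"])


def score_vas(mark_cm: float, variant: str = "vas_dizziness") -> ScoreResult:
    """Visual-analog score: the distance (cm) from 0 to the mark on a 10-cm line."""
    spec = _DEFS["vas"]
    lo, hi = spec["scale"]
    if not lo <= mark_cm <= hi:
        raise ValueError(f"VAS mark must be within [{lo}, {hi}] cm, got {mark_cm}")
    if variant not in VAS_VARIANTS:
        raise ValueError(f"unknown VAS variant {variant!r}; valid: {VAS_VARIANTS}")
    mdc = spec["mdc_by_variant"].get(variant)
    return ScoreResult(variant, float(mark_cm), lo, hi, mdc=mdc)


def vas_difference(post_cm: float, baseline_cm: float, variant: str = "vas_dizziness") -> ScoreResult:
    """Post-minus-baseline VAS change (e.g., after one minute of head turns).

    May be negative when symptoms eased.
    """
    post = score_vas(post_cm, variant)
    base = score_vas(baseline_cm, variant)
    lo, hi = _DEFS["vas"]["scale"]
    return ScoreResult(
        f"{variant}_difference", post.value - base.value, lo - hi, hi - lo, mdc=post.mdc
    )


def _duration_points(duration_s: float, bands: Sequence[Mapping]) -> int:
    for b in bands:
        lo_ok = duration_s > b["min_s"] if b.get("min_exclusive") else duration_s >= b["min_s"]
        if b["max_s"] is None:
            hi_ok = True
        else:
            hi_ok = duration_s < b["max_s"] if b.get("max_exclusive") else duration_s <= b["max_s"]
        if lo_ok and hi_ok:
            return b["points"]
    raise ValueError(f"no duration band matches {duration_s} s")


def score_mmst(
    baseline_intensity: float,
    movements: Sequence[Sequence[float]],
) -> ScoreResult:
    """Motion Sensitivity Quotient from 10 provoking movements.

    Per movement the item score is ``max(0, intensity - baseline)`` plus
    duration points (<5 s: 0; 5–10 s: 1; 11–30 s: 2; >30 s: 3) — symptom
    relief never scores negative.  The quotient is
    ``n_positive * sum(scores) / 20.48`` where ``n_positive`` counts
    movements with a positive item score.
    """
    spec = _DEFS["mmst"]
    ilo, ihi = spec["intensity_scale"]
    if not ilo <= baseline_intensity <= ihi:
        raise ValueError(f"baseline intensity must be within [{ilo}, {ihi}]")
    if len(movements) != spec["n_movements"]:
        raise ValueError(f"mMST requires {spec['n_movements']} movements, got {len(movements)}")
    scores = []
    for i, (intensity, duration_s) in enumerate(movements):
        if not ilo <= intensity <= ihi:
            raise ValueError(f"movement {i + 1}: intensity {intensity} outside [{ilo}, {ihi}]")
        if duration_s < 0:
            raise ValueError(f"movement {i + 1}: negative duration {duration_s}")
        scores.append(
            max(0.0, intensity - baseline_intensity)
            + _duration_points(duration_s, spec["duration_points"])
        )
    n_positive = sum(1 for s in scores if s > 0)
    msq = n_positive * sum(scores) / spec["quotient_divisor"]
    max_item = (ihi - ilo) + max(b["points"] for b in spec["duration_points"])
    n = spec["n_movements"]
    scale_max = n * (n * max_item) / spec["quotient_divisor"]
    return ScoreResult("mmst", msq, 0.0, scale_max)


def score_sus(items: Sequence[float]) -> ScoreResult:
    """Standard System Usability Scale score with curved letter grade.

    Odd items contribute ``value - 1``, even items ``5 - value``; the sum is
    scaled by 2.5 to 0–100 and graded on the curved (percentile-anchored)
    letter scale.
    """
    spec = _DEFS["sus"]
    if len(items) != spec["n_items"]:
        raise ValueError(f"SUS requires {spec['n_items']} items, got {len(items)}")
    ilo, ihi = spec["item_scale"]
    total = 0.0
    for i, v in enumerate(items):
        if not ilo <= v <= ihi:
            raise ValueError(f"SUS item {i + 1} value {v!r} outside [{ilo}, {ihi}]")
        total += (v - ilo) if (i + 1) % 2 == 1 else (ihi - v)
    value = total * 2.5
    grade = next(g["grade"] for g in spec["curved_grades"] if value >= g["min"])
    lo, hi = spec["scale"]
    return ScoreResult("sus", value, lo, hi, category=grade)


def score_response(response: InstrumentResponse) -> ScoreResult:
    """Score an :class:`InstrumentResponse` by dispatching on its instrument."""
    name = response.instrument
    if name == "mabc":
        return score_mabc(response.items)
    if name == "dhi":
        return score_dhi(response.items)
    if name == "drs":
        return score_drs(response.items[0])
    if name in VAS_VARIANTS:
        if len(response.items) == 1:
            return score_vas(response.items[0], name)
        if len(response.items) == 2:
            return vas_difference(response.items[1], response.items[0], name)
        raise ValueError(f"{name} expects [mark] or [baseline, post], got {response.items!r}")
    if name == "mmst":
        baseline, movements = response.items[0], response.items[1:]
        return score_mmst(baseline, movements)
    if name == "sus":
        return score_sus(response.items)
    raise ValueError(f"unknown instrument {name!r}")
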