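"""Assembly of the patient summary rehabilitation report.

The report is a single schema-versioned JSON document bundling session
configurations and metrics, PRO score trajectories with minimal-detectable-
change flags, and weekly adherence.  Serialization is deterministic: keys
are sorted and identical inputs produce byte-identical output, so reports
can be diffed and golden-tested.
"""

from __future__ import annotations

import json
from typing import List, Mapping, Sequence

from .exercises import compute_adherence
from .reliability import MDC_REGISTRY

__all__ = ["SCHEMA_VERSION", "build_report", "report_json"]

SCHEMA_VERSION = "1.0"


def _require(cond: bool, path: str, message: str, errors: List[str]) -> None:
    if not cond:
        errors.append(f"{path}: {message}")


def build_report(
    sessions: Sequence[Mapping],
    scores: Sequence[Mapping],
    adherence: Sequence[Mapping],
) -> dict:
    """Build the summary report document.

    Parameters
    ----------
    sessions : list of {"config": dict, "metrics": dict}
        Echo of each exercise session's configuration and aggregates.
    scores : list of {"instrument": str, "session": label, "value": number}
        PRO scores over time; consecutive scores of an instrument with a
        registered minimal detectable change are flagged when the change
        exceeds it.
    adherence : list of {"week": int, "completed": n, "assigned": n}
        Weekly exercise counts; weeks are sorted deterministically.
    """
    errors: List[str] = []
    for i, s in enumerate(sessions):
        _require(isinstance(s, Mapping) and "config" in s and "metrics" in s,
                 f"sessions[{i}]", "must contain 'config' and 'metrics'", errors)
    for i, s in enumerate(scores):
        ok = isinstance(s, Mapping) and {"instrument", "value"} <= set(s)
        _require(ok, f"scores[{i}]", "must contain 'instrument' and 'value'", errors)
    for i, w in enumerate(adherence):
        ok = isinstance(w, Mapping) and {"week", "completed", "assigned"} <= set(w)
        _require(ok, f"adherence[{i}]", "must contain 'week', 'completed', 'assigned'", errors)
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors))

    trajectories: dict = {}
    for s in scores:
        trajectories.setdefault(s["instrument"], []).append(
            {"session": s.get("session"), "value": s["value"]}
        )
    for name, traj in trajectories.items():
        mdc = MDC_REGISTRY.get(name)
        for prev, cur in zip(traj, traj[1:]):
            if mdc is not None:
                cur["mdc_exceeded"] = abs(cur["value"] - prev["value"]) > mdc

    weeks = sorted(adherence, key=lambda w: w["week"])
    if weeks:
        adh = compute_adherence([w["completed"] for w in weeks], [w["assigned"] for w in weeks])
        adherence_block = {
            "weeks": [
                {"week": w["week"], "completed": w["completed"], "assigned": w["assigned"],
                 "pct": p}
                for w, p in zip(weeks, adh["weekly_pct"])
            ],
            "overall_pct": adh["overall_pct"],
        }
    else:
        adherence_block = {"weeks": [], "overall_pct": None}

    return {
        "schema_version": SCHEMA_VERSION,
        "sessions": [dict(s) for s in sessions],
        "pro_trajectories": trajectories,
        "adherence": adherence_block,
    }


def report_json(report: Mapping) -> str:
    """Deterministic serialization: sorted keys, fixed separators."""
    return json.dumps(report, sort_keys=True, separators=(",", ":"), allow_nan=False)
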