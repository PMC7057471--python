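"""Clinical sepsis classifiers over worst-value panels.

Three rule-based classifications of a suspected-infection hospitalization:

* **SOFA** — total Sequential Organ Failure Assessment points >= 2 summed
  across the six organ systems (respiratory, cardiovascular, renal,
  hematological, hepatic, neurological).
* **qSOFA** — at least two of: altered mentation (GCS < 15 or non-alert on
  the AVPU scale), systolic blood pressure <= 100 mmHg, respiratory
  rate >= 22 /min.
* **EHR** — surveillance-style organ-dysfunction markers: vasopressor use,
  mechanical ventilation, creatinine >= 2.0 mg/dL, bilirubin >= 2.0 mg/dL,
  platelets < 100 x10^3/uL, or lactate >= 2.0 mmol/L; any one marker
  classifies the event as sepsis.

Missing panel values are treated as normal throughout: an absent measurement
contributes zero SOFA points and never satisfies a qSOFA or EHR criterion.
Only hospitalizations with chart-confirmed infection as a primary reason are
eligible to be classified sepsis under any of the three definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import InfectionEvent, WorstValuePanel

__all__ = [
    "SofaBreakdown",
    "DEFAULT_SOFA_TABLE",
    "sofa_score",
    "qsofa_classify",
    "ehr_classify",
    "classify_events",
    "SofaTableError",
]


class SofaTableError(ValueError):
    """Raised for a malformed SOFA threshold table."""


#: Default SOFA threshold table.  Each graded system lists cutpoints in
#: worsening order; the points awarded equal the number of cutpoints the
#: value crosses.  ``direction`` "below" means strictly less than the
#: cutpoint; "at_or_above" means greater than or equal.  The cardiovascular
#: system is special-cased: any vasopressor use scores
#: ``vasopressor_points`` (dose tiers are not abstracted), otherwise
#: MAP < 70 mmHg scores 1.  ``respiratory_support_required`` gates the 3-4
#: point respiratory tiers on mechanical ventilation when enabled.
DEFAULT_SOFA_TABLE: dict = {
    "respiratory": {
        "variable": "pao2_fio2_ratio",
        "direction": "below",
        "cutpoints": [400.0, 300.0, 200.0, 100.0],
    },
    "hematological": {
        "variable": "platelets_10e3_per_uL",
        "direction": "below",
        "cutpoints": [150.0, 100.0, 50.0, 20.0],
    },
    "hepatic": {
        "variable": "bilirubin_mg_dL",
        "direction": "at_or_above",
        "cutpoints": [1.2, 2.0, 6.0, 12.0],
    },
    "neurological": {
        "variable": "gcs_total",
        "direction": "below",
        "cutpoints": [15.0, 13.0, 10.0, 6.0],
    },
    "renal": {
        "variable": "creatinine_mg_dL",
        "direction": "at_or_above",
        "cutpoints": [1.2, 2.0, 3.5, 5.0],
    },
    "cardiovascular": {
        "map_cutpoint": 70.0,
        "vasopressor_points": 2,
    },
    "options": {
        "respiratory_support_required": False,
    },
}

SOFA_SYSTEMS = (
    "respiratory",
    "cardiovascular",
    "renal",
    "hematological",
    "hepatic",
    "neurological",
)


@dataclass(frozen=True)
class SofaBreakdown:
    """Per-system SOFA points and their total."""

    respiratory: int = 0
    cardiovascular: int = 0
    renal: int = 0
    hematological: int = 0
    hepatic: int = 0
    neurological: int = 0

    def __post_init__(self) -> None:
        for name in SOFA_SYSTEMS:
            v = getattr(self, name)
            if not (0 <= v <= 4):
                raise ValueError(f"SOFA {name} points {v} outside [0, 4]")

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in SOFA_SYSTEMS)


def _validate_table(table: Mapping) -> None:
    for system in ("respiratory", "hematological", "hepatic", "neurological", "renal"):
        spec = table.get(system)
        if spec is None:
            raise SofaTableError(f"SOFA table missing system '{system}'")
        cut = list(spec["cutpoints"])
        if len(cut) != 4:
            raise SofaTableError(f"SOFA {system}: expected 4 cutpoints, got {len(cut)}")
        direction = spec["direction"]
        if direction == "below":
            ok = all(a > b for a, b in zip(cut, cut[1:]))
        elif direction == "at_or_above":
            ok = all(a < b for a, b in zip(cut, cut[1:]))
        else:
            raise SofaTableError(f"SOFA {system}: unknown direction {direction!r}")
        if not ok:
            raise SofaTableError(f"SOFA {system}: cutpoints not monotone for {direction}")
    if "cardiovascular" not in table:
        raise SofaTableError("SOFA table missing system 'cardiovascular'")


def _graded_points(value: Optional[float], spec: Mapping) -> int:
    if value is None:
        return 0
    cut: Sequence[float] = spec["cutpoints"]
    if spec["direction"] == "below":
        return sum(value < c for c in cut)
    return sum(value >= c for c in cut)


def sofa_score(panel: WorstValuePanel, table: Mapping | None = None) -> SofaBreakdown:
    """Score a worst-value panel with the (config-overridable) SOFA table.

    Absent inputs score 0 points for their system.
    """
    table = DEFAULT_SOFA_TABLE if table is None else table
    _validate_table(table)
    opts = table.get("options", {})

    resp = _graded_points(panel.pao2_fio2_ratio, table["respiratory"])
    if opts.get("respiratory_support_required") and resp > 2:
        if not panel.mechanical_ventilation:
            resp = 2

    cv_spec = table["cardiovascular"]
    if panel.vasopressor_use:
        cardio = int(cv_spec.get("vasopressor_points", 2))
    elif panel.map_mmHg is not None and panel.map_mmHg < cv_spec.get("map_cutpoint", 70.0):
        cardio = 1
    else:
        cardio = 0

    return SofaBreakdown(
        respiratory=resp,
        cardiovascular=cardio,
        renal=_graded_points(panel.creatinine_mg_dL, table["renal"]),
        hematological=_graded_points(panel.platelets_10e3_per_uL, table["hematological"]),
        hepatic=_graded_points(panel.bilirubin_mg_dL, table["hepatic"]),
        neurological=_graded_points(panel.gcs_total, table["neurological"]),
    )


def qsofa_classify(panel: WorstValuePanel) -> tuple[int, bool]:
    """Count qSOFA criteria met; sepsis when the count is >= 2.

    Boundary values satisfy their criteria (SBP = 100, RR = 22, GCS = 14,
    AVPU = voice all count); an absent measurement never does.
    """
    altered = (panel.gcs_total is not None and panel.gcs_total < 15) or (
        panel.avpu is not None and panel.avpu != "alert"
    )
    low_sbp = panel.sbp_mmHg is not None and panel.sbp_mmHg <= 100
    high_rr = panel.resp_rate_per_min is not None and panel.resp_rate_per_min >= 22
    count = int(altered) + int(low_sbp) + int(high_rr)
    return count, count >= 2


#: EHR organ-dysfunction triggers: name -> predicate on a panel.
_EHR_TRIGGERS = {
    "vasopressor": lambda p: bool(p.vasopressor_use),
    "mechanical_ventilation": lambda p: bool(p.mechanical_ventilation),
    "creatinine": lambda p: p.creatinine_mg_dL is not None and p.creatinine_mg_dL >= 2.0,
    "bilirubin": lambda p: p.bilirubin_mg_dL is not None and p.bilirubin_mg_dL >= 2.0,
    "platelets": lambda p: p.platelets_10e3_per_uL is not None and p.platelets_10e3_per_uL < 100,
    "lactate": lambda p: p.lactate_mmol_L is not None and p.lactate_mmol_L >= 2.0,
}


def ehr_classify(panel: WorstValuePanel) -> tuple[frozenset[str], bool]:
    """Return the satisfied EHR organ-dysfunction triggers; sepsis iff any."""
    triggers = frozenset(name for name, pred in _EHR_TRIGGERS.items() if pred(panel))
    return triggers, bool(triggers)


def classify_events(
    events: Iterable[InfectionEvent], sofa_table: Mapping | None = None
) -> pd.DataFrame:
    """Classify every event under all three clinical definitions.

    Returns one row per event with the raw scores and the sepsis flags.
    Events without chart-confirmed primary infection keep their computed
    scores but are flagged non-sepsis under every definition, because the
    clinical criteria are defined on confirmed infection hospitalizations.
    """
    rows = []
    seen: set[str] = set()
    for ev in events:
        if ev.event_id in seen:
            raise ValueError(f"duplicate event key {ev.event_id!r}")
        seen.add(ev.event_id)
        breakdown = sofa_score(ev.panel, sofa_table)
        qsofa_count, qsofa_pos = qsofa_classify(ev.panel)
        triggers, ehr_pos = ehr_classify(ev.panel)
        eligible = ev.infection_primary
        rows.append(
            {
                "event_id": ev.event_id,
                "participant_id": ev.participant_id,
                "admission_date": ev.admission_date,
                "infection_primary": ev.infection_primary,
                "sofa_total": breakdown.total,
                "sofa_respiratory": breakdown.respiratory,
                "sofa_cardiovascular": breakdown.cardiovascular,
                "sofa_renal": breakdown.renal,
                "sofa_hematological": breakdown.hematological,
                "sofa_hepatic": breakdown.hepatic,
                "sofa_neurological": breakdown.neurological,
                "qsofa_count": qsofa_count,
                "ehr_triggers": ";".join(sorted(triggers)),
                "sofa_sepsis": eligible and breakdown.total >= 2,
                "qsofa_sepsis": eligible and qsofa_pos,
                "ehr_sepsis": eligible and ehr_pos,
            }
        )
    columns = [
        "event_id", "participant_id", "admission_date", "infection_primary",
        "sofa_total", "sofa_respiratory", "sofa_cardiovascular", "sofa_renal",
        "sofa_hematological", "sofa_hepatic", "sofa_neurological",
        "qsofa_count", "ehr_triggers", "sofa_sepsis", "qsofa_sepsis", "ehr_sepsis",
    ]
    return pd.DataFrame(rows, columns=columns)
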