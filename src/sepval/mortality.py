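"""90-day person-time mortality rates with censoring.

Follow-up for each suspected-infection event starts at the admission date
and ends at the earliest of: death, loss of Parts A+B coverage, initiation
of Part C, loss to follow-up, or 90 days from admission.  In-hospital deaths
count.  Rates are deaths per 100 person-years; a same-day death or censoring
contributes half a day of person-time so that the denominator is never zero
(config-overridable).

Rates are reported overall, within each classifier-positive group, and
within the four concordant/discordant cells of every claims x clinical pair.
The module also emits an analysis-ready survival dataset (time in days,
status, flags) for external proportional-hazards fits.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .linkage import CLASSIFIER_FLAGS
from .model import InfectionEvent, Participant

__all__ = [
    "FollowUpRecord",
    "follow_up",
    "build_followup",
    "rate_by_group",
    "mortality_report",
    "survival_dataset",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class FollowUpRecord:
    event_id: str
    participant_id: str
    start: dt.date
    end: dt.date
    died_in_window: bool
    stop_cause: str  # "death" | "ab_loss" | "part_c" | "ltfu" | "horizon"
    person_days: float

    @property
    def person_years(self) -> float:
        return self.person_days / DAYS_PER_YEAR


def follow_up(
    event: InfectionEvent,
    participant: Participant,
    horizon_days: int = 90,
    same_day_person_days: float = 0.5,
) -> FollowUpRecord:
    """Resolve the earliest-stopping-rule follow-up interval for one event."""
    adm = event.admission_date
    if participant.death_date is not None and participant.death_date < adm:
        raise ValueError(
            f"event {event.event_id}: death date {participant.death_date} precedes admission"
        )

    candidates: list[tuple[dt.date, str]] = [(adm + dt.timedelta(days=horizon_days), "horizon")]
    if participant.death_date is not None:
        candidates.append((participant.death_date, "death"))
    ab_end = participant.ab_censor_date(adm)
    if ab_end is not None:
        candidates.append((ab_end, "ab_loss"))
    c_start = participant.part_c_start()
    if c_start is not None and c_start >= adm:
        candidates.append((c_start, "part_c"))
    if participant.ltfu_date is not None and participant.ltfu_date >= adm:
        candidates.append((participant.ltfu_date, "ltfu"))

    # earliest stop wins; death takes precedence over a same-day censor
    end = min(d for d, _ in candidates)
    causes = [c for d, c in candidates if d == end]
    cause = "death" if "death" in causes else causes[0]
    died = cause == "death"
    person_days = float((end - adm).days)
    if person_days == 0:
        person_days = same_day_person_days
    return FollowUpRecord(
        event_id=event.event_id,
        participant_id=event.participant_id,
        start=adm,
        end=end,
        died_in_window=died,
        stop_cause=cause,
        person_days=person_days,
    )


def build_followup(
    analysis: pd.DataFrame,
    participants: Mapping[str, Participant],
    horizon_days: int = 90,
    same_day_person_days: float = 0.5,
) -> pd.DataFrame:
    """Follow-up records for every analysis-set event, joined to its flags."""
    records = []
    for row in analysis.itertuples(index=False):
        part = participants[row.participant_id]
        ev = InfectionEvent(
            event_id=row.event_id,
            participant_id=row.participant_id,
            admission_date=row.admission_date,
            infection_primary=bool(row.infection_primary),
        )
        rec = follow_up(ev, part, horizon_days, same_day_person_days)
        records.append(
            {
                "event_id": rec.event_id,
                "participant_id": rec.participant_id,
                "start": rec.start,
                "end": rec.end,
                "died": rec.died_in_window,
                "stop_cause": rec.stop_cause,
                "person_days": rec.person_days,
                "person_years": rec.person_years,
            }
        )
    fu = pd.DataFrame(records)
    keep = ["event_id"] + [c for c in CLASSIFIER_FLAGS if c in analysis.columns]
    return fu.merge(analysis[keep], on="event_id", validate="one_to_one")


def rate_by_group(followup: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Deaths, person-years and rate per 100 person-years by group label.

    A group with zero person-years gets an absent (NaN) rate.
    """
    g = followup.groupby(group_col, dropna=False).agg(
        events=("event_id", "size"),
        deaths=("died", "sum"),
        person_years=("person_years", "sum"),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        g["rate_per_100py"] = np.where(
            g["person_years"] > 0, 100.0 * g["deaths"] / g["person_years"], np.nan
        )
    return g.reset_index()


_PAIR_CELLS = (
    ("index+/std+", True, True),
    ("index+/std-", True, False),
    ("index-/std+", False, True),
    ("index-/std-", False, False),
)


def mortality_report(
    followup: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = tuple(
        (i, s) for i in ("implicit_explicit", "cms") for s in ("sofa_sepsis", "qsofa_sepsis", "ehr_sepsis")
    ),
) -> pd.DataFrame:
    """Mortality rates overall, per classifier-positive group, and within the
    concordant/discordant cells of each pair."""
    rows = []

    def add(label_group: str, label: str, sub: pd.DataFrame) -> None:
        deaths = int(sub["died"].sum())
        py = float(sub["person_years"].sum())
        rows.append(
            {
                "group": label_group,
                "label": label,
                "events": len(sub),
                "deaths": deaths,
                "person_years": py,
                "rate_per_100py": 100.0 * deaths / py if py > 0 else np.nan,
            }
        )

    add("overall", "all_events", followup)
    for flag in CLASSIFIER_FLAGS:
        if flag in followup.columns:
            add("classifier_positive", flag, followup[followup[flag]])
    for index_col, standard_col in pairs:
        for cell_label, iv, sv in _PAIR_CELLS:
            sub = followup[(followup[index_col] == iv) & (followup[standard_col] == sv)]
            add(f"{index_col}_vs_{standard_col}", cell_label, sub)
    return pd.DataFrame(rows)


def survival_dataset(followup: pd.DataFrame, analysis: pd.DataFrame) -> pd.DataFrame:
    """Event-level survival table (time in days, status, flags, covariates)
    ready for any standard proportional-hazards fitter."""
    cols = ["event_id", "participant_id", "person_days", "died"]
    out = followup[cols].rename(columns={"person_days": "time_days", "died": "status"})
    flag_cols = [c for c in CLASSIFIER_FLAGS if c in analysis.columns]
    extra = [c for c in analysis.columns if c.startswith("cov_")]
    return out.merge(
        analysis[["event_id", "admission_date", "infection_primary"] + flag_cols + extra],
        on="event_id",
        validate="one_to_one",
    )
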