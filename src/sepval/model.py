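"""Core domain types shared by every pipeline stage.

All dates are calendar dates (``datetime.date``); every interval of dates is
closed ``[start, end]``, matching the day-level precision of administrative
claims.  Physiologic panel fields are individually optional: an absent value
means the measurement was not abstracted, and downstream classifiers treat
absence as normal.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "DateInterval",
    "Participant",
    "WorstValuePanel",
    "InfectionEvent",
    "Claim",
    "EpisodeOfCare",
    "AVPU_LEVELS",
    "STUDY_WINDOW",
]

AVPU_LEVELS = ("alert", "voice", "pain", "unresponsive")

#: Default study window for suspected-infection events.
STUDY_WINDOW = (dt.date(2003, 2, 5), dt.date(2012, 12, 31))


@dataclass(frozen=True, order=True)
class DateInterval:
    """Closed interval of calendar dates."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} precedes start {self.start}")

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day <= self.end

    @property
    def days(self) -> int:
        return (self.end - self.start).days + 1


_PANEL_NUMERIC = (
    "sbp_mmHg",
    "resp_rate_per_min",
    "gcs_total",
    "map_mmHg",
    "pao2_fio2_ratio",
    "platelets_10e3_per_uL",
    "bilirubin_mg_dL",
    "creatinine_mg_dL",
    "lactate_mmol_L",
)


@dataclass(frozen=True)
class WorstValuePanel:
    """Worst physiologic/laboratory values over the first 28 h of a
    hospitalization.

    Every field may be absent (``None``).  Numeric values, when present, must
    be strictly positive; the Glasgow coma score lies in [3, 15]; ``avpu`` is
    one of :data:`AVPU_LEVELS`.
    """

    sbp_mmHg: Optional[float] = None
    resp_rate_per_min: Optional[float] = None
    gcs_total: Optional[float] = None
    avpu: Optional[str] = None
    map_mmHg: Optional[float] = None
    pao2_fio2_ratio: Optional[float] = None
    platelets_10e3_per_uL: Optional[float] = None
    bilirubin_mg_dL: Optional[float] = None
    creatinine_mg_dL: Optional[float] = None
    lactate_mmol_L: Optional[float] = None
    vasopressor_use: Optional[bool] = None
    mechanical_ventilation: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in _PANEL_NUMERIC:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"panel field {name}={v!r} must be strictly positive")
        if self.gcs_total is not None and not (3 <= self.gcs_total <= 15):
            raise ValueError(f"gcs_total={self.gcs_total!r} outside [3, 15]")
        if self.avpu is not None and self.avpu not in AVPU_LEVELS:
            raise ValueError(f"unknown avpu token {self.avpu!r}")

    def replace(self, **kwargs) -> "WorstValuePanel":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class InfectionEvent:
    """One suspected-infection hospitalization reported by a participant.

    ``infection_primary`` records whether chart review confirmed infection as
    a primary reason for the hospitalization.
    """

    event_id: str
    participant_id: str
    admission_date: dt.date
    infection_primary: bool
    panel: WorstValuePanel = field(default_factory=WorstValuePanel)


@dataclass(frozen=True)
class Participant:
    """Enrollment, coverage and vital-status information for one person."""

    participant_id: str
    birth_date: Optional[dt.date] = None
    death_date: Optional[dt.date] = None
    coverage_ab: tuple[DateInterval, ...] = ()
    coverage_c: tuple[DateInterval, ...] = ()
    ltfu_date: Optional[dt.date] = None
    baseline_covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivs = sorted(self.coverage_ab)
        if tuple(ivs) != tuple(self.coverage_ab):
            object.__setattr__(self, "coverage_ab", tuple(ivs))
        for prev, nxt in zip(ivs, ivs[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"participant {self.participant_id}: overlapping A+B coverage intervals"
                )
        if self.birth_date is not None:
            for name in ("death_date", "ltfu_date"):
                d = getattr(self, name)
                if d is not None and d < self.birth_date:
                    raise ValueError(
                        f"participant {self.participant_id}: {name} precedes birth_date"
                    )

    def covered_ab(self, day: dt.date) -> bool:
        return any(day in iv for iv in self.coverage_ab)

    def part_c_start(self) -> Optional[dt.date]:
        """Earliest managed-care (Part C) enrollment date, if any."""
        return min((iv.start for iv in self.coverage_c), default=None)

    def ab_censor_date(self, day: dt.date) -> Optional[dt.date]:
        """End of the A+B coverage interval containing *day*, if finite.

        Returns the last covered day; follow-up beyond it is censored.
        """
        for iv in self.coverage_ab:
            if day in iv:
                return iv.end
        return None


CLAIM_TYPES = ("inpatient", "outpatient", "carrier")


@dataclass(frozen=True)
class Claim:
    """A single fee-for-service claim with its diagnosis codes."""

    claim_id: str
    participant_id: str
    claim_type: str
    from_date: dt.date
    thru_date: dt.date
    dx_codes: frozenset[str]

    def __post_init__(self) -> None:
        if self.claim_type not in CLAIM_TYPES:
            raise ValueError(f"claim {self.claim_id}: unknown claim_type {self.claim_type!r}")
        if self.thru_date < self.from_date:
            raise ValueError(
                f"claim {self.claim_id}: thru_date {self.thru_date} precedes from_date"
            )
        if not self.dx_codes:
            raise ValueError(f"claim {self.claim_id}: dx_codes is empty")


@dataclass(frozen=True)
class EpisodeOfCare:
    """A merged interval of claims treated as one care encounter."""

    episode_id: str
    participant_id: str
    start_date: dt.date
    end_date: dt.date
    dx_codes: frozenset[str]
    member_claim_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(f"episode {self.episode_id}: end precedes start")

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day <= self.end_date

    @property
    def length_days(self) -> int:
        return (self.end_date - self.start_date).days + 1
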