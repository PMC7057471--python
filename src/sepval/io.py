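"""Readers and writers for the delimited-text input tables.

Four plain CSV inputs drive the pipeline:

* ``events.csv`` — one row per suspected-infection event with the worst-value
  panel (absent cells stay absent, never zero-filled);
* ``claims.csv`` — one row per claim, diagnosis codes ``;``-separated;
* ``coverage.csv`` — long format: one row per coverage interval, with
  ``part`` either ``AB`` (Parts A and B jointly active) or ``C``;
* ``participants.csv`` — vital status (birth/death/loss-to-follow-up dates);
  any extra columns are carried as opaque baseline covariates.

Malformed rows raise :class:`RowError` carrying the 1-based line number.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .icd9 import canonicalize
from .model import (
    AVPU_LEVELS,
    Claim,
    DateInterval,
    InfectionEvent,
    Participant,
    WorstValuePanel,
)

__all__ = [
    "RowError",
    "read_events",
    "write_events",
    "read_claims",
    "write_claims",
    "read_participants",
    "write_participants",
    "write_coverage",
]


class RowError(ValueError):
    """A malformed input row, with file and 1-based line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _parse_date(text: str, path, line: int, what: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise RowError(path, line, f"malformed {what} date {text!r} (expected YYYY-MM-DD)")


def _parse_opt_date(text: str, path, line: int, what: str) -> Optional[dt.date]:
    text = text.strip()
    return _parse_date(text, path, line, what) if text else None


_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _parse_bool(text: str, path, line: int, what: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise RowError(path, line, f"malformed boolean {what}={text!r}")


def _parse_opt_bool(text: str, path, line: int, what: str) -> Optional[bool]:
    return _parse_bool(text, path, line, what) if text.strip() else None


def _parse_opt_float(text: str, path, line: int, what: str) -> Optional[float]:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise RowError(path, line, f"malformed numeric {what}={text!r}")


PANEL_COLUMNS = (
    "sbp_mmHg",
    "resp_rate_per_min",
    "gcs_total",
    "avpu",
    "map_mmHg",
    "pao2_fio2_ratio",
    "platelets_10e3_per_uL",
    "bilirubin_mg_dL",
    "creatinine_mg_dL",
    "lactate_mmol_L",
    "vasopressor_use",
    "mechanical_ventilation",
)

EVENT_COLUMNS = ("event_id", "participant_id", "admission_date", "infection_primary") + PANEL_COLUMNS


def _require_header(header: Sequence[str], required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise RowError(path, 1, f"missing required column(s): {', '.join(missing)}")


def read_events(path: str | Path) -> list[InfectionEvent]:
    """Read the events table; absent cells become absent panel fields."""
    events: list[InfectionEvent] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_header(reader.fieldnames or [], EVENT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            avpu = (row["avpu"] or "").strip().lower() or None
            if avpu is not None and avpu not in AVPU_LEVELS:
                raise RowError(path, lineno, f"unknown avpu token {row['avpu']!r}")
            try:
                panel = WorstValuePanel(
                    sbp_mmHg=_parse_opt_float(row["sbp_mmHg"], path, lineno, "sbp_mmHg"),
                    resp_rate_per_min=_parse_opt_float(
                        row["resp_rate_per_min"], path, lineno, "resp_rate_per_min"
                    ),
                    gcs_total=_parse_opt_float(row["gcs_total"], path, lineno, "gcs_total"),
                    avpu=avpu,
                    map_mmHg=_parse_opt_float(row["map_mmHg"], path, lineno, "map_mmHg"),
                    pao2_fio2_ratio=_parse_opt_float(
                        row["pao2_fio2_ratio"], path, lineno, "pao2_fio2_ratio"
                    ),
                    platelets_10e3_per_uL=_parse_opt_float(
                        row["platelets_10e3_per_uL"], path, lineno, "platelets_10e3_per_uL"
                    ),
                    bilirubin_mg_dL=_parse_opt_float(
                        row["bilirubin_mg_dL"], path, lineno, "bilirubin_mg_dL"
                    ),
                    creatinine_mg_dL=_parse_opt_float(
                        row["creatinine_mg_dL"], path, lineno, "creatinine_mg_dL"
                    ),
                    lactate_mmol_L=_parse_opt_float(
                        row["lactate_mmol_L"], path, lineno, "lactate_mmol_L"
                    ),
                    vasopressor_use=_parse_opt_bool(
                        row["vasopressor_use"], path, lineno, "vasopressor_use"
                    ),
                    mechanical_ventilation=_parse_opt_bool(
                        row["mechanical_ventilation"], path, lineno, "mechanical_ventilation"
                    ),
                )
            except RowError:
                raise
            except ValueError as exc:
                raise RowError(path, lineno, str(exc))
            events.append(
                InfectionEvent(
                    event_id=row["event_id"].strip(),
                    participant_id=row["participant_id"].strip(),
                    admission_date=_parse_date(row["admission_date"], path, lineno, "admission"),
                    infection_primary=_parse_bool(
                        row["infection_primary"], path, lineno, "infection_primary"
                    ),
                    panel=panel,
                )
            )
    return events


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_events(events: Iterable[InfectionEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            p = ev.panel
            writer.writerow(
                [
                    ev.event_id,
                    ev.participant_id,
                    ev.admission_date.isoformat(),
                    _fmt(ev.infection_primary),
                ]
                + [_fmt(getattr(p, col)) for col in PANEL_COLUMNS]
            )


CLAIM_COLUMNS = ("claim_id", "participant_id", "claim_type", "from_date", "thru_date", "dx_codes")


def read_claims(path: str | Path) -> list[Claim]:
    """Read the claims table; codes are canonicalized on load."""
    claims: list[Claim] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_header(reader.fieldnames or [], CLAIM_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            codes = frozenset(
                canonicalize(c) for c in row["dx_codes"].split(";") if c.strip()
            )
            try:
                claims.append(
                    Claim(
                        claim_id=row["claim_id"].strip(),
                        participant_id=row["participant_id"].strip(),
                        claim_type=row["claim_type"].strip().lower(),
                        from_date=_parse_date(row["from_date"], path, lineno, "from"),
                        thru_date=_parse_date(row["thru_date"], path, lineno, "thru"),
                        dx_codes=codes,
                    )
                )
            except RowError:
                raise
            except ValueError as exc:
                raise RowError(path, lineno, str(exc))
    return claims


def write_claims(claims: Iterable[Claim], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLAIM_COLUMNS)
        for c in claims:
            writer.writerow(
                [
                    c.claim_id,
                    c.participant_id,
                    c.claim_type,
                    c.from_date.isoformat(),
                    c.thru_date.isoformat(),
                    ";".join(sorted(c.dx_codes)),
                ]
            )


PARTICIPANT_COLUMNS = ("participant_id", "birth_date", "death_date", "ltfu_date")
COVERAGE_COLUMNS = ("participant_id", "part", "start_date", "end_date")


def read_participants(
    participants_path: str | Path, coverage_path: str | Path
) -> dict[str, Participant]:
    """Assemble participants from the vital-status and coverage tables.

    Columns beyond the documented vital-status header are carried as opaque
    baseline covariates.
    """
    coverage_ab: dict[str, list[DateInterval]] = {}
    coverage_c: dict[str, list[DateInterval]] = {}
    with open(coverage_path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_header(reader.fieldnames or [], COVERAGE_COLUMNS, coverage_path)
        for lineno, row in enumerate(reader, start=2):
            part = row["part"].strip().upper()
            if part not in ("AB", "C"):
                raise RowError(coverage_path, lineno, f"unknown coverage part {row['part']!r}")
            iv = DateInterval(
                _parse_date(row["start_date"], coverage_path, lineno, "start"),
                _parse_date(row["end_date"], coverage_path, lineno, "end"),
            )
            target = coverage_ab if part == "AB" else coverage_c
            target.setdefault(row["participant_id"].strip(), []).append(iv)

    participants: dict[str, Participant] = {}
    with open(participants_path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_header(reader.fieldnames or [], PARTICIPANT_COLUMNS, participants_path)
        extra_cols = [c for c in (reader.fieldnames or []) if c not in PARTICIPANT_COLUMNS]
        for lineno, row in enumerate(reader, start=2):
            pid = row["participant_id"].strip()
            try:
                participants[pid] = Participant(
                    participant_id=pid,
                    birth_date=_parse_opt_date(row["birth_date"], participants_path, lineno, "birth"),
                    death_date=_parse_opt_date(row["death_date"], participants_path, lineno, "death"),
                    ltfu_date=_parse_opt_date(row["ltfu_date"], participants_path, lineno, "ltfu"),
                    coverage_ab=tuple(sorted(coverage_ab.get(pid, []))),
                    coverage_c=tuple(sorted(coverage_c.get(pid, []))),
                    baseline_covariates={c: row[c] for c in extra_cols},
                )
            except RowError:
                raise
            except ValueError as exc:
                raise RowError(participants_path, lineno, str(exc))
    return participants


def write_participants(participants: Iterable[Participant], path: str | Path) -> None:
    participants = list(participants)
    extra = sorted({k for p in participants for k in p.baseline_covariates})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(PARTICIPANT_COLUMNS) + extra)
        for p in participants:
            writer.writerow(
                [
                    p.participant_id,
                    p.birth_date.isoformat() if p.birth_date else "",
                    p.death_date.isoformat() if p.death_date else "",
                    p.ltfu_date.isoformat() if p.ltfu_date else "",
                ]
                + [_fmt(p.baseline_covariates.get(k)) for k in extra]
            )


def write_coverage(participants: Iterable[Participant], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COVERAGE_COLUMNS)
        for p in participants:
            for part, ivs in (("AB", p.coverage_ab), ("C", p.coverage_c)):
                for iv in ivs:
                    writer.writerow(
                        [p.participant_id, part, iv.start.isoformat(), iv.end.isoformat()]
                    )
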