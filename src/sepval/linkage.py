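"""Event-episode linkage, coverage exclusions, and the analysis dataset.

A cohort-detected suspected-infection event and a claims episode of care are
considered the same event when the cohort admission date falls between the
episode start and end dates, inclusive.  Events are excluded from analysis
when they fall outside the study window, when the participant lacked
Medicare Parts A+B coverage on the admission date, or when they occur on or
after the participant initiated Part C (managed care) — such events are not
expected to appear in fee-for-service claims.

The result is the analysis dataset: one row per retained event carrying all
five classifier flags (three clinical, two claims-based), the matched
episode, and the primary-infection-in-claims subgroup flag.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .clinical import classify_events
from .episodes import build_episodes, classify_episodes
from .icd9 import CodeTaxonomy
from .model import Claim, EpisodeOfCare, InfectionEvent, Participant, STUDY_WINDOW

__all__ = [
    "LinkageDiagnostics",
    "link_events",
    "build_analysis_set",
    "primary_infection_subgroup",
    "CLASSIFIER_FLAGS",
]

#: Canonical order of the five classifier flag columns.
CLASSIFIER_FLAGS = ("sofa_sepsis", "qsofa_sepsis", "ehr_sepsis", "implicit_explicit", "cms")

EXCLUSION_REASONS = ("none", "lost_AB", "gained_C", "outside_window")


@dataclass
class LinkageDiagnostics:
    n_events: int = 0
    n_excluded: dict = field(default_factory=dict)
    n_matched: int = 0
    n_multi_match: int = 0


def _match_episode(
    admission: dt.date, episodes: Sequence[EpisodeOfCare]
) -> tuple[EpisodeOfCare | None, int]:
    hits = [e for e in episodes if e.contains(admission)]
    if not hits:
        return None, 0
    # deterministic tie-break: earliest start, then longest episode, then id
    hits.sort(key=lambda e: (e.start_date, -e.length_days, e.episode_id))
    return hits[0], len(hits)


def link_events(
    events: Sequence[InfectionEvent],
    episodes: Sequence[EpisodeOfCare],
    participants: Mapping[str, Participant],
    window: tuple[dt.date, dt.date] = STUDY_WINDOW,
) -> tuple[pd.DataFrame, LinkageDiagnostics]:
    """Match events to episodes and apply coverage exclusions.

    Returns one row per input event with ``exclusion_reason`` (``none`` for
    retained rows), the matched ``episode_id`` (or empty), and the number of
    candidate episodes.  Raises on an event whose participant is unknown.
    """
    eps_by_pid: dict[str, list[EpisodeOfCare]] = {}
    for e in episodes:
        eps_by_pid.setdefault(e.participant_id, []).append(e)

    diag = LinkageDiagnostics(n_events=len(events), n_excluded={r: 0 for r in EXCLUSION_REASONS[1:]})
    rows = []
    for ev in events:
        part = participants.get(ev.participant_id)
        if part is None:
            raise KeyError(f"event {ev.event_id}: unknown participant {ev.participant_id!r}")

        reason = "none"
        if not (window[0] <= ev.admission_date <= window[1]):
            reason = "outside_window"
        else:
            c_start = part.part_c_start()
            if c_start is not None and ev.admission_date >= c_start:
                reason = "gained_C"
            elif not part.covered_ab(ev.admission_date):
                reason = "lost_AB"
        if reason != "none":
            diag.n_excluded[reason] += 1

        episode, n_hits = (None, 0)
        if reason == "none":
            episode, n_hits = _match_episode(ev.admission_date, eps_by_pid.get(ev.participant_id, []))
            if episode is not None:
                diag.n_matched += 1
            if n_hits > 1:
                diag.n_multi_match += 1

        rows.append(
            {
                "event_id": ev.event_id,
                "participant_id": ev.participant_id,
                "admission_date": ev.admission_date,
                "infection_primary": ev.infection_primary,
                "exclusion_reason": reason,
                "matched": episode is not None,
                "episode_id": episode.episode_id if episode else "",
                "n_candidate_episodes": n_hits,
            }
        )
    columns = [
        "event_id", "participant_id", "admission_date", "infection_primary",
        "exclusion_reason", "matched", "episode_id", "n_candidate_episodes",
    ]
    return pd.DataFrame(rows, columns=columns), diag


def build_analysis_set(
    events: Sequence[InfectionEvent],
    claims: Sequence[Claim],
    participants: Mapping[str, Participant],
    taxonomy: CodeTaxonomy,
    window: tuple[dt.date, dt.date] = STUDY_WINDOW,
    sofa_table: Mapping | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, LinkageDiagnostics]:
    """Run classification, episode building and linkage end to end.

    Returns ``(analysis, excluded, diagnostics)``.  ``analysis`` has one row
    per retained suspected-infection event with the five classifier flags;
    claims flags are False for unmatched events.
    """
    clinical = classify_events(events, sofa_table)
    episodes = build_episodes(claims)
    episode_class = classify_episodes(episodes, taxonomy)
    linked, diag = link_events(events, episodes, participants, window)

    df = linked.merge(
        clinical.drop(columns=["participant_id", "admission_date", "infection_primary"]),
        on="event_id",
        how="left",
        validate="one_to_one",
    )
    df = df.merge(
        episode_class[["episode_id", "implicit_explicit", "cms", "basis"]],
        on="episode_id",
        how="left",
    )
    for col in ("implicit_explicit", "cms"):
        df[col] = df[col].astype("boolean").fillna(False).astype(bool)
    df["basis"] = df["basis"].fillna("")
    df["in_claims_primary_subgroup"] = df["matched"] & df["infection_primary"]

    excluded = df[df["exclusion_reason"] != "none"].reset_index(drop=True)
    analysis = df[df["exclusion_reason"] == "none"].reset_index(drop=True)
    return analysis, excluded, diag


def primary_infection_subgroup(analysis: pd.DataFrame) -> pd.DataFrame:
    """Events with a matched claims episode and chart-confirmed primary
    infection — the sensitivity-analysis subset."""
    return analysis[analysis["in_claims_primary_subgroup"]].reset_index(drop=True)
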