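"""Episode-of-care assembly and claims-based sepsis classification.

Inpatient claims belonging to one continuous stay are chained into a single
episode: two inpatient claims merge when the discharge (thru) date of one
falls on, after, or the day before the admission (from) date of the next —
i.e. overlapping or back-to-back stays are one encounter.  Outpatient and
carrier claims attach to an inpatient episode whose interval contains their
from-date; otherwise each forms a singleton episode.

Each episode is then classified two ways against the loaded code taxonomy:

* **implicit/explicit** — diagnosis codes for both infection and acute organ
  dysfunction (the implicit route), or an explicit severe-sepsis/septic-shock
  code;
* **CMS** — any code on the severe sepsis / septic shock measure list.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .icd9 import CodeTaxonomy
from .model import Claim, EpisodeOfCare

__all__ = ["build_episodes", "classify_episode", "classify_episodes", "EpisodeClassification"]

_ONE_DAY = dt.timedelta(days=1)


def _sort_key(claim: Claim):
    return (claim.from_date, claim.thru_date, claim.claim_type, claim.claim_id)


def build_episodes(claims: Iterable[Claim]) -> list[EpisodeOfCare]:
    """Assemble episodes of care from raw claims.

    Deterministic under any input ordering: claims are grouped by participant
    and sorted internally.  Episode ids are ``<participant>-E<k>`` numbered by
    episode start date.
    """
    by_pid: dict[str, list[Claim]] = {}
    for c in claims:
        by_pid.setdefault(c.participant_id, []).append(c)

    episodes: list[EpisodeOfCare] = []
    for pid in sorted(by_pid):
        inpatient = sorted((c for c in by_pid[pid] if c.claim_type == "inpatient"), key=_sort_key)
        other = sorted((c for c in by_pid[pid] if c.claim_type != "inpatient"), key=_sort_key)

        # chain-merge inpatient claims: overlap or gap of <= 1 day joins
        merged: list[list[Claim]] = []
        for c in inpatient:
            if merged and c.from_date <= merged[-1][-1].thru_date + _ONE_DAY:
                group = merged[-1]
                group.append(c)
                # keep the running max thru_date last for the chain test
                if c.thru_date < group[-2].thru_date:
                    group[-1], group[-2] = group[-2], group[-1]
            else:
                merged.append([c])

        spans = [
            (min(c.from_date for c in g), max(c.thru_date for c in g), g) for g in merged
        ]

        # attach outpatient/carrier claims to a containing inpatient episode
        leftovers: list[Claim] = []
        for c in other:
            host = next((s for s in spans if s[0] <= c.from_date <= s[1]), None)
            if host is not None:
                host[2].append(c)
            else:
                leftovers.append(c)

        raw = [(start, end, g) for start, end, g in spans]
        raw.extend((c.from_date, c.thru_date, [c]) for c in leftovers)
        raw.sort(key=lambda t: (t[0], t[1], t[2][0].claim_id))
        for k, (start, end, group) in enumerate(raw, start=1):
            codes = frozenset().union(*(c.dx_codes for c in group))
            episodes.append(
                EpisodeOfCare(
                    episode_id=f"{pid}-E{k}",
                    participant_id=pid,
                    start_date=start,
                    end_date=end,
                    dx_codes=codes,
                    member_claim_ids=tuple(sorted(c.claim_id for c in group)),
                )
            )
    return episodes


@dataclass(frozen=True)
class EpisodeClassification:
    episode_id: str
    participant_id: str
    implicit_explicit: bool
    cms: bool
    basis: str  # "explicit" | "implicit" | "cms" | ""


def classify_episode(episode: EpisodeOfCare, taxonomy: CodeTaxonomy) -> EpisodeClassification:
    """Classify one episode under the implicit/explicit and CMS algorithms."""
    codes = episode.dx_codes
    has_explicit = taxonomy.explicit_sepsis.matches_any(codes)
    has_implicit = taxonomy.infection.matches_any(codes) and taxonomy.organ_dysfunction.matches_any(
        codes
    )
    has_cms = taxonomy.cms.matches_any(codes)
    if has_explicit:
        basis = "explicit"
    elif has_implicit:
        basis = "implicit"
    elif has_cms:
        basis = "cms"
    else:
        basis = ""
    return EpisodeClassification(
        episode_id=episode.episode_id,
        participant_id=episode.participant_id,
        implicit_explicit=has_explicit or has_implicit,
        cms=has_cms,
        basis=basis,
    )


def classify_episodes(
    episodes: Sequence[EpisodeOfCare], taxonomy: CodeTaxonomy
) -> pd.DataFrame:
    rows = [
        {
            "episode_id": e.episode_id,
            "participant_id": e.participant_id,
            "start_date": e.start_date,
            "end_date": e.end_date,
            "n_claims": len(e.member_claim_ids),
            "dx_codes": ";".join(sorted(e.dx_codes)),
            "implicit_explicit": c.implicit_explicit,
            "cms": c.cms,
            "basis": c.basis,
        }
        for e, c in ((e, classify_episode(e, taxonomy)) for e in episodes)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "episode_id", "participant_id", "start_date", "end_date", "n_claims",
            "dx_codes", "implicit_explicit", "cms", "basis",
        ],
    )
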