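import datetime as dt

import pytest

from sepval.icd9 import CodeTaxonomy
from sepval.model import Claim, DateInterval, InfectionEvent, Participant, WorstValuePanel


@pytest.fixture(scope="session")
def taxonomy() -> CodeTaxonomy:
    return CodeTaxonomy.from_dict(
        {
            "infection_codes": ["038*", "486", "5990"],
            "organ_dysfunction_codes": ["584*", "51881", "2866"],
            "explicit_sepsis_codes": ["99592", "78552"],
            "cms_codes": ["99591", "99592", "78552"],
        }
    )


def make_claim(
    claim_id="C1",
    pid="P1",
    claim_type="inpatient",
    from_date=dt.date(2005, 1, 1),
    thru_date=dt.date(2005, 1, 5),
    codes=("486",),
):
    return Claim(claim_id, pid, claim_type, from_date, thru_date, frozenset(codes))


def make_event(
    event_id="E1",
    pid="P1",
    admission=dt.date(2005, 1, 3),
    primary=True,
    **panel_fields,
):
    return InfectionEvent(
        event_id=event_id,
        participant_id=pid,
        admission_date=admission,
        infection_primary=primary,
        panel=WorstValuePanel(**panel_fields),
    )


def make_participant(
    pid="P1",
    coverage=(dt.date(2002, 1, 1), dt.date(2013, 12, 31)),
    part_c_start=None,
    death=None,
    ltfu=None,
):
    coverage_c = ()
    if part_c_start is not None:
        coverage_c = (DateInterval(part_c_start, dt.date(2013, 12, 31)),)
    return Participant(
        participant_id=pid,
        birth_date=dt.date(1935, 6, 1),
        death_date=death,
        coverage_ab=(DateInterval(*coverage),),
        coverage_c=coverage_c,
        ltfu_date=ltfu,
    )
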