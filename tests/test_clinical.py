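import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from sepval.clinical import (
    DEFAULT_SOFA_TABLE,
    SofaTableError,
    classify_events,
    ehr_classify,
    qsofa_classify,
    sofa_score,
)
from sepval.model import WorstValuePanel

from conftest import make_event


class TestSofa:
    def test_all_absent_panel_scores_zero(self):
        b = sofa_score(WorstValuePanel())
        assert b.total == 0

    def test_thrombocytopenia_plus_bilirubin(self):
        # platelets 90 -> 2 hematological, bilirubin 2.5 -> 2 hepatic
        b = sofa_score(WorstValuePanel(platelets_10e3_per_uL=90, bilirubin_mg_dL=2.5))
        assert (b.hematological, b.hepatic, b.total) == (2, 2, 4)

    def test_mild_renal_only_is_below_threshold(self):
        b = sofa_score(WorstValuePanel(creatinine_mg_dL=1.5))
        assert (b.renal, b.total) == (1, 1)

    @pytest.mark.parametrize(
        "field, value, system, points",
        [
            ("pao2_fio2_ratio", 399, "respiratory", 1),
            ("pao2_fio2_ratio", 99, "respiratory", 4),
            ("platelets_10e3_per_uL", 150, "hematological", 0),
            ("platelets_10e3_per_uL", 19, "hematological", 4),
            ("bilirubin_mg_dL", 1.2, "hepatic", 1),
            ("bilirubin_mg_dL", 12.0, "hepatic", 4),
            ("gcs_total", 14, "neurological", 1),
            ("gcs_total", 10, "neurological", 2),
            ("gcs_total", 6, "neurological", 3),
            ("gcs_total", 5, "neurological", 4),
            ("creatinine_mg_dL", 1.19, "renal", 0),
            ("creatinine_mg_dL", 5.0, "renal", 4),
            ("map_mmHg", 69, "cardiovascular", 1),
            ("vasopressor_use", True, "cardiovascular", 2),
        ],
    )
    def test_component_cutpoints(self, field, value, system, points):
        b = sofa_score(WorstValuePanel(**{field: value}))
        assert getattr(b, system) == points

    def test_vent_requirement_caps_respiratory(self):
        table = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_SOFA_TABLE.items()}
        table["options"] = {"respiratory_support_required": True}
        panel = WorstValuePanel(pao2_fio2_ratio=80)
        assert sofa_score(panel, table).respiratory == 2
        vent = WorstValuePanel(pao2_fio2_ratio=80, mechanical_ventilation=True)
        assert sofa_score(vent, table).respiratory == 4

    def test_non_monotone_table_rejected(self):
        table = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_SOFA_TABLE.items()}
        table["renal"] = {"variable": "creatinine_mg_dL", "direction": "at_or_above",
                         "cutpoints": [1.2, 1.0, 3.5, 5.0]}
        with pytest.raises(SofaTableError, match="renal"):
            sofa_score(WorstValuePanel(), table)


class TestQsofa:
    def test_boundary_values_count(self):
        count, septic = qsofa_classify(WorstValuePanel(sbp_mmHg=100, resp_rate_per_min=22))
        assert (count, septic) == (2, True)

    def test_just_above_boundaries_do_not(self):
        count, septic = qsofa_classify(
            WorstValuePanel(sbp_mmHg=101, resp_rate_per_min=21, gcs_total=15, avpu="alert")
        )
        assert (count, septic) == (0, False)

    def test_avpu_alone_gives_altered_mentation(self):
        # normal GCS but non-alert AVPU satisfies the mentation criterion
        count, septic = qsofa_classify(
            WorstValuePanel(gcs_total=15, avpu="pain", resp_rate_per_min=30)
        )
        assert (count, septic) == (2, True)

    def test_gcs_14_is_altered(self):
        count, _ = qsofa_classify(WorstValuePanel(gcs_total=14))
        assert count == 1


class TestEhr:
    @pytest.mark.parametrize(
        "kwargs, expected_triggers",
        [
            ({"lactate_mmol_L": 2.0}, {"lactate"}),
            ({"platelets_10e3_per_uL": 100}, set()),  # strict < 100
            ({"platelets_10e3_per_uL": 99.9}, {"platelets"}),
            ({"vasopressor_use": True}, {"vasopressor"}),
            ({"mechanical_ventilation": True}, {"mechanical_ventilation"}),
            ({"creatinine_mg_dL": 2.0, "bilirubin_mg_dL": 2.0}, {"creatinine", "bilirubin"}),
            ({}, set()),
        ],
    )
    def test_triggers(self, kwargs, expected_triggers):
        triggers, septic = ehr_classify(WorstValuePanel(**kwargs))
        assert set(triggers) == expected_triggers
        assert septic is bool(expected_triggers)


class TestClassifyEvents:
    def test_non_primary_events_are_never_sepsis(self):
        ev = make_event(primary=False, lactate_mmol_L=9.0, sbp_mmHg=70, resp_rate_per_min=40,
                        creatinine_mg_dL=5.0)
        row = classify_events([ev]).iloc[0]
        assert not row.sofa_sepsis and not row.qsofa_sepsis and not row.ehr_sepsis
        assert row.sofa_total >= 2  # scores still recorded

    def test_empty_event_list(self):
        df = classify_events([])
        assert df.empty and "sofa_sepsis" in df.columns

    def test_duplicate_event_keys_rejected(self):
        ev = make_event()
        with pytest.raises(ValueError, match="duplicate"):
            classify_events([ev, ev])

    def test_ten_event_fixture_matches_hand_scoring(self):
        # hand-computed truth for a mixed panel fixture
        events = [
            make_event("F01", lactate_mmol_L=2.5),                       # EHR only
            make_event("F02", platelets_10e3_per_uL=90, bilirubin_mg_dL=2.5),  # SOFA 4, EHR
            make_event("F03", sbp_mmHg=95, resp_rate_per_min=25),        # qSOFA 2
            make_event("F04", creatinine_mg_dL=1.5),                     # SOFA 1 only
            make_event("F05"),                                           # nothing
            make_event("F06", vasopressor_use=True),                     # CV 2 -> SOFA, EHR
            make_event("F07", gcs_total=12, map_mmHg=65),                # CNS 2 + CV 1 -> SOFA
            make_event("F08", primary=False, lactate_mmol_L=8.0),        # gated off
            make_event("F09", avpu="voice", sbp_mmHg=100),               # qSOFA 2
            make_event("F10", pao2_fio2_ratio=250, creatinine_mg_dL=2.1),  # SOFA 2+2, EHR
        ]
        df = classify_events(events).set_index("event_id")
        expected = {
            "F01": (False, False, True),
            "F02": (True, False, True),
            "F03": (False, True, False),
            "F04": (False, False, False),
            "F05": (False, False, False),
            "F06": (True, False, True),
            "F07": (True, False, False),
            "F08": (False, False, False),
            "F09": (False, True, False),
            "F10": (True, False, True),
        }
        for eid, (sofa, qsofa, ehr) in expected.items():
            row = df.loc[eid]
            assert (row.sofa_sepsis, row.qsofa_sepsis, row.ehr_sepsis) == (sofa, qsofa, ehr), eid


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

panel_strategy = st.builds(
    WorstValuePanel,
    sbp_mmHg=st.one_of(st.none(), st.floats(40, 220)),
    resp_rate_per_min=st.one_of(st.none(), st.floats(5, 60)),
    gcs_total=st.one_of(st.none(), st.integers(3, 15).map(float)),
    avpu=st.one_of(st.none(), st.sampled_from(["alert", "voice", "pain", "unresponsive"])),
    map_mmHg=st.one_of(st.none(), st.floats(30, 150)),
    pao2_fio2_ratio=st.one_of(st.none(), st.floats(40, 600)),
    platelets_10e3_per_uL=st.one_of(st.none(), st.floats(5, 600)),
    bilirubin_mg_dL=st.one_of(st.none(), st.floats(0.1, 30)),
    creatinine_mg_dL=st.one_of(st.none(), st.floats(0.2, 12)),
    lactate_mmol_L=st.one_of(st.none(), st.floats(0.2, 20)),
    vasopressor_use=st.one_of(st.none(), st.booleans()),
    mechanical_ventilation=st.one_of(st.none(), st.booleans()),
)

# worse value per field (toward the abnormal direction)
_WORSEN = {
    "sbp_mmHg": lambda v: max(40.0, v - 20),
    "resp_rate_per_min": lambda v: v + 8,
    "gcs_total": lambda v: max(3.0, v - 3),
    "avpu": lambda v: "unresponsive",
    "map_mmHg": lambda v: max(30.0, v - 15),
    "pao2_fio2_ratio": lambda v: max(40.0, v - 120),
    "platelets_10e3_per_uL": lambda v: max(5.0, v - 60),
    "bilirubin_mg_dL": lambda v: v + 3,
    "creatinine_mg_dL": lambda v: v + 1.5,
    "lactate_mmol_L": lambda v: v + 2,
    "vasopressor_use": lambda v: True,
    "mechanical_ventilation": lambda v: True,
}


def _scores(panel):
    triggers, _ = ehr_classify(panel)
    return sofa_score(panel).total, qsofa_classify(panel)[0], len(triggers)


@settings(max_examples=200, derandomize=True)
@given(panel=panel_strategy, field=st.sampled_from(sorted(_WORSEN)))
def test_worsening_any_field_never_lowers_scores(panel, field):
    """Monotonicity: moving one value toward the abnormal direction cannot
    decrease the SOFA total, qSOFA count, or EHR trigger count."""
    value = getattr(panel, field)
    if value is None:
        return
    worse = panel.replace(**{field: _WORSEN[field](value)})
    assert all(w >= b for w, b in zip(_scores(worse), _scores(panel)))


@settings(max_examples=200, derandomize=True)
@given(panel=panel_strategy, field=st.sampled_from(sorted(_WORSEN)))
def test_deleting_a_field_never_flips_negative_to_positive(panel, field):
    """Missing-is-normal: removing any measurement can only lower scores."""
    if getattr(panel, field) is None:
        return
    reduced = panel.replace(**{field: None})
    assert all(r <= f for r, f in zip(_scores(reduced), _scores(panel)))
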