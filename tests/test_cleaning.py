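"""Deduplication rule, drug-name normalization, unit conversion, assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from faersignal.cleaning import (DrugDictionary, age_in_years, assemble_reports,
                                 deduplicate, normalize_drug, weight_in_kg)
from faersignal.io import (DrugRecord, PtSocMap, QuarterData, ReacRecord,
                           TherRecord)
from faersignal.dates import PartialDate

from conftest import make_demo


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def test_latest_fda_dt_wins():
    demos = [make_demo("10", "X", fda="20200101"),
             make_demo("7", "X", fda="20200301")]
    kept = deduplicate(demos)
    assert [d.primaryid for d in kept] == ["7"]


def test_fda_dt_tie_broken_by_highest_numeric_primaryid():
    demos = [make_demo("111", "X", fda="20200301"),
             make_demo("222", "X", fda="20200301")]
    assert deduplicate(demos)[0].primaryid == "222"


def test_unique_caseids_pass_through_sorted():
    demos = [make_demo("2", "B"), make_demo("1", "A")]
    kept = deduplicate(demos)
    assert [d.caseid for d in kept] == ["A", "B"]
    assert deduplicate(kept) == kept          # idempotent


def test_non_numeric_primaryid_tie_is_error():
    demos = [make_demo("abc", "X", fda="20200301"),
             make_demo("xyz", "X", fda="20200301")]
    with pytest.raises(ValueError, match="non-numeric"):
        deduplicate(demos)


def test_partial_fda_dt_ordering_pads_with_01():
    # month-precision 202003 sorts before 20200302, after 20200201
    demos = [make_demo("1", "X", fda="202003"),
             make_demo("2", "X", fda="20200302")]
    assert deduplicate(demos)[0].primaryid == "2"


@settings(max_examples=60, deadline=None)
@given(st.permutations(range(8)), st.data())
def test_dedup_is_order_independent(perm, data):
    """Any permutation of the input yields the identical output set."""
    base = [make_demo(str(100 + i), f"C{i % 3}",
                      fda=f"2020{data.draw(st.integers(1, 12)):02d}01")
            for i in range(8)]
    shuffled = [base[i] for i in perm]
    assert deduplicate(shuffled) == deduplicate(base)


# ---------------------------------------------------------------------------
# Drug-name normalization
# ---------------------------------------------------------------------------

@pytest.fixture()
def tolvaptan_dict():
    return DrugDictionary({"SAMSCA": "tolvaptan", "tolvaptan": "tolvaptan"})


@pytest.mark.parametrize("raw", ["SAMSCA", "Samsca", " samsca "])
def test_synonym_lookup_hits(raw, tolvaptan_dict):
    assert normalize_drug(raw, tolvaptan_dict) == "tolvaptan"


@pytest.mark.parametrize("raw", ["  Tolvaptan  ", "tolvaptan.", "TOLVAPTAN 15MG",
                                 "Tolvaptan 15 mg tablets"])
def test_punctuation_and_dose_tokens_ignored(raw, tolvaptan_dict):
    assert normalize_drug(raw, tolvaptan_dict) == "tolvaptan"


def test_unmapped_names_flagged_never_silently_kept(tolvaptan_dict):
    assert normalize_drug("drugXYZ", tolvaptan_dict) == "unmapped:drugxyz"


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("value, unit, years", [
    (6.5, "decade", 65.0), (72, "year", 72.0), (18, "month", 1.5),
    (52.18, "week", 1.0), (365.25, "day", 1.0),
])
def test_age_unit_conversion(value, unit, years):
    assert age_in_years(value, unit) == pytest.approx(years)


def test_age_unknown_unit_or_missing_value_is_none():
    assert age_in_years(50, "unknown") is None
    assert age_in_years(None, "year") is None


def test_weight_conversion():
    assert weight_in_kg(70, "kg") == 70
    assert weight_in_kg(154.324, "lbs") == pytest.approx(70.0, abs=0.01)
    assert weight_in_kg(70, "unknown") is None


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _quarter():
    data = QuarterData()
    data.demo = [make_demo("1", "A"), make_demo("2", "B")]
    data.drug = [
        DrugRecord("1", 1, "SAMSCA", "PS"),
        DrugRecord("2", 1, "tolvaptan", "C"),     # concomitant only
        DrugRecord("99", 1, "aspirin", "PS"),     # orphan
    ]
    data.reac = [ReacRecord("1", "Thirst"), ReacRecord("1", "thirst"),
                 ReacRecord("1", "polyuria"), ReacRecord("2", "nausea"),
                 ReacRecord("99", "rash")]
    data.ther = [TherRecord("1", 1, PartialDate.parse("20200101"))]
    return data


@pytest.fixture()
def assembled():
    pt_map = PtSocMap({"thirst": "general disorders", "polyuria": "renal"})
    d = DrugDictionary({"SAMSCA": "tolvaptan", "tolvaptan": "tolvaptan",
                        "aspirin": "aspirin"})
    return assemble_reports(_quarter(), pt_map, d)


def test_within_report_duplicate_pts_collapse(assembled):
    reports, _ = assembled
    assert reports[0].pt_names() == ["thirst", "polyuria"]


def test_orphan_rows_dropped_and_counted(assembled):
    _, log = assembled
    assert log.orphan_drug_rows == 1
    assert log.orphan_reac_rows == 1


def test_output_count_equals_deduplicated_demos(assembled):
    reports, _ = assembled
    assert len(reports) == 2


def test_unmapped_pt_gets_unmapped_soc_and_is_counted(assembled):
    reports, log = assembled
    case_b = next(r for r in reports if r.caseid == "B")
    assert case_b.pts == [("nausea", "unmapped")]
    assert log.unmapped_pts == {"nausea": 1}


def test_concomitant_role_does_not_make_case_primary_suspect(assembled):
    reports, _ = assembled
    case_b = next(r for r in reports if r.caseid == "B")
    assert case_b.has_drug("tolvaptan")
    assert not case_b.is_primary_suspect("tolvaptan")
    case_a = next(r for r in reports if r.caseid == "A")
    assert case_a.is_primary_suspect("tolvaptan")


def test_therapy_start_attached_by_drug_seq(assembled):
    reports, _ = assembled
    case_a = next(r for r in reports if r.caseid == "A")
    assert case_a.therapy_starts[1] == PartialDate.parse("20200101")
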