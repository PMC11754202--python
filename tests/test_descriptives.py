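"""Demographic summaries, onset bins, outcome/concomitant rankings, subgroups."""

import pytest

from faersignal.contingency import build_all_tables
from faersignal.dates import PartialDate
from faersignal.descriptives import (age_bin, concomitant_frequency, onset_bin,
                                     onset_days, subgroup_signals, summarize,
                                     top_events_by_outcome, weight_bin)

from conftest import make_case


# ---------------------------------------------------------------------------
# Bins
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("age, bin_", [
    (17.9, "<18"), (18.0, "18-45"), (44.9, "18-45"), (45.0, "45-65"),
    (65.0, "65-75"), (75.0, ">=75"), (None, "unknown"),
])
def test_fine_age_bins_are_half_open(age, bin_):
    assert age_bin(age) == bin_


@pytest.mark.parametrize("age, bin_", [(17, "<18"), (18, "18-65"),
                                       (64.9, "18-65"), (65, ">=65")])
def test_coarse_age_bins(age, bin_):
    assert age_bin(age, coarse=True) == bin_


@pytest.mark.parametrize("days, bin_", [
    (0, "<7"), (6, "<7"), (7, "7-28"), (27, "7-28"), (28, "28-60"),
    (59, "28-60"), (60, ">=60"), (400, ">=60"), (None, "unknown"),
])
def test_onset_bins(days, bin_):
    assert onset_bin(days) == bin_


def test_weight_bins():
    assert weight_bin(39.9) == "<40"
    assert weight_bin(100) == ">=100"
    assert weight_bin(None) == "unknown"


# ---------------------------------------------------------------------------
# Onset days
# ---------------------------------------------------------------------------

def _case_with_onset(start, event):
    return make_case("1", [("tolvaptan", "PS")], [("thirst", "gen")],
                     demo_kw={"event_dt": PartialDate.parse(event)} if event else {},
                     therapy_starts={1: PartialDate.parse(start)} if start else {})


def test_onset_simple_difference():
    case = _case_with_onset("20230101", "20230105")
    assert onset_days(case, "tolvaptan") == 4
    assert onset_bin(4) == "<7"


def test_onset_month_precision_start_is_unknown():
    assert onset_days(_case_with_onset("202301", "20230115"), "tolvaptan") is None


def test_onset_event_before_start_is_unknown():
    assert onset_days(_case_with_onset("20230110", "20230105"), "tolvaptan") is None


def test_onset_missing_either_date_is_unknown():
    assert onset_days(_case_with_onset(None, "20230105"), "tolvaptan") is None
    assert onset_days(_case_with_onset("20230101", None), "tolvaptan") is None


def test_onset_uses_earliest_ps_start_of_the_target_drug():
    case = make_case("1", [("tolvaptan", "PS"), ("tolvaptan", "PS")],
                     [("thirst", "gen")],
                     demo_kw={"event_dt": PartialDate.parse("20230110")},
                     therapy_starts={1: PartialDate.parse("20230108"),
                                     2: PartialDate.parse("20230101")})
    assert onset_days(case, "tolvaptan") == 9


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def _summary_corpus():
    return [
        make_case("1", [("tolvaptan", "PS")], [("thirst", "gen")],
                  outcomes={"death", "hospitalization"},
                  demo_kw={"sex": "female"}),
        make_case("2", [("tolvaptan", "PS")], [("thirst", "gen")],
                  demo_kw={"sex": "female"}),
        make_case("3", [("tolvaptan", "PS")], [("nausea", "gi")],
                  demo_kw={"sex": "male"}),
        make_case("4", [("tolvaptan", "PS")], [("rash", "skin")]),
        make_case("5", [("aspirin", "PS")], [("rash", "skin")],
                  demo_kw={"sex": "male"}),       # not a PS case of the drug
    ]


def test_summary_sex_counts_and_percentages():
    df = summarize(_summary_corpus(), "tolvaptan")
    sex = df[df.section == "sex"].set_index("category")
    assert sex.loc["female", "count"] == 2
    assert sex.loc["female", "pct"] == 50.0
    assert sex.loc["male", "count"] == 1
    assert sex.loc["unknown", "count"] == 1


def test_multi_outcome_case_counts_once_per_outcome():
    df = summarize(_summary_corpus(), "tolvaptan")
    out = df[df.section == "outcome"].set_index("category")
    assert out.loc["death", "count"] == 1
    assert out.loc["hospitalization", "count"] == 1


def test_non_outcome_sections_sum_to_case_total():
    df = summarize(_summary_corpus(), "tolvaptan")
    for section in ("sex", "age", "weight", "onset", "year"):
        assert df[df.section == section]["count"].sum() == 4


# ---------------------------------------------------------------------------
# Outcome-linked events and concomitants
# ---------------------------------------------------------------------------

def _outcome_corpus():
    return [
        make_case("1", [("tolvaptan", "PS")], [("x", "s")], outcomes={"death"}),
        make_case("2", [("tolvaptan", "PS")], [("x", "s"), ("x", "s")],
                  outcomes={"death"}),
        make_case("3", [("tolvaptan", "PS")], [("y", "s")], outcomes={"death"}),
        make_case("4", [("tolvaptan", "PS")], [("z", "s")]),
    ]


def test_top_events_by_outcome_ranking():
    top = top_events_by_outcome(_outcome_corpus(), "tolvaptan", "death")
    assert top == [("x", 2), ("y", 1)]


def test_top_events_k_truncation_and_empty():
    assert top_events_by_outcome(_outcome_corpus(), "tolvaptan", "death", k=1) \
        == [("x", 2)]
    assert top_events_by_outcome(_outcome_corpus(), "tolvaptan",
                                 "disability") == []


def test_unknown_outcome_is_error():
    with pytest.raises(ValueError, match="outcome"):
        top_events_by_outcome(_outcome_corpus(), "tolvaptan", "demise")


def test_concomitant_distinct_case_counts():
    corpus = [
        make_case("1", [("tolvaptan", "PS"), ("furosemide", "C"),
                        ("furosemide", "SS")], [("x", "s")]),
        make_case("2", [("tolvaptan", "PS"), ("furosemide", "C"),
                        ("aspirin", "I")], [("x", "s")]),
        make_case("3", [("tolvaptan", "PS")], [("x", "s")]),
        make_case("4", [("aspirin", "PS"), ("warfarin", "C")], [("x", "s")]),
    ]
    assert concomitant_frequency(corpus, "tolvaptan") == \
        [("furosemide", 2), ("aspirin", 1)]
    assert concomitant_frequency(corpus[2:3], "tolvaptan") == []


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

def _sexed_corpus():
    male = {"sex": "male"}
    female = {"sex": "female"}
    return [
        make_case("1", [("tolvaptan", "PS")], [("q", "s")], demo_kw=male),
        make_case("2", [("tolvaptan", "PS")], [("p", "s")], demo_kw=female),
        make_case("3", [("aspirin", "PS")], [("q", "s")], demo_kw=male),
        make_case("4", [("aspirin", "PS")], [("p", "s")], demo_kw=female),
    ]


def test_event_confined_to_one_stratum():
    out = subgroup_signals(_sexed_corpus(), "tolvaptan", "sex", "PT")
    male_events = {s.event for s in out["male"]}
    female_events = {s.event for s in out["female"]}
    assert "q" in male_events and "q" not in female_events


def test_single_stratum_equals_crude_analysis():
    corpus = [c for c in _sexed_corpus() if c.demo.sex == "male"]
    out = subgroup_signals(corpus, "tolvaptan", "sex", "PT")
    assert set(out) == {"male"}
    crude = build_all_tables(corpus, "tolvaptan", "PT")
    by_event = {s.event: s for s in out["male"]}
    for event, t in crude.items():
        assert by_event[event].table == t


def test_stratum_a_sums_to_crude_a(fixture_reports):
    crude = build_all_tables(fixture_reports, "tolvaptan", "PT")
    out = subgroup_signals(fixture_reports, "tolvaptan", "age_coarse", "PT")
    for event, t in crude.items():
        total = sum(s.table.a for rows in out.values()
                    for s in rows if s.event == event)
        assert total == t.a


def test_small_stratum_count_reported_but_not_flagged():
    corpus = _sexed_corpus()
    out = subgroup_signals(corpus, "tolvaptan", "sex", "PT")
    q = next(s for s in out["male"] if s.event == "q")
    assert q.n == 1
    assert not q.flag_ror          # n gate


def test_unknown_stratifier_is_error():
    with pytest.raises(ValueError, match="stratifier"):
        subgroup_signals(_sexed_corpus(), "tolvaptan", "height", "PT")
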