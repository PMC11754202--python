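"""The four disproportionality algorithms, their identities and flags."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from faersignal.contingency import ContingencyTable
from faersignal.signals import (BcpnnPriors, Thresholds, bcpnn_stats,
                                compute_signal, ebgm_stats, evaluate_flags,
                                prr_stats, rank_signals, ror_stats)

BALANCED = ContingencyTable(10, 10, 10, 10)
SKEWED = ContingencyTable(20, 10, 10, 20)

cells = st.integers(1, 500)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------

def test_ror_is_one_under_independence():
    ror, lo, hi = ror_stats(BALANCED)
    assert ror == pytest.approx(1.0)
    assert lo < 1 < hi


def test_ror_hand_computation():
    ror, lo, hi = ror_stats(SKEWED)
    assert ror == pytest.approx(4.0)
    # 4 * exp(-/+ 1.96*sqrt(0.3)), evaluated with 30-digit arithmetic
    assert lo == pytest.approx(1.36719083376208738955956904299, rel=1e-12)
    assert hi == pytest.approx(11.7028286065764031470441698704, rel=1e-12)


def test_ror_zero_cell_non_computable_without_correction():
    t = ContingencyTable(5, 0, 3, 10)
    assert all(math.isnan(x) for x in ror_stats(t))
    ror, lo, hi = ror_stats(t.with_correction())
    assert math.isfinite(ror) and lo < ror < hi


# ---------------------------------------------------------------------------
# PRR
# ---------------------------------------------------------------------------

def test_prr_values():
    assert prr_stats(BALANCED)[0] == pytest.approx(1.0)
    assert prr_stats(SKEWED)[0] == pytest.approx(2.0)   # (20/30)/(10/30)


def test_prr_zero_c_non_computable():
    assert math.isnan(prr_stats(ContingencyTable(5, 5, 0, 10))[0])


def test_ror_dominates_prr_iff_ror_above_one_exhaustive():
    """ROR >= PRR <=> ROR >= 1 over all tables with cells in 1..6
    (ROR/PRR = (1 + a/b)/(1 + c/d))."""
    for a, b, c, d in itertools.product(range(1, 7), repeat=4):
        t = ContingencyTable(a, b, c, d)
        ror, prr = ror_stats(t)[0], prr_stats(t)[0]
        if ror > 1:
            assert ror > prr or math.isclose(ror, prr)
        elif ror < 1:
            assert ror < prr or math.isclose(ror, prr)
        else:
            assert prr == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

def test_ic_log2_values():
    ic, *_ = bcpnn_stats(BALANCED)
    assert ic == pytest.approx(0.0)
    ic, *_ = bcpnn_stats(SKEWED)
    assert ic == pytest.approx(math.log2(4 / 3))


def test_bcpnn_moments_match_symbolic_transcription():
    """E(IC), V(IC) for (5,5,5,5): frozen from an exact rational
    evaluation of the posterior-moment formulas (sympy, 20 digits)."""
    ic, e_ic, v_ic, ic025 = bcpnn_stats(ContingencyTable(5, 5, 5, 5))
    assert e_ic == pytest.approx(0.0, abs=1e-12)       # exact independence
    assert v_ic == pytest.approx(0.43075288476463883121, rel=1e-12)
    assert ic025 == pytest.approx(-2 * math.sqrt(v_ic))


def test_ic_non_computable_at_zero_a_but_moments_finite():
    ic, e_ic, v_ic, ic025 = bcpnn_stats(ContingencyTable(0, 5, 5, 5))
    assert math.isnan(ic)
    assert math.isfinite(e_ic) and math.isfinite(v_ic) and math.isfinite(ic025)


def test_gamma_prior_scales_with_margins():
    pri = BcpnnPriors()
    t = ContingencyTable(5, 5, 5, 5)
    n = t.n_total
    expected = (n + 2) * (n + 2) / ((5 + 5 + 1) * (5 + 5 + 1))
    assert pri.gamma(t) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# EBGM
# ---------------------------------------------------------------------------

def test_ebgm_observed_over_expected():
    assert ebgm_stats(BALANCED)[0] == pytest.approx(1.0)
    ebgm, e05, e95 = ebgm_stats(SKEWED)
    assert ebgm == pytest.approx(4 / 3)
    assert e05 < ebgm < e95


@settings(max_examples=300, deadline=None)
@given(tables)
def test_ic_identity_log2_ebgm(t):
    """The IC and EBGM point formulas share one argument."""
    ic = bcpnn_stats(t)[0]
    ebgm = ebgm_stats(t)[0]
    assert ic == pytest.approx(math.log2(ebgm), abs=1e-12)


@settings(max_examples=300, deadline=None)
@given(tables)
def test_ci_geometric_mean_recovers_point(t):
    for fn in (ror_stats, prr_stats, ebgm_stats):
        point, lo, hi = fn(t)
        assert math.sqrt(lo * hi) == pytest.approx(point, rel=1e-9)


@settings(max_examples=100, deadline=None)
@given(st.integers(1, 200), cells, cells, cells)
def test_ror_prr_strictly_increase_in_a(a, b, c, d):
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert ror_stats(t2)[0] > ror_stats(t1)[0]
    assert prr_stats(t2)[0] > prr_stats(t1)[0]


@settings(max_examples=100, deadline=None)
@given(st.integers(1, 200), st.integers(2, 500), st.integers(2, 500),
       st.integers(1, 500))
def test_all_four_increase_when_a_grows_at_fixed_margins(a, b, c, d):
    """Moving one case into the target cell while holding both margins
    and N fixed (a+1, b-1, c-1, d+1) strictly increases every
    statistic.  (With b, c, d fixed instead, IC and EBGM are *not*
    monotone: N grows with a and the observed/expected ratio tends to
    1, so only ROR and PRR admit that form of the property.)"""
    t1 = ContingencyTable(a, b, c, d)
    t2 = ContingencyTable(a + 1, b - 1, c - 1, d + 1)
    assert ror_stats(t2)[0] > ror_stats(t1)[0]
    assert prr_stats(t2)[0] > prr_stats(t1)[0]
    assert bcpnn_stats(t2)[0] > bcpnn_stats(t1)[0]
    assert ebgm_stats(t2)[0] > ebgm_stats(t1)[0]


# ---------------------------------------------------------------------------
# Flags and ranking
# ---------------------------------------------------------------------------

def _flagged_stats(**kw):
    s = compute_signal("e", "PT", ContingencyTable(50, 500, 50, 5000))
    return s


def test_strong_signal_flags_all_four():
    s = _flagged_stats()
    assert s.flag_ror and s.flag_prr and s.flag_bcpnn and s.flag_ebgm
    assert s.flag_all4


def test_n_gate_disables_ror_and_prr():
    s = compute_signal("e", "PT", ContingencyTable(2, 20, 2, 200))
    assert not s.flag_ror and not s.flag_prr


def test_thresholds_are_strict_where_specified():
    import dataclasses
    s = _flagged_stats()
    s = dataclasses.replace(s, ebgm05=2.0)      # boundary: strict >
    s = evaluate_flags(s, Thresholds())
    assert not s.flag_ebgm
    s = dataclasses.replace(s, ror=3.0)         # boundary: inclusive >=
    assert evaluate_flags(s, Thresholds()).flag_ror


def test_prr_ci_condition_configurable():
    import dataclasses
    s = _flagged_stats()
    s = dataclasses.replace(s, prr_ci_low=0.9)
    assert not evaluate_flags(s, Thresholds()).flag_prr
    assert evaluate_flags(s, Thresholds(require_prr_ci=False)).flag_prr


def test_non_computable_statistic_never_flags():
    s = compute_signal("e", "PT", ContingencyTable(5, 0, 3, 10))
    assert not s.flag_ror
    assert not s.flag_all4


def test_rank_by_n_descending():
    rows = [compute_signal(e, "PT", ContingencyTable(n, 10, 10, 100))
            for e, n in (("a", 5), ("b", 9), ("c", 7))]
    assert [r.event for r in rank_signals(rows, by="n")] == ["b", "c", "a"]


def test_rank_tie_broken_by_n_then_name():
    rows = [compute_signal("x", "PT", ContingencyTable(4, 4, 10, 10)),
            compute_signal("y", "PT", ContingencyTable(8, 8, 20, 20))]
    ranked = rank_signals(rows, by="ror")       # equal ROR = 2.5? -> n decides
    assert ranked[0].event == "y"
    assert rank_signals([], by="ebgm") == []


def test_unknown_rank_key_is_error():
    with pytest.raises(ValueError):
        rank_signals([], by="pct")
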