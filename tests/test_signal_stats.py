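"""Unit and property tests for the four disproportionality statistics,
their criteria and the multiple-testing correction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerspv import signal_stats as ss
from faerspv.cohort import CasePtPair
from faerspv.faers_io import MISSING_DATE
from faerspv.signal_stats import ContingencyTable

WORKED = ContingencyTable(20, 80, 100, 9800)

cells = st.integers(min_value=1, max_value=500)


@st.composite
def tables(draw):
    return ContingencyTable(draw(cells), draw(cells), draw(cells), draw(cells))


# ---------------------------------------------------------------------------
# Hand-arithmetic oracle on the worked 2×2
# ---------------------------------------------------------------------------

def test_worked_table_ror():
    r = ss.ror_with_ci(WORKED)
    assert r.ror == pytest.approx(24.5)                       # (20·9800)/(80·100)
    se = math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 9800)
    assert r.ci95[0] == pytest.approx(24.5 * math.exp(-1.959963984540054 * se))
    assert r.ci95[1] == pytest.approx(24.5 * math.exp(1.959963984540054 * se))
    assert not r.degenerate


def test_worked_table_prr_and_chi2():
    p = ss.prr_with_chi2(WORKED)
    assert p.prr == pytest.approx(19.8)                       # (20/100)/(100/9900)
    n = WORKED.n_total
    chi2 = (20 * 9800 - 80 * 100) ** 2 * n / (100 * 9900 * 120 * 9880)
    assert p.chi2 == pytest.approx(chi2)
    assert 0 < p.p < 1e-10


def test_worked_table_ic_and_ebgm_share_core_ratio():
    i = ss.bcpnn_ic(WORKED)
    e = ss.ebgm_with_ci(WORKED)
    assert e.ebgm == pytest.approx(16.6667, abs=1e-3)         # 20·10000/(100·120)
    assert i.ic == pytest.approx(math.log2(16.6667), abs=1e-3)
    assert 2.0 ** i.ic == pytest.approx(e.ebgm)


# ---------------------------------------------------------------------------
# Algebraic identities
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t", [
    ContingencyTable(10, 10, 10, 10),
    ContingencyTable(5, 15, 20, 60),
    ContingencyTable(3, 9, 100, 300),
])
def test_all_four_estimates_equal_one_on_independence_tables(t):
    assert t.a * t.d == t.b * t.c   # a/b = c/d precondition
    assert ss.ror_with_ci(t).ror == pytest.approx(1.0)
    assert ss.prr_with_chi2(t).prr == pytest.approx(1.0)
    assert ss.prr_with_chi2(t).chi2 == pytest.approx(0.0)
    assert ss.bcpnn_ic(t).ic == pytest.approx(0.0)
    assert ss.ebgm_with_ci(t).ebgm == pytest.approx(1.0)


@given(tables())
def test_ebgm_equals_two_to_the_ic(t):
    assert 2.0 ** ss.bcpnn_ic(t).ic == pytest.approx(ss.ebgm_with_ci(t).ebgm, rel=1e-9)


@given(tables())
def test_chi2_invariant_under_transposition(t):
    assert ss.prr_with_chi2(t).chi2 == pytest.approx(ss.prr_with_chi2(t.transposed()).chi2,
                                                     rel=1e-9)


@given(tables())
def test_ror_at_least_prr_iff_ror_at_least_one(t):
    ror = ss.ror_with_ci(t).ror
    prr = ss.prr_with_chi2(t).prr
    if ror > 1:
        assert ror >= prr
    elif ror < 1:
        assert ror <= prr
    else:
        assert prr == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Degenerate cells
# ---------------------------------------------------------------------------

def test_zero_a_reports_ror_zero_with_degenerate_ci():
    r = ss.ror_with_ci(ContingencyTable(0, 10, 5, 100))
    assert r.ror == 0.0
    assert r.degenerate
    assert r.ci95[0] > 0   # CI computed on corrected cells, not collapsed


def test_zero_b_uses_haldane_correction_for_estimate():
    t = ContingencyTable(3, 0, 5, 100)
    r = ss.ror_with_ci(t)
    aa, bb, cc, dd = 3.5, 0.5, 5.5, 100.5
    assert r.ror == pytest.approx(aa * dd / (bb * cc))
    assert r.degenerate
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    assert r.ci95[0] == pytest.approx(r.ror * math.exp(-1.959963984540054 * se))


def test_shrunk_ic_finite_and_negative_at_zero_a():
    i = ss.bcpnn_ic(ContingencyTable(0, 10, 5, 100))
    assert i.degenerate
    assert i.ic == -math.inf              # raw mode flags the degeneracy
    assert math.isfinite(i.ic_e) and i.ic_e < 0
    assert math.isfinite(i.ic025)


def test_zero_a_ebgm_zero_flagged():
    e = ss.ebgm_with_ci(ContingencyTable(0, 10, 5, 100))
    assert e.ebgm == 0.0 and e.degenerate


# ---------------------------------------------------------------------------
# Criteria and correction
# ---------------------------------------------------------------------------

def test_strong_rare_signal_passes_all_four_criteria():
    """A rare but extreme pair — 7 focal reports, reporting rate ~45× the
    background — must be flagged by every algorithm, as printed signal
    tables show for such rows (e.g. starvation ketoacidosis, n=7,
    ROR=PRR=45.56)."""
    # Reconstruct counts matching the printed ROR/PRR: focal pairs 78,709 of
    # which a=7; background rate = focal rate / 45.56.
    a, b = 7, 78_702
    c = 39
    d = round(c / ((a / (a + b)) / 45.56)) - c
    t = ContingencyTable(a, b, c, d)
    s = ss.compute_signal(t)
    assert s.ror == pytest.approx(45.56, rel=0.01)
    assert s.prr == pytest.approx(45.56, rel=0.01)
    assert s.ror_sig and s.prr_sig and s.bcpnn_sig and s.mgps_sig
    assert s.significant_all4


def test_independence_table_sets_no_flags():
    s = ss.compute_signal(ContingencyTable(10, 10, 10, 10))
    assert not (s.ror_sig or s.prr_sig or s.bcpnn_sig or s.mgps_sig)
    assert not s.significant_all4


def test_n_reports_gate_blocks_tiny_counts():
    # Huge ratio but only 2 focal reports: the N >= 3 gate must hold.
    s = ss.compute_signal(ContingencyTable(2, 10, 1, 10_000))
    assert not s.ror_sig and not s.prr_sig


def test_bonferroni_threshold():
    assert ss.bonferroni_threshold(0.05, 100) == pytest.approx(5e-4)
    assert ss.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    with pytest.raises(ValueError, match="n_tests"):
        ss.bonferroni_threshold(0.05, 0)


def test_pt_frequency_bounds():
    assert ss.pt_frequency(0, 1000) == 0.0
    with pytest.raises(ValueError):
        ss.pt_frequency(5, 0)
    with pytest.raises(ValueError):
        ss.pt_frequency(5, 4)


# ---------------------------------------------------------------------------
# Table building
# ---------------------------------------------------------------------------

def _pair(cid: str, focal: bool, pt: str, soc: str | None = None) -> CasePtPair:
    return CasePtPair(primaryid=cid, caseid=cid, drug_is_focal_ps=focal, pt=pt,
                      soc=soc, sex="F", event_dt=MISSING_DATE, start_dt=MISSING_DATE)


def test_build_table_minimal_partition():
    pairs = [_pair("1", True, "X"), _pair("2", True, "Y"),
             _pair("3", False, "X"), _pair("4", False, "Y")]
    t = ss.build_table(pairs, "X")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_soc_level_counts_once_per_case():
    pairs = [_pair("1", True, "NAUSEA", "GI"), _pair("1", True, "VOMITING", "GI"),
             _pair("2", False, "NAUSEA", "GI"), _pair("3", False, "RASH", "SKIN")]
    t = ss.build_table(pairs, "GI", level="SOC")
    assert t.a == 1    # one case, not two PTs
    assert t.c == 1


def test_build_table_unknown_event_rejected():
    with pytest.raises(ValueError, match="unknown event"):
        ss.build_table([_pair("1", True, "X")], "NOPE")


def test_table_cells_match_bruteforce_set_algebra(small_db):
    """Every 2×2 cell equals an independent set-intersection recount."""
    pairs = small_db.pairs
    focal_pairs = {(p.caseid, p.pt) for p in pairs if p.drug_is_focal_ps}
    other_pairs = {(p.caseid, p.pt) for p in pairs if not p.drug_is_focal_ps}
    for event in ("NAUSEA", "HEADACHE", "INJECTION SITE PAIN"):
        t = ss.build_table(pairs, event)
        assert t.a == sum(1 for _, pt in focal_pairs if pt == event)
        assert t.b == len(focal_pairs) - t.a
        assert t.c == sum(1 for _, pt in other_pairs if pt == event)
        assert t.d == len(other_pairs) - t.c


def test_signal_table_consistent_with_single_tables(small_db):
    df = ss.signal_table(small_db.pairs, level="PT")
    row = df[df.event == "NAUSEA"].iloc[0]
    t = ss.build_table(small_db.pairs, "NAUSEA")
    assert (row.a, row.b, row.c, row.d) == (t.a, t.b, t.c, t.d)
    s = ss.compute_signal(t)
    assert row.ror == pytest.approx(s.ror)
    assert row.ebgm == pytest.approx(s.ebgm)
    assert df.attrs["n_tests"] >= 1


def test_indication_exclusion_bars_signal_not_statistics():
    pairs = ([_pair(f"f{i}", True, "WEIGHT DECREASED") for i in range(60)]
             + [_pair(f"f{i}", True, "OTHER") for i in range(60, 100)]
             + [_pair(f"o{i}", False, "WEIGHT DECREASED") for i in range(10)]
             + [_pair(f"o{i}", False, "OTHER") for i in range(10, 1000)])
    df = ss.signal_table(pairs, indication_exclude=("WEIGHT DECREASED",))
    row = df[df.event == "WEIGHT DECREASED"].iloc[0]
    assert row.significant_all4          # statistics still computed and strong
    assert row.indication_excluded
    assert not row.signal                # but barred from the significant set
    assert ss.significant_signals(df).event.tolist() == []
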