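"""Unit and property tests for deduplication, drug-name matching and
cohort construction."""

from __future__ import annotations

import random

import pandas as pd
import pytest

from faerspv import cohort
from faerspv.faers_io import DemoRecord, DrugRecord, MISSING_DATE, ReacRecord, parse_flexible_date


def _demo(pid: str, cid: str, fda: str, sex: str = "F") -> DemoRecord:
    return DemoRecord(primaryid=pid, caseid=cid, fda_dt=parse_flexible_date(fda),
                      event_dt=MISSING_DATE, sex=sex, age_years=None, weight_kg=None,
                      country="US", reporter="consumer", outcome_codes=frozenset())


def _drug(pid: str, name: str, role: str = "PS", seq: str = "1") -> DrugRecord:
    return DrugRecord(primaryid=pid, drug_seq=seq, drug_name=name, role_code=role,
                      start_dt=MISSING_DATE, indication=None)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def test_latest_fda_dt_wins():
    res = cohort.deduplicate([_demo("1", "A", "20230101"), _demo("2", "A", "20230301")])
    assert res.kept_primaryids == frozenset({"2"})


def test_fda_dt_tie_broken_by_higher_primaryid():
    res = cohort.deduplicate([_demo("5", "B", "20230101"), _demo("9", "B", "20230101")])
    assert res.kept_primaryids == frozenset({"9"})
    # numeric, not lexicographic, comparison
    res2 = cohort.deduplicate([_demo("10", "B", "20230101"), _demo("9", "B", "20230101")])
    assert res2.kept_primaryids == frozenset({"10"})


def test_missing_fda_dt_loses_to_any_dated_version():
    res = cohort.deduplicate([_demo("7", "C", ""), _demo("3", "C", "20220601")])
    assert res.kept_primaryids == frozenset({"3"})


def test_single_record_cases_kept_verbatim():
    res = cohort.deduplicate([_demo("1", "A", ""), _demo("2", "B", "")])
    assert res.kept_primaryids == frozenset({"1", "2"})
    assert res.n_dropped == 0


def _random_versions(seed: int, n: int = 1000, n_cases: int = 400):
    rnd = random.Random(seed)
    pids = rnd.sample(range(10_000, 99_999), n)
    recs = []
    for pid in pids:
        cid = f"C{rnd.randrange(n_cases)}"
        if rnd.random() < 0.05:
            fda = ""
        else:
            fda = f"202{rnd.randrange(2, 4)}{rnd.randrange(1, 13):02d}{rnd.randrange(1, 29):02d}"
        recs.append(_demo(str(pid), cid, fda))
    return recs


def test_dedup_matches_bruteforce_group_sort_take_last():
    """Independent oracle: group by caseid, sort by (fda_dt, numeric
    primaryid), take the last row."""
    recs = _random_versions(seed=2024)
    df = pd.DataFrame({
        "caseid": [r.caseid for r in recs],
        "primaryid": [int(r.primaryid) for r in recs],
        "fda": [int(r.fda_dt.raw) if r.fda_dt.is_exact else -1 for r in recs],
    })
    expected = set(
        df.sort_values(["fda", "primaryid"], kind="mergesort")
          .groupby("caseid").tail(1)["primaryid"].astype(str))
    assert set(cohort.deduplicate(recs).kept_primaryids) == expected


def test_dedup_idempotent_and_order_invariant():
    recs = _random_versions(seed=7)
    kept = cohort.deduplicate(recs).kept_primaryids
    shuffled = list(recs)
    random.Random(1).shuffle(shuffled)
    assert cohort.deduplicate(shuffled).kept_primaryids == kept
    surviving = [r for r in recs if r.primaryid in kept]
    assert cohort.deduplicate(surviving).kept_primaryids == kept


# ---------------------------------------------------------------------------
# Drug-name matching
# ---------------------------------------------------------------------------

NAMES = ("TIRZEPATIDE", "MOUNJARO", "ZEPBOUND")


@pytest.mark.parametrize("verbatim, expected", [
    ("Mounjaro", True),
    ("MOUNJARO 5MG/0.5ML PEN", True),
    ("  tirzepatide  ", True),
    ("ZEPBOUND (TIRZEPATIDE)", True),
    ("METFORMIN", False),
    ("ZEPBOUNDX", False),          # word boundary: no partial-token match
    ("XMOUNJARO", False),
])
def test_match_focal_drug_substring(verbatim, expected):
    assert cohort.match_focal_drug(verbatim, NAMES) is expected


def test_match_focal_drug_exact_mode():
    assert cohort.match_focal_drug("MOUNJARO", NAMES, mode="exact")
    assert not cohort.match_focal_drug("MOUNJARO 5MG/0.5ML PEN", NAMES, mode="exact")


def test_match_focal_drug_empty_list_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        cohort.match_focal_drug("MOUNJARO", [])


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def test_concomitant_only_case_contributes_no_pairs():
    demo = [_demo("1", "A", "20230101")]
    drugs = [_drug("1", "MOUNJARO", role="C")]
    reacs = [ReacRecord("1", "NAUSEA")]
    pairs = cohort.build_case_pt_pairs(demo, drugs, reacs, {"1"}, NAMES)
    assert pairs == []


def test_pts_deduplicated_within_case():
    demo = [_demo("1", "A", "20230101")]
    drugs = [_drug("1", "MOUNJARO")]
    reacs = [ReacRecord("1", "NAUSEA"), ReacRecord("1", "NAUSEA"), ReacRecord("1", "VOMITING")]
    pairs = cohort.build_case_pt_pairs(demo, drugs, reacs, {"1"}, NAMES)
    assert sorted(p.pt for p in pairs) == ["NAUSEA", "VOMITING"]


def test_cohort_size_monotone_under_stricter_role_filter(small_db):
    kwargs = dict(demo=small_db.demo, drugs=small_db.drugs, reacs=small_db.reacs,
                  kept_primaryids=small_db.dedup.kept_primaryids, focal_names=NAMES)
    ps_only = cohort.build_case_pt_pairs(role_filter=("PS",), **kwargs)
    ps_ss = cohort.build_case_pt_pairs(role_filter=("PS", "SS"), **kwargs)
    all_roles = cohort.build_case_pt_pairs(role_filter=("PS", "SS", "C", "I"), **kwargs)
    assert len(ps_only) <= len(ps_ss) <= len(all_roles)


def test_pair_count_matches_bruteforce_recount(small_db):
    """Independent recount over the emitted files with pandas set algebra."""
    demo_frames, drug_frames, reac_frames = [], [], []
    for q in sorted(small_db.dir.glob("DEMO*.txt")):
        demo_frames.append(pd.read_csv(q, sep="$", dtype=str, engine="python"))
    for q in sorted(small_db.dir.glob("DRUG*.txt")):
        drug_frames.append(pd.read_csv(q, sep="$", dtype=str, engine="python"))
    for q in sorted(small_db.dir.glob("REAC*.txt")):
        reac_frames.append(pd.read_csv(q, sep="$", dtype=str, engine="python"))
    demo = pd.concat(demo_frames)
    drug = pd.concat(drug_frames)
    reac = pd.concat(reac_frames)
    kept = set(
        demo.assign(fda=demo.fda_dt.astype(int), pid=demo.primaryid.astype(int))
            .sort_values(["fda", "pid"], kind="mergesort")
            .groupby("caseid").tail(1)["primaryid"])
    aliases = set(small_db.config.focal_aliases)
    focal_pids = set(drug[(drug.role_cod == "PS") & drug.drugname.isin(aliases)
                          & drug.primaryid.isin(kept)].primaryid)
    expected = len(reac[reac.primaryid.isin(focal_pids)][["primaryid", "pt"]]
                   .drop_duplicates())
    got = [p for p in small_db.pairs if p.drug_is_focal_ps]
    assert len(got) == expected


def test_focal_flag_partition(small_db):
    pids = {p.primaryid for p in small_db.pairs}
    focal = {p.primaryid for p in small_db.pairs if p.drug_is_focal_ps}
    other = {p.primaryid for p in small_db.pairs if not p.drug_is_focal_ps}
    assert focal | other == pids
    assert not (focal & other)


def test_pt_soc_map_duplicate_keeps_first(tmp_path, caplog):
    p = tmp_path / "map.txt"
    p.write_text("pt$soc\nNAUSEA$Gastrointestinal disorders\nNAUSEA$Other\n")
    mapping = cohort.load_pt_soc_map(p)
    assert mapping["NAUSEA"] == "Gastrointestinal disorders"
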