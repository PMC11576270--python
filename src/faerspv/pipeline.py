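"""End-to-end orchestration: ingest → dedup → cohort → signals → TTO → subgroups.

Reads a directory of FAERS-style quarterly tables, deduplicates case
versions, selects the focal-drug primary-suspect cohort, and emits the full
result bundle as delimited text: a descriptive characteristics table,
SOC- and PT-level signal tables, the significant-PT ranking, the
time-to-onset bundle (histogram, Weibull fit, per-SOC summary, sex KM
curves) and the sex-subgroup comparison, plus a machine-readable run log
with dedup and exclusion tallies.  Outputs are pure functions of the inputs
and configuration, so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import cohort as cohort_mod
from . import faers_io, signal_stats, subgroup, tto

logger = logging.getLogger(__name__)

ALL_STAGES = ("descriptive", "signals", "tto", "subgroup")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input_dir: Path
    output_dir: Path
    focal_drug_names: tuple[str, ...] = ("TIRZEPATIDE", "MOUNJARO", "ZEPBOUND")
    pt_soc_map_path: Path | None = None      # default: <input_dir>/pt_soc_map.txt if present
    indication_exclude: tuple[str, ...] = ()
    auto_exclude_indications: bool = True
    p_nominal: float = 0.05
    top_k: int = 20
    min_reports: int = 3
    match_mode: str = "substring"
    comparator: str = "stratum"
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        if self.pt_soc_map_path is not None and not Path(self.pt_soc_map_path).is_file():
            raise ValueError(f"pt_soc_map_path does not exist: {self.pt_soc_map_path}")
        if not 0 < self.p_nominal < 1:
            raise ValueError(f"p_nominal must lie in (0, 1), got {self.p_nominal}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunResult:
    """In-memory bundle of everything a run produced."""

    descriptive: pd.DataFrame | None = None
    soc_table: pd.DataFrame | None = None
    pt_table: pd.DataFrame | None = None
    pt_significant: pd.DataFrame | None = None
    tto_observations: list = field(default_factory=list)
    tto_exclusions: Counter = field(default_factory=Counter)
    tto_histogram: pd.DataFrame | None = None
    weibull: tto.WeibullFit | None = None
    tto_by_soc: pd.DataFrame | None = None
    km: tto.KmResult | None = None
    subgroups: dict = field(default_factory=dict)
    topk_comparison: subgroup.TopKComparison | None = None
    log: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Descriptive characteristics
# ---------------------------------------------------------------------------

def _band(value: float | None, bands: Sequence[tuple[str, float, float]]) -> str:
    if value is None:
        return "Unknown"
    for label, lo, hi in bands:
        if lo <= value <= hi:
            return label
    return "Unknown"


_AGE_BANDS = (("<18", float("-inf"), 17.9999), ("18-65", 18.0, 65.0), (">65", 65.0001, float("inf")))
_WT_BANDS = (("<50", float("-inf"), 49.9999), ("50-100", 50.0, 100.0), (">100", 100.0001, float("inf")))


def descriptive_summary(cases: Sequence[faers_io.DemoRecord],
                        indications: Mapping[str, str] | None = None,
                        top_countries: int = 3,
                        top_indications: int = 5) -> pd.DataFrame:
    """Demographic characteristics of the cohort as (block, category, count,
    percent) rows; percentages are 100·count/total to one decimal.

    Blocks: sex, age bands, weight bands, top reporting countries (plus
    "Other"), reporter type, serious outcomes (a case counts once per
    outcome; "Unknown" means no outcome recorded) and top indications.
    """
    total = len(cases)
    rows: list[tuple[str, str, int]] = []

    def block(name: str, counter: Counter, order: Sequence[str]) -> None:
        for cat in order:
            rows.append((name, cat, counter.get(cat, 0)))

    sex_c = Counter("Female" if c.sex == "F" else "Male" if c.sex == "M" else "Unknown"
                    for c in cases)
    block("Gender", sex_c, ("Female", "Male", "Unknown"))

    age_c = Counter(_band(c.age_years, _AGE_BANDS) for c in cases)
    block("Age", age_c, ("<18", "18-65", ">65", "Unknown"))

    wt_c = Counter(_band(c.weight_kg, _WT_BANDS) for c in cases)
    block("Weight", wt_c, ("<50", "50-100", ">100", "Unknown"))

    country_c = Counter(c.country or "Unknown" for c in cases)
    top = [k for k, _ in sorted(country_c.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]]
    for k in top:
        rows.append((f"Reported countries (top {top_countries})", k, country_c[k]))
    other = total - sum(country_c[k] for k in top)
    rows.append((f"Reported countries (top {top_countries})", "Other", other))

    rep_c = Counter(c.reporter for c in cases)
    for label, key in (("Health professionals", "health professional"),
                       ("Consumer", "consumer"), ("Unknown", "unknown")):
        rows.append(("Reported person", label, rep_c.get(key, 0)))

    out_c: Counter = Counter()
    n_no_outcome = 0
    for c in cases:
        if not c.outcome_codes:
            n_no_outcome += 1
        for code in c.outcome_codes:
            out_c[code] += 1
    for code in ("HO", "LT", "DS", "CA", "DE", "OT", "RI"):
        rows.append(("Outcome", faers_io.OUTCOME_LABELS[code], out_c.get(code, 0)))
    rows.append(("Outcome", "Unknown", n_no_outcome))

    if indications is not None:
        ind_c = Counter(indications.get(c.primaryid) or "Unknown" for c in cases)
        top_i = [k for k, _ in sorted(ind_c.items(), key=lambda kv: (-kv[1], kv[0]))[:top_indications]]
        for k in top_i:
            rows.append((f"Indication (top {top_indications})", k, ind_c[k]))
        rows.append((f"Indication (top {top_indications})", "Other",
                     total - sum(ind_c[k] for k in top_i)))

    df = pd.DataFrame(rows, columns=["block", "category", "count"])
    df["percent"] = (100.0 * df["count"] / total).round(1) if total else 0.0
    return df


# ---------------------------------------------------------------------------
# Ingestion helpers
# ---------------------------------------------------------------------------

def _read_all(input_dir: Path, kind: str) -> tuple[list[dict], int]:
    """Concatenate all quarterly files of one table kind (sorted by name)."""
    records: list[dict] = []
    n_malformed = 0
    for path in sorted(Path(input_dir).glob(f"{kind}*.txt")):
        parsed = faers_io.read_table(path, kind)
        records.extend(parsed.records)
        n_malformed += parsed.n_malformed
    return records, n_malformed


def load_database(input_dir: str | Path):
    """Read every quarterly table under ``input_dir`` into typed records.

    Returns (demo, drugs, reacs, malformed-count-per-table).  RPSR files,
    if any, are tolerated and ignored.
    """
    input_dir = Path(input_dir)
    malformed: dict[str, int] = {}
    raw: dict[str, list[dict]] = {}
    for kind in ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC"):
        raw[kind], malformed[kind] = _read_all(input_dir, kind)
    if not raw["DEMO"]:
        raise ValueError(f"no DEMO*.txt files with records found under {input_dir}")

    def as_table(kind: str) -> faers_io.ParsedTable:
        cols = sorted({c for r in raw[kind] for c in r}) if raw[kind] else \
            list(faers_io.MANDATORY_COLUMNS[kind])
        return faers_io.ParsedTable(kind, cols, raw[kind], malformed[kind])

    demo = faers_io.demo_records(as_table("DEMO"), outc=as_table("OUTC"))
    drugs = faers_io.drug_records(as_table("DRUG"), ther=as_table("THER"),
                                  indi=as_table("INDI"))
    reacs = faers_io.reac_records(as_table("REAC"))
    return demo, drugs, reacs, malformed


# ---------------------------------------------------------------------------
# The run itself
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run(config: RunConfig) -> RunResult:
    """Execute the configured stages and write the result bundle.

    Any stage failure raises with the stage name prefixed, so a broken
    input is attributable to the step that rejected it.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = RunResult()
    stage = "ingest"
    try:
        demo, drugs, reacs, malformed = load_database(config.input_dir)

        stage = "dedup"
        dedup = cohort_mod.deduplicate(demo)

        stage = "cohort"
        map_path = config.pt_soc_map_path
        if map_path is None:
            candidate = Path(config.input_dir) / "pt_soc_map.txt"
            map_path = candidate if candidate.is_file() else None
        pt_soc = cohort_mod.load_pt_soc_map(map_path) if map_path else None
        pairs = cohort_mod.build_case_pt_pairs(
            demo, drugs, reacs, dedup.kept_primaryids, config.focal_drug_names,
            pt_soc_map=pt_soc, focal_only=False, match_mode=config.match_mode)
        focal_pairs = [p for p in pairs if p.drug_is_focal_ps]
        focal_pids = {p.primaryid for p in focal_pairs}
        focal_cases = [r for r in demo
                       if r.primaryid in focal_pids]

        exclude = {e.upper() for e in config.indication_exclude}
        indications: dict[str, str] = {}
        for d in drugs:
            if d.primaryid in focal_pids and d.role_code == "PS" and d.indication:
                indications.setdefault(d.primaryid, d.indication.upper())
        if config.auto_exclude_indications:
            pt_names = {p.pt for p in pairs}
            exclude |= set(indications.values()) & pt_names

        res.log = {
            "n_demo_rows": len(demo),
            "n_malformed": malformed,
            "n_cases": dedup.n_cases,
            "n_duplicate_versions_dropped": dedup.n_dropped,
            "n_focal_cases": len(focal_cases),
            "n_pairs_total": len(pairs),
            "n_focal_pairs": len(focal_pairs),
            "indication_excluded_pts": sorted(exclude),
        }

        if "descriptive" in config.stages:
            stage = "descriptive"
            res.descriptive = descriptive_summary(focal_cases, indications)
            _write(res.descriptive, out_dir / "descriptive.tsv")

        if "signals" in config.stages:
            stage = "signals"
            res.soc_table = signal_stats.signal_table(
                pairs, level="SOC", p_nominal=config.p_nominal,
                min_reports=config.min_reports)
            res.pt_table = signal_stats.signal_table(
                pairs, level="PT", p_nominal=config.p_nominal,
                min_reports=config.min_reports, indication_exclude=exclude)
            res.pt_significant = signal_stats.significant_signals(res.pt_table)
            _write(res.soc_table, out_dir / "soc_signals.tsv")
            _write(res.pt_table, out_dir / "pt_signals.tsv")
            _write(res.pt_significant, out_dir / "pt_significant.tsv")
            res.log["n_tests"] = res.pt_table.attrs["n_tests"]
            res.log["bonferroni_threshold"] = res.pt_table.attrs["bonferroni_threshold"]
            res.log["n_significant_pts"] = int(len(res.pt_significant))

        if "tto" in config.stages:
            stage = "tto"
            res.tto_observations, res.tto_exclusions = tto.extract_tto(focal_pairs)
            res.tto_histogram = tto.bin_tto(res.tto_observations)
            _write(res.tto_histogram, out_dir / "tto_histogram.tsv")
            res.tto_by_soc = tto.tto_by_soc(res.tto_observations)
            _write(res.tto_by_soc, out_dir / "tto_by_soc.tsv")
            res.log["tto_exclusions"] = dict(sorted(res.tto_exclusions.items()))
            days = [o.days for o in res.tto_observations]
            if len(days) >= 10 and len(set(days)) > 1:
                res.weibull = tto.weibull_fit(days)
                w = res.weibull
                (out_dir / "tto_weibull.txt").write_text(
                    f"n={w.n}\n"
                    f"shape={w.shape:.6g}\nshape_ci95={w.shape_ci95[0]:.6g},{w.shape_ci95[1]:.6g}\n"
                    f"scale={w.scale:.6g}\nscale_ci95={w.scale_ci95[0]:.6g},{w.scale_ci95[1]:.6g}\n"
                    f"trend={w.trend}\n"
                    f"median={w.median:.6g}\nq1={w.q1:.6g}\nq3={w.q3:.6g}\n"
                    f"min={w.min:.6g}\nmax={w.max:.6g}\n",
                    encoding="utf-8")
            else:
                logger.warning("too few complete TTO observations for a Weibull fit")
            strata_n = Counter(o.sex for o in res.tto_observations)
            if strata_n.get("F", 0) > 0 and strata_n.get("M", 0) > 0:
                res.km = tto.km_by_sex(res.tto_observations)
                _write(res.km.curves, out_dir / "km_curves.tsv")
                (out_dir / "km_logrank.txt").write_text(
                    f"statistic={res.km.statistic:.6g}\np_value={res.km.p_value:.6g}\n",
                    encoding="utf-8")

        if "subgroup" in config.stages:
            stage = "subgroup"
            for sex in ("F", "M"):
                try:
                    res.subgroups[sex] = subgroup.stratified_signals(
                        pairs, sex, k=config.top_k, comparator=config.comparator,
                        p_nominal=config.p_nominal, min_reports=config.min_reports,
                        indication_exclude=exclude)
                    _write(res.subgroups[sex].table, out_dir / f"subgroup_{sex}.tsv")
                except ValueError as exc:
                    logger.warning("subgroup %s skipped: %s", sex, exc)
            if "F" in res.subgroups and "M" in res.subgroups:
                res.topk_comparison = subgroup.compare_top_k(
                    res.subgroups["F"], res.subgroups["M"], k=config.top_k)
                _write(res.topk_comparison.rank_table, out_dir / "subgroup_topk.tsv")
                (out_dir / "subgroup_overlap.txt").write_text(
                    "shared=" + ",".join(res.topk_comparison.shared) + "\n"
                    "F_only=" + ",".join(res.topk_comparison.a_only) + "\n"
                    "M_only=" + ",".join(res.topk_comparison.b_only) + "\n",
                    encoding="utf-8")

        (out_dir / "run_log.json").write_text(
            json.dumps(res.log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return res
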