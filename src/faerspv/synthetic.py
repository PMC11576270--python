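"""Synthetic FAERS-dialect database generator with known ground truth.

Real spontaneous-report extracts cannot ship with a test suite, so this
module fabricates a multi-quarter FAERS-style database whose every property
is known in advance: which case versions survive deduplication, which
drug–event pairs carry an elevated reporting rate (overall or in one sex),
and which Weibull law generated the onset times.  Every downstream stage —
parsing, dedup, cohorting, disproportionality, time-to-onset, subgroups —
can then be checked against the generator's ledger instead of against
downloads.

What is emulated, with defaults mirroring a large real-world cohort of a
recently approved injectable antidiabetic:

* cross-quarter duplicate case versions (same CASEID, distinct PRIMARYID
  and FDA_DT),
* a heavily female cohort (68.8% F / 19.0% M / 12.2% unknown) with strong
  missingness in age, weight and outcomes,
* ~2 preferred terms per report (truncated Poisson, minimum 1) drawn from a
  flat PT→SOC vocabulary,
* planted reporting-rate ratios for chosen (drug, PT) pairs, implemented by
  rescaling the focal drug's per-PT weights and renormalising — the
  realised ratio is therefore verified empirically, never assumed,
* Weibull-distributed onset times (default shape 0.63, scale chosen so the
  median is 23 days) with only ~3.6% of reports carrying a full 8-digit
  event date; incomplete dates are emitted as 4- or 6-digit strings or left
  blank, and ~1% of reports have their dates swapped to exercise the
  negative-onset exclusion.

Generation is byte-deterministic for a given configuration and seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import faers_io

DEFAULT_FOCAL_DRUG = "TIRZEPATIDE"

DEFAULT_DRUGS: tuple[str, ...] = (
    DEFAULT_FOCAL_DRUG, "METFORMIN", "SEMAGLUTIDE", "ATORVASTATIN", "LISINOPRIL",
)

#: Verbatim strings used for the focal drug in DRUG rows (generic name,
#: brand names, and a branded string with dose text to exercise
#: word-boundary matching).
DEFAULT_FOCAL_ALIASES: tuple[str, ...] = (
    "TIRZEPATIDE", "MOUNJARO", "ZEPBOUND", "MOUNJARO 5 MG/0.5 ML PEN",
)

DEFAULT_PT_SOC: tuple[tuple[str, str], ...] = (
    ("NAUSEA", "Gastrointestinal disorders"),
    ("VOMITING", "Gastrointestinal disorders"),
    ("DIARRHOEA", "Gastrointestinal disorders"),
    ("CONSTIPATION", "Gastrointestinal disorders"),
    ("ERUCTATION", "Gastrointestinal disorders"),
    ("DYSPEPSIA", "Gastrointestinal disorders"),
    ("ABDOMINAL PAIN UPPER", "Gastrointestinal disorders"),
    ("FLATULENCE", "Gastrointestinal disorders"),
    ("ABDOMINAL DISTENSION", "Gastrointestinal disorders"),
    ("PANCREATITIS", "Gastrointestinal disorders"),
    ("INJECTION SITE PAIN", "General disorders and administration site conditions"),
    ("INJECTION SITE HAEMORRHAGE", "General disorders and administration site conditions"),
    ("INJECTION SITE ERYTHEMA", "General disorders and administration site conditions"),
    ("INJECTION SITE PRURITUS", "General disorders and administration site conditions"),
    ("INJECTION SITE BRUISING", "General disorders and administration site conditions"),
    ("INJECTION SITE RASH", "General disorders and administration site conditions"),
    ("FATIGUE", "General disorders and administration site conditions"),
    ("HUNGER", "General disorders and administration site conditions"),
    ("INCORRECT DOSE ADMINISTERED", "Injury, poisoning and procedural complications"),
    ("OFF LABEL USE", "Injury, poisoning and procedural complications"),
    ("EXTRA DOSE ADMINISTERED", "Injury, poisoning and procedural complications"),
    ("ACCIDENTAL UNDERDOSE", "Injury, poisoning and procedural complications"),
    ("PRODUCT ADMINISTERED AT INAPPROPRIATE SITE", "Injury, poisoning and procedural complications"),
    ("DECREASED APPETITE", "Metabolism and nutrition disorders"),
    ("STARVATION KETOACIDOSIS", "Metabolism and nutrition disorders"),
    ("INCREASED APPETITE", "Metabolism and nutrition disorders"),
    ("HYPOGLYCAEMIA", "Metabolism and nutrition disorders"),
    ("HEADACHE", "Nervous system disorders"),
    ("DIZZINESS", "Nervous system disorders"),
    ("DYSGEUSIA", "Nervous system disorders"),
    ("ALLODYNIA", "Nervous system disorders"),
    ("BLOOD GLUCOSE DECREASED", "Investigations"),
    ("WEIGHT DECREASED", "Investigations"),
    ("BLOOD CALCITONIN INCREASED", "Investigations"),
    ("GLYCOSYLATED HAEMOGLOBIN DECREASED", "Investigations"),
    ("ALOPECIA", "Skin and subcutaneous tissue disorders"),
    ("RASH", "Skin and subcutaneous tissue disorders"),
    ("URTICARIA", "Skin and subcutaneous tissue disorders"),
    ("PRURITUS", "Skin and subcutaneous tissue disorders"),
    ("INSOMNIA", "Psychiatric disorders"),
    ("ANXIETY", "Psychiatric disorders"),
)

DEFAULT_PLANTED_RR: dict[tuple[str, str], float] = {
    (DEFAULT_FOCAL_DRUG, "NAUSEA"): 5.0,
    (DEFAULT_FOCAL_DRUG, "INJECTION SITE PAIN"): 8.0,
    (DEFAULT_FOCAL_DRUG, "INCORRECT DOSE ADMINISTERED"): 10.0,
}

#: Indications assigned to the primary-suspect drug, with the cohort's
#: observed shares ("WEIGHT DECREASED" doubles as a PT, exercising the
#: indication-exclusion rule downstream).
DEFAULT_INDICATIONS: tuple[tuple[str, float], ...] = (
    ("PRODUCT USED FOR UNKNOWN INDICATION", 0.573),
    ("TYPE 2 DIABETES MELLITUS", 0.208),
    ("WEIGHT DECREASED", 0.051),
    ("DIABETES MELLITUS", 0.051),
    ("GLUCOSE TOLERANCE IMPAIRED", 0.035),
    ("OBESITY", 0.082),
)

_OUTCOME_CODES = ("OT", "HO", "DE", "LT", "DS", "RI", "CA")
_OUTCOME_WEIGHTS = (0.034, 0.026, 0.0025, 0.0016, 0.0015, 0.0013, 0.0001)

_DEMO_COLUMNS = ("primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
                 "sex", "age", "age_cod", "wt", "wt_cod", "occr_country", "occp_cod")
_DRUG_COLUMNS = ("primaryid", "caseid", "drug_seq", "role_cod", "drugname")
_REAC_COLUMNS = ("primaryid", "caseid", "pt")
_THER_COLUMNS = ("primaryid", "caseid", "dsg_drug_seq", "start_dt")
_INDI_COLUMNS = ("primaryid", "caseid", "indi_drug_seq", "indi_pt")
_OUTC_COLUMNS = ("primaryid", "caseid", "outc_cod")


def default_tto_scale(shape: float = 0.63, median_days: float = 23.0) -> float:
    """Weibull scale η such that the distribution median equals
    ``median_days``: η = median / ln2^(1/β)."""
    return median_days / math.log(2.0) ** (1.0 / shape)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic database.

    ``n_reports`` counts pre-dedup report *versions*; ``duplicate_fraction``
    is the probability that a case is emitted as two versions.
    ``background_rate`` is the per-PT marginal probability scale — a scalar
    gives a flat vocabulary, a mapping sets per-PT weights.  ``planted_rr``
    multiplies the focal drug's weight for chosen PTs before
    renormalisation; ``sex_specific_rr`` layers a further per-sex
    multiplier on top.
    """

    n_reports: int = 10_000
    n_quarters: int = 8
    drug_vocab: tuple[str, ...] = DEFAULT_DRUGS
    focal_aliases: tuple[str, ...] = DEFAULT_FOCAL_ALIASES
    pt_vocab: tuple[tuple[str, str], ...] = DEFAULT_PT_SOC
    background_rate: float | Mapping[str, float] = 0.1
    planted_rr: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_RR))
    sex_mix: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.688, "M": 0.190, "unknown": 0.122})
    sex_specific_rr: Mapping[tuple[str, str, str], float] | None = None
    duplicate_fraction: float = 0.10
    tto_shape: float = 0.63
    tto_scale: float = field(default_factory=default_tto_scale)
    event_date_completeness: float = 0.036
    start_date_completeness: float = 0.95
    negative_tto_fraction: float = 0.01
    start_quarter: str = "2022Q2"
    seed: int = 0

    @property
    def focal_drug(self) -> str:
        return self.drug_vocab[0]

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field."""
        if not isinstance(self.n_reports, (int, np.integer)) or self.n_reports < 1:
            raise ValueError(f"n_reports must be a positive integer, got {self.n_reports!r}")
        if not isinstance(self.n_quarters, (int, np.integer)) or self.n_quarters < 1:
            raise ValueError(f"n_quarters must be a positive integer, got {self.n_quarters!r}")
        if not self.drug_vocab:
            raise ValueError("drug_vocab must be non-empty (first entry is the focal drug)")
        if len(set(self.drug_vocab)) != len(self.drug_vocab):
            raise ValueError("drug_vocab contains duplicate names")
        if not self.focal_aliases:
            raise ValueError("focal_aliases must be non-empty")
        pts = [pt for pt, _ in self.pt_vocab]
        if not pts:
            raise ValueError("pt_vocab must be non-empty")
        if len(set(pts)) != len(pts):
            raise ValueError("pt_vocab contains duplicate PT names")
        if isinstance(self.background_rate, Mapping):
            missing = [pt for pt in pts if pt not in self.background_rate]
            if missing:
                raise ValueError(f"background_rate mapping is missing PTs: {missing[:3]}")
            bad = [pt for pt, r in self.background_rate.items() if not 0 <= r <= 1]
            if bad:
                raise ValueError(f"background_rate values outside [0, 1] for {bad[:3]}")
        elif not 0 <= float(self.background_rate) <= 1:
            raise ValueError(f"background_rate must lie in [0, 1], got {self.background_rate}")
        total = sum(self.sex_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sex_mix must sum to 1 (got {total})")
        if set(self.sex_mix) != {"F", "M", "unknown"}:
            raise ValueError(f"sex_mix keys must be F/M/unknown, got {sorted(self.sex_mix)}")
        if any(v < 0 for v in self.sex_mix.values()):
            raise ValueError("sex_mix probabilities must be non-negative")
        for (drug, pt), rr in self.planted_rr.items():
            if drug not in self.drug_vocab:
                raise ValueError(f"planted_rr references unknown drug {drug!r}")
            if pt not in pts:
                raise ValueError(f"planted_rr references unknown PT {pt!r}")
            if rr < 0:
                raise ValueError(f"planted_rr for ({drug}, {pt}) must be >= 0, got {rr}")
        if self.sex_specific_rr:
            for (drug, pt, sex), mult in self.sex_specific_rr.items():
                if drug not in self.drug_vocab:
                    raise ValueError(f"sex_specific_rr references unknown drug {drug!r}")
                if pt not in pts:
                    raise ValueError(f"sex_specific_rr references unknown PT {pt!r}")
                if sex not in self.sex_mix:
                    raise ValueError(f"sex_specific_rr references unknown sex {sex!r}")
                if mult < 0:
                    raise ValueError(f"sex_specific_rr multiplier must be >= 0, got {mult}")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError(f"duplicate_fraction must lie in [0, 1), got {self.duplicate_fraction}")
        if self.tto_shape <= 0:
            raise ValueError(f"tto_shape must be positive, got {self.tto_shape}")
        if self.tto_scale <= 0:
            raise ValueError(f"tto_scale must be positive, got {self.tto_scale}")
        for name in ("event_date_completeness", "start_date_completeness",
                     "negative_tto_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        _parse_quarter(self.start_quarter)  # raises naming start_quarter


@dataclass
class GroundTruth:
    """The generator's ledger: what a correct analysis should recover."""

    focal_drug: str
    n_report_versions: int
    n_cases: int
    n_duplicated_cases: int
    kept_primaryids: tuple[str, ...]
    planted_rr: dict[tuple[str, str], float]
    sex_specific_rr: dict[tuple[str, str, str], float]
    tto_shape: float
    tto_scale: float
    event_date_completeness: float
    sex_mix: dict[str, float]


# ---------------------------------------------------------------------------
# Quarters and dates
# ---------------------------------------------------------------------------

def _parse_quarter(label: str) -> tuple[int, int]:
    try:
        year, q = label.upper().split("Q")
        year_i, q_i = int(year), int(q)
        if not 1 <= q_i <= 4:
            raise ValueError
        return year_i, q_i
    except (ValueError, AttributeError):
        raise ValueError(f"start_quarter must look like '2022Q2', got {label!r}") from None


def quarter_sequence(start: str, n: int) -> list[tuple[str, dt.date, dt.date]]:
    """n quarter (label, first day, last day) triples starting at ``start``."""
    year, q = _parse_quarter(start)
    out = []
    for _ in range(n):
        first = dt.date(year, 3 * (q - 1) + 1, 1)
        if q == 4:
            nxt = dt.date(year + 1, 1, 1)
        else:
            nxt = dt.date(year, 3 * q + 1, 1)
        out.append((f"{year}Q{q}", first, nxt - dt.timedelta(days=1)))
        year, q = (year + 1, 1) if q == 4 else (year, q + 1)
    return out


def _fmt(d: dt.date) -> str:
    return d.strftime("%Y%m%d")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _pt_weight_vector(cfg: GeneratorConfig, drug: str, sex: str) -> np.ndarray:
    pts = [pt for pt, _ in cfg.pt_vocab]
    if isinstance(cfg.background_rate, Mapping):
        w = np.array([cfg.background_rate[pt] for pt in pts], dtype=float)
    else:
        w = np.full(len(pts), float(cfg.background_rate))
    for i, pt in enumerate(pts):
        w[i] *= cfg.planted_rr.get((drug, pt), 1.0)
        if cfg.sex_specific_rr:
            w[i] *= cfg.sex_specific_rr.get((drug, pt, sex), 1.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("PT weight vector sums to zero; check background_rate/planted_rr")
    return w / total


def generate_database(config: GeneratorConfig, out_dir: str | Path) -> GroundTruth:
    """Emit DEMO/DRUG/REAC/THER/INDI/OUTC files per quarter plus a
    ground-truth ledger and a PT→SOC mapping table.

    Each duplicated case appears under the same CASEID with distinct
    PRIMARYIDs and FDA_DTs (the later version is the one the dedup rule
    must keep).  Exactly one drug row per report carries the PS role;
    further rows, when present, are concomitant.  Identical configurations
    and seeds reproduce the output byte for byte.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    quarters = quarter_sequence(config.start_quarter, config.n_quarters)
    nq = len(quarters)
    pts = [pt for pt, _ in config.pt_vocab]
    n_pts = len(pts)
    drugs = list(config.drug_vocab)
    sex_labels = ("F", "M", "unknown")
    sex_probs = np.array([config.sex_mix[s] for s in sex_labels])
    sex_cum = np.cumsum(sex_probs)
    out_weights = np.array(_OUTCOME_WEIGHTS)
    p_any_outcome = out_weights.sum()
    out_cum = np.cumsum(out_weights / p_any_outcome)
    indi_names = [n for n, _ in DEFAULT_INDICATIONS]
    indi_cum = np.cumsum([w for _, w in DEFAULT_INDICATIONS])

    weight_cache: dict[tuple[str, str], np.ndarray] = {}

    def pvec(drug: str, sex: str) -> np.ndarray:
        key = (drug, sex)
        if key not in weight_cache:
            weight_cache[key] = _pt_weight_vector(config, drug, sex)
        return weight_cache[key]

    rows: dict[tuple[str, str], list[dict]] = {}

    def add(kind: str, qlabel: str, rec: dict) -> None:
        rows.setdefault((kind, qlabel), []).append(rec)

    kept: list[str] = []
    n_dup_cases = 0
    emitted = 0
    case_idx = 0
    while emitted < config.n_reports:
        caseid = str(10_000_000 + case_idx)
        case_idx += 1
        can_dup = config.n_reports - emitted >= 2
        nv = 2 if (can_dup and rng.random() < config.duplicate_fraction) else 1
        if nv == 2:
            n_dup_cases += 1

        # -- demographics ---------------------------------------------------
        u = rng.random()
        sex = sex_labels[int(np.searchsorted(sex_cum, u))]
        age = ""
        age_cod = ""
        if rng.random() < 0.527:
            age = str(int(np.clip(round(rng.normal(50.0, 15.0)), 12, 90)))
            age_cod = "YR"
        wt = ""
        wt_cod = ""
        if rng.random() < 0.019:
            kg = float(np.clip(rng.normal(105.0, 25.0), 40.0, 200.0))
            if rng.random() < 0.3:
                wt, wt_cod = f"{kg / 0.45359237:.1f}", "LBS"
            else:
                wt, wt_cod = f"{kg:.1f}", "KG"
        country = "US" if rng.random() < 0.989 else ["JP", "AE", "CA", "GB"][int(rng.integers(4))]
        r = rng.random()
        occp = "CN" if r < 0.939 else ("MD" if r < 0.999 else "")
        outcome = ""
        if rng.random() < p_any_outcome:
            outcome = _OUTCOME_CODES[int(np.searchsorted(out_cum, rng.random()))]

        # -- drugs ----------------------------------------------------------
        ps_idx = int(rng.integers(len(drugs)))
        ps_drug = drugs[ps_idx]
        if ps_drug == config.focal_drug:
            ps_name = config.focal_aliases[int(rng.integers(len(config.focal_aliases)))]
        else:
            ps_name = ps_drug
        n_con = min(int(rng.poisson(0.7)), 3)
        con_names = [drugs[int(rng.integers(len(drugs)))] for _ in range(n_con)]

        # -- reactions ------------------------------------------------------
        k = 0
        while k == 0:
            k = int(rng.poisson(2.0))
        k = min(k, n_pts)
        pt_idx = rng.choice(n_pts, size=k, replace=False, p=pvec(ps_drug, sex))
        case_pts = [pts[i] for i in sorted(pt_idx)]

        indication = indi_names[int(np.searchsorted(indi_cum, rng.random()))]

        # -- dates ----------------------------------------------------------
        q1 = int(rng.integers(nq))
        label1, first1, last1 = quarters[q1]
        fda1 = first1 + dt.timedelta(days=int(rng.integers((last1 - first1).days + 1)))
        if nv == 2:
            q2 = int(rng.integers(q1, nq))
            label2, first2, last2 = quarters[q2]
            fda2 = first2 + dt.timedelta(days=int(rng.integers((last2 - first2).days + 1)))
            if q2 == q1 and fda2 < fda1:
                fda1, fda2 = fda2, fda1
        delay = int(round(config.tto_scale * rng.weibull(config.tto_shape)))
        event_date = fda1 - dt.timedelta(days=int(rng.integers(30)))
        start_date = event_date - dt.timedelta(days=delay)
        if rng.random() < config.negative_tto_fraction:
            start_date, event_date = event_date, start_date
        u = rng.random()
        if u < config.event_date_completeness:
            event_str = _fmt(event_date)
        else:
            v = rng.random()
            if v < 0.5:
                event_str = ""
            elif v < 0.75:
                event_str = event_date.strftime("%Y%m")
            else:
                event_str = event_date.strftime("%Y")
        start_str = _fmt(start_date) if rng.random() < config.start_date_completeness else ""

        # -- emit versions --------------------------------------------------
        versions = [(1, quarters[q1][0], fda1)]
        if nv == 2:
            versions.append((2, quarters[q2][0], fda2))
        kept.append(caseid + str(versions[-1][0]))
        for ver, qlabel, fda in versions:
            pid = caseid + str(ver)
            add("DEMO", qlabel, {
                "primaryid": pid, "caseid": caseid, "caseversion": str(ver),
                "fda_dt": _fmt(fda), "event_dt": event_str, "sex": sex if sex != "unknown" else "",
                "age": age, "age_cod": age_cod, "wt": wt, "wt_cod": wt_cod,
                "occr_country": country, "occp_cod": occp,
            })
            add("DRUG", qlabel, {"primaryid": pid, "caseid": caseid, "drug_seq": "1",
                                 "role_cod": "PS", "drugname": ps_name})
            for j, cname in enumerate(con_names, start=2):
                add("DRUG", qlabel, {"primaryid": pid, "caseid": caseid,
                                     "drug_seq": str(j), "role_cod": "C", "drugname": cname})
            for pt in case_pts:
                add("REAC", qlabel, {"primaryid": pid, "caseid": caseid, "pt": pt})
            add("THER", qlabel, {"primaryid": pid, "caseid": caseid,
                                 "dsg_drug_seq": "1", "start_dt": start_str})
            add("INDI", qlabel, {"primaryid": pid, "caseid": caseid,
                                 "indi_drug_seq": "1", "indi_pt": indication})
            if outcome:
                add("OUTC", qlabel, {"primaryid": pid, "caseid": caseid, "outc_cod": outcome})
        emitted += nv

    columns = {"DEMO": _DEMO_COLUMNS, "DRUG": _DRUG_COLUMNS, "REAC": _REAC_COLUMNS,
               "THER": _THER_COLUMNS, "INDI": _INDI_COLUMNS, "OUTC": _OUTC_COLUMNS}
    for qlabel, _, _ in quarters:
        for kind, cols in columns.items():
            faers_io.write_table(out_dir / f"{kind}{qlabel}.txt", cols,
                                 rows.get((kind, qlabel), []))

    with (out_dir / "pt_soc_map.txt").open("w", encoding="utf-8") as fh:
        fh.write("pt$soc\n")
        for pt, soc in config.pt_vocab:
            fh.write(f"{pt}${soc}\n")

    gt = GroundTruth(
        focal_drug=config.focal_drug,
        n_report_versions=emitted,
        n_cases=case_idx,
        n_duplicated_cases=n_dup_cases,
        kept_primaryids=tuple(kept),
        planted_rr=dict(config.planted_rr),
        sex_specific_rr=dict(config.sex_specific_rr or {}),
        tto_shape=config.tto_shape,
        tto_scale=config.tto_scale,
        event_date_completeness=config.event_date_completeness,
        sex_mix=dict(config.sex_mix),
    )
    write_ground_truth(gt, out_dir / "ground_truth.txt")
    return gt


# ---------------------------------------------------------------------------
# Ledger serialisation
# ---------------------------------------------------------------------------
#
# Plain key=value lines; repeatable keys:
#   planted_rr=DRUG|PT|RR          sex_specific_rr=DRUG|PT|SEX|MULT
#   kept=PRIMARYID                 sex_mix=SEX:PROB,SEX:PROB,...

def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    lines = [
        "schema=faerspv-ground-truth-1",
        f"focal_drug={gt.focal_drug}",
        f"n_report_versions={gt.n_report_versions}",
        f"n_cases={gt.n_cases}",
        f"n_duplicated_cases={gt.n_duplicated_cases}",
        f"tto_shape={gt.tto_shape!r}",
        f"tto_scale={gt.tto_scale!r}",
        f"event_date_completeness={gt.event_date_completeness!r}",
        "sex_mix=" + ",".join(f"{s}:{p!r}" for s, p in sorted(gt.sex_mix.items())),
    ]
    for (drug, pt), rr in sorted(gt.planted_rr.items()):
        lines.append(f"planted_rr={drug}|{pt}|{rr!r}")
    for (drug, pt, sex), m in sorted(gt.sex_specific_rr.items()):
        lines.append(f"sex_specific_rr={drug}|{pt}|{sex}|{m!r}")
    for pid in gt.kept_primaryids:
        lines.append(f"kept={pid}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_ground_truth(path: str | Path) -> GroundTruth:
    kept: list[str] = []
    planted: dict[tuple[str, str], float] = {}
    sexrr: dict[tuple[str, str, str], float] = {}
    scalars: dict[str, str] = {}
    sex_mix: dict[str, float] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        if key == "kept":
            kept.append(val)
        elif key == "planted_rr":
            drug, pt, rr = val.split("|")
            planted[(drug, pt)] = float(rr)
        elif key == "sex_specific_rr":
            drug, pt, sex, m = val.split("|")
            sexrr[(drug, pt, sex)] = float(m)
        elif key == "sex_mix":
            for part in val.split(","):
                s, _, p = part.partition(":")
                sex_mix[s] = float(p)
        else:
            scalars[key] = val
    if scalars.get("schema") != "faerspv-ground-truth-1":
        raise ValueError(f"{path}: unrecognised ground-truth schema")
    return GroundTruth(
        focal_drug=scalars["focal_drug"],
        n_report_versions=int(scalars["n_report_versions"]),
        n_cases=int(scalars["n_cases"]),
        n_duplicated_cases=int(scalars["n_duplicated_cases"]),
        kept_primaryids=tuple(kept),
        planted_rr=planted,
        sex_specific_rr=sexrr,
        tto_shape=float(scalars["tto_shape"]),
        tto_scale=float(scalars["tto_scale"]),
        event_date_completeness=float(scalars["event_date_completeness"]),
        sex_mix=sex_mix,
    )


# ---------------------------------------------------------------------------
# Empirical verification helper
# ---------------------------------------------------------------------------

def realized_rate_ratio(pairs, pt: str) -> float:
    """Empirical case-level reporting-rate ratio for one PT:
    P(PT | focal case) / P(PT | other case), counted over a pair universe.

    Because planting rescales and renormalises the PT weights, the realised
    ratio sits somewhat below the nominal multiplier; this helper is how
    tests verify what was actually planted.
    """
    focal_cases: set[str] = set()
    other_cases: set[str] = set()
    focal_hit: set[str] = set()
    other_hit: set[str] = set()
    for p in pairs:
        (focal_cases if p.drug_is_focal_ps else other_cases).add(p.caseid)
        if p.pt == pt:
            (focal_hit if p.drug_is_focal_ps else other_hit).add(p.caseid)
    if not focal_cases or not other_cases or not other_hit:
        raise ValueError("rate ratio undefined: empty stratum or zero background rate")
    return (len(focal_hit) / len(focal_cases)) / (len(other_hit) / len(other_cases))
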