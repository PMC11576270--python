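"""Readers and writers for FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System (FAERS) distributes each quarter as a
set of ``$``-delimited text tables with a single header row: demographics
(DEMO), drugs (DRUG), reactions (REAC), therapy dates (THER), indications
(INDI), outcomes (OUTC) and report sources (RPSR, read-tolerated but unused
downstream).  This module parses that dialect into light-weight record types
and normalises the field conventions that matter for analysis: flexible
dates of varying precision, sex codes, age and weight units, drug role codes
and outcome codes.

The dialect has no quoting mechanism; an embedded ``$`` inside a free-text
field is not representable and is not supported.  Lines whose field count
does not match the header are counted as malformed and logged, never
silently dropped without trace.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: Columns that must be present (lower-cased) for each table kind.
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid"),
    "DRUG": ("primaryid", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
    "THER": ("primaryid", "start_dt"),
    "INDI": ("primaryid", "indi_pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "RPSR": ("primaryid",),
}

TABLE_KINDS = tuple(MANDATORY_COLUMNS)

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: Serious-outcome codes (OUTC table) and their descriptive labels.
OUTCOME_LABELS = {
    "HO": "Hospitalization-initial or prolonged",
    "LT": "Life-threatening",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "DE": "Death",
    "OT": "Other serious outcome",
    "RI": "Required intervention",
}

_HEALTH_PROFESSIONAL_CODES = {"MD", "PH", "OT", "RN", "HP"}
_CONSUMER_CODES = {"CN"}

_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WEIGHT_UNIT_TO_KG = {"KG": 1.0, "LBS": 0.45359237, "GMS": 0.001}


# ---------------------------------------------------------------------------
# Flexible dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlexDate:
    """A FAERS date of day, month, year or unknown precision.

    FAERS date fields hold 8-digit (YYYYMMDD), 6-digit (YYYYMM) or 4-digit
    (YYYY) strings, or are empty.  Only exact (8-digit, valid calendar)
    dates are usable for time-to-onset arithmetic; partial dates exist so
    that exclusion rules can distinguish "imprecise" from "absent".
    """

    raw: str
    kind: str  # "exact" | "partial" | "missing"
    date: dt.date | None = None

    @property
    def is_exact(self) -> bool:
        return self.kind == "exact"

    @property
    def is_partial(self) -> bool:
        return self.kind == "partial"

    @property
    def is_missing(self) -> bool:
        return self.kind == "missing"


MISSING_DATE = FlexDate("", "missing", None)


def parse_flexible_date(raw: str | None) -> FlexDate:
    """Classify a raw FAERS date string as exact, partial or missing.

    8-digit strings that form a valid calendar date parse as exact;
    4-digit (year) and 6-digit (year-month, month 01-12) strings parse as
    partial; everything else — including impossible calendar dates — is
    missing.  Total function: never raises.
    """
    s = (raw or "").strip()
    if not s or not s.isdigit():
        return FlexDate(s, "missing") if s else MISSING_DATE
    if len(s) == 8:
        try:
            return FlexDate(s, "exact", dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])))
        except ValueError:
            return FlexDate(s, "missing")
    if len(s) == 6:
        if 1 <= int(s[4:6]) <= 12:
            return FlexDate(s, "partial")
        return FlexDate(s, "missing")
    if len(s) == 4:
        return FlexDate(s, "partial")
    return FlexDate(s, "missing")


# ---------------------------------------------------------------------------
# Raw table reading / writing
# ---------------------------------------------------------------------------

@dataclass
class ParsedTable:
    """One parsed ASCII table: raw string records plus a malformed-line tally."""

    kind: str
    columns: list[str]
    records: list[dict[str, str]]
    n_malformed: int
    path: Path | None = None


def read_table(path: str | Path, table_kind: str) -> ParsedTable:
    """Read one FAERS-dialect table.

    Parameters
    ----------
    path : file with a ``$``-delimited header line followed by data lines.
    table_kind : one of DEMO, DRUG, REAC, THER, INDI, OUTC, RPSR.

    Returns one record (a column → raw string mapping, all columns
    preserved) per well-formed data line.  Lines whose field count differs
    from the header are counted in ``n_malformed`` and logged.

    Raises ``ValueError`` if the table kind is unknown, the file is empty,
    or a mandatory column for that kind is absent from the header.
    """
    kind = table_kind.upper()
    if kind not in MANDATORY_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, expected a header row")
    columns = [c.strip().lower() for c in lines[0].split(DELIMITER)]
    for col in MANDATORY_COLUMNS[kind]:
        if col not in columns:
            raise ValueError(f"{path}: {kind} table is missing mandatory column '{col}'")
    ncol = len(columns)
    records: list[dict[str, str]] = []
    n_malformed = 0
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(DELIMITER)
        if len(fields) != ncol:
            n_malformed += 1
            logger.warning("%s:%d: malformed line (%d fields, expected %d)",
                           path, lineno, len(fields), ncol)
            continue
        records.append(dict(zip(columns, fields)))
    return ParsedTable(kind, columns, records, n_malformed, path)


def write_table(path: str | Path, columns: Iterable[str], records: Iterable[Mapping[str, object]]) -> None:
    """Write records in the FAERS ASCII dialect (``$``-delimited, header row)."""
    columns = list(columns)
    lines = [DELIMITER.join(columns)]
    for rec in records:
        vals = []
        for c in columns:
            v = rec.get(c, "")
            vals.append("" if v is None else str(v))
        lines.append(DELIMITER.join(vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Typed records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemoRecord:
    """One demographic row: a single version of a safety report."""

    primaryid: str
    caseid: str
    fda_dt: FlexDate
    event_dt: FlexDate
    sex: str                      # "F" | "M" | "unknown"
    age_years: float | None
    weight_kg: float | None
    country: str
    reporter: str                 # "health professional" | "consumer" | "unknown"
    outcome_codes: frozenset[str]
    extras: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DrugRecord:
    """One drug row, with therapy start and indication joined on."""

    primaryid: str
    drug_seq: str
    drug_name: str
    role_code: str
    start_dt: FlexDate
    indication: str | None


@dataclass(frozen=True)
class ReacRecord:
    """One reaction row: a MedDRA preferred term reported for a case version."""

    primaryid: str
    pt: str


def _parse_number(raw: str | None) -> float | None:
    try:
        return float((raw or "").strip())
    except ValueError:
        return None


def demo_records(parsed: ParsedTable, outc: ParsedTable | None = None) -> list[DemoRecord]:
    """Convert a parsed DEMO table to typed records, joining OUTC codes by primaryid.

    Sex values outside {F, M} map to "unknown"; age is normalised to years
    via the unit code (unparseable → missing); weight to kilograms.  Rows
    with an empty primaryid or caseid violate the key invariant and are
    skipped with a warning.
    """
    outcomes: dict[str, set[str]] = {}
    if outc is not None:
        for r in outc.records:
            code = (r.get("outc_cod") or "").strip().upper()
            if code:
                outcomes.setdefault(r["primaryid"].strip(), set()).add(code)
    out: list[DemoRecord] = []
    for r in parsed.records:
        pid = (r.get("primaryid") or "").strip()
        cid = (r.get("caseid") or "").strip()
        if not pid or not cid:
            logger.warning("DEMO row with empty primaryid/caseid skipped: %r", r)
            continue
        sex_raw = ((r.get("sex") or r.get("gndr_cod") or "")).strip().upper()
        sex = sex_raw if sex_raw in ("F", "M") else "unknown"
        age = _parse_number(r.get("age"))
        if age is not None:
            unit = (r.get("age_cod") or "YR").strip().upper() or "YR"
            factor = _AGE_UNIT_TO_YEARS.get(unit)
            age = age * factor if factor is not None else None
        wt = _parse_number(r.get("wt"))
        if wt is not None:
            unit = (r.get("wt_cod") or "KG").strip().upper() or "KG"
            factor = _WEIGHT_UNIT_TO_KG.get(unit)
            wt = wt * factor if factor is not None else None
        occp = (r.get("occp_cod") or "").strip().upper()
        if occp in _HEALTH_PROFESSIONAL_CODES:
            reporter = "health professional"
        elif occp in _CONSUMER_CODES:
            reporter = "consumer"
        else:
            reporter = "unknown"
        out.append(DemoRecord(
            primaryid=pid,
            caseid=cid,
            fda_dt=parse_flexible_date(r.get("fda_dt")),
            event_dt=parse_flexible_date(r.get("event_dt")),
            sex=sex,
            age_years=age,
            weight_kg=wt,
            country=(r.get("occr_country") or r.get("reporter_country") or "").strip(),
            reporter=reporter,
            outcome_codes=frozenset(outcomes.get(pid, ())),
            extras={k: v for k, v in r.items()},
        ))
    return out


def drug_records(drug: ParsedTable,
                 ther: ParsedTable | None = None,
                 indi: ParsedTable | None = None) -> list[DrugRecord]:
    """Convert a parsed DRUG table to typed records, joining THER start dates
    and INDI indications.

    The join is by (primaryid, drug sequence number) when the sequence
    columns are present on both sides, falling back to primaryid with
    first-row-wins when they are not — the minimal deterministic rule.
    """
    starts: dict[tuple[str, str], FlexDate] = {}
    starts_by_pid: dict[str, FlexDate] = {}
    starts_seq_pids: set[str] = set()
    if ther is not None:
        for r in ther.records:
            pid = r["primaryid"].strip()
            seq = (r.get("dsg_drug_seq") or "").strip()
            fd = parse_flexible_date(r.get("start_dt"))
            if seq:
                starts.setdefault((pid, seq), fd)
                starts_seq_pids.add(pid)
            starts_by_pid.setdefault(pid, fd)
    indications: dict[tuple[str, str], str] = {}
    indications_by_pid: dict[str, str] = {}
    indi_seq_pids: set[str] = set()
    if indi is not None:
        for r in indi.records:
            pid = r["primaryid"].strip()
            seq = (r.get("indi_drug_seq") or "").strip()
            ind = (r.get("indi_pt") or "").strip()
            if not ind:
                continue
            if seq:
                indications.setdefault((pid, seq), ind)
                indi_seq_pids.add(pid)
            indications_by_pid.setdefault(pid, ind)
    out: list[DrugRecord] = []
    for r in drug.records:
        pid = (r.get("primaryid") or "").strip()
        name = (r.get("drugname") or "").strip()
        if not pid:
            continue
        seq = (r.get("drug_seq") or "").strip()
        # Sequence-level join when sequence numbers exist on both sides;
        # primaryid-level first-row-wins only when they do not.
        start = starts.get((pid, seq))
        if start is None and not (seq and pid in starts_seq_pids):
            start = starts_by_pid.get(pid)
        if start is None:
            start = MISSING_DATE
        ind = indications.get((pid, seq))
        if ind is None and not (seq and pid in indi_seq_pids):
            ind = indications_by_pid.get(pid)
        role = (r.get("role_cod") or "").strip().upper()
        if role not in ROLE_CODES:
            logger.warning("DRUG row %s has unrecognised role code %r", pid, role)
        out.append(DrugRecord(pid, seq, name, role, start, ind))
    return out


def reac_records(parsed: ParsedTable) -> list[ReacRecord]:
    """Convert a parsed REAC table to typed records (empty PTs skipped)."""
    out: list[ReacRecord] = []
    for r in parsed.records:
        pid = (r.get("primaryid") or "").strip()
        pt = (r.get("pt") or "").strip()
        if pid and pt:
            out.append(ReacRecord(pid, pt))
    return out
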