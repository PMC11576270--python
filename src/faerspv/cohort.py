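"""Case deduplication, focal-drug cohort selection and PT→SOC attachment.

FAERS republishes case versions across quarters, so the same CASEID appears
under several PRIMARYIDs.  The FDA-recommended resolution rule is applied
here: per CASEID keep the version with the most recent FDA_DT, breaking
ties by the higher PRIMARYID.  The cohort is then the set of deduplicated
cases carrying at least one primary-suspect (PS) row for the focal drug,
and the analysis unit downstream is the distinct (case, preferred term)
pair.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .faers_io import DemoRecord, DrugRecord, FlexDate, MISSING_DATE, ReacRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

@dataclass
class DedupResult:
    """Kept report versions plus an audit trail of the resolution."""

    kept_primaryids: frozenset[str]
    kept_by_caseid: dict[str, str]
    n_versions: int

    @property
    def n_cases(self) -> int:
        return len(self.kept_by_caseid)

    @property
    def n_dropped(self) -> int:
        return self.n_versions - self.n_cases


def _primaryid_key(pid: str) -> tuple[int, int, str]:
    # Numeric ids compare numerically and sort above non-numeric ones;
    # non-numeric ids fall back to lexicographic order so the rule is total.
    if pid.isdigit():
        return (1, int(pid), pid)
    return (0, 0, pid)


def _version_key(rec: DemoRecord) -> tuple:
    d = rec.fda_dt.date if rec.fda_dt.is_exact else None
    return (1 if d is not None else 0, d or dt.date.min, _primaryid_key(rec.primaryid))


def deduplicate(demo: Iterable[DemoRecord]) -> DedupResult:
    """Resolve case versions: one kept PRIMARYID per CASEID.

    Within a CASEID the version with the latest exact FDA_DT wins; ties on
    FDA_DT go to the (numerically) higher PRIMARYID; versions with a
    missing FDA_DT lose to any dated version.  Deterministic, idempotent
    and invariant to input order.
    """
    best: dict[str, DemoRecord] = {}
    n = 0
    for rec in demo:
        n += 1
        cur = best.get(rec.caseid)
        if cur is None or _version_key(rec) > _version_key(cur):
            best[rec.caseid] = rec
    kept = {cid: r.primaryid for cid, r in best.items()}
    return DedupResult(frozenset(kept.values()), kept, n)


# ---------------------------------------------------------------------------
# Drug-name matching
# ---------------------------------------------------------------------------

def _normalize_name(s: str) -> str:
    return " ".join(s.upper().split())


def match_focal_drug(drug_name: str, name_list: Iterable[str], mode: str = "substring") -> bool:
    """Does a verbatim drug-name string refer to the focal drug?

    FAERS has no uniform drug coding, so reports are found by name: the
    generic name plus brand names.  Names are upper-cased, trimmed and
    whitespace-collapsed; in the default "substring" mode a list entry
    matches anywhere in the verbatim string at word boundaries (so
    "MOUNJARO 5MG/0.5ML PEN" matches "MOUNJARO"), while "exact" mode
    requires full equality.
    """
    entries = [_normalize_name(e) for e in name_list]
    if not entries:
        raise ValueError("name_list must be non-empty")
    name = _normalize_name(drug_name)
    if mode == "exact":
        return name in entries
    if mode != "substring":
        raise ValueError(f"unknown match mode {mode!r}; expected 'substring' or 'exact'")
    return any(
        re.search(rf"(?<![A-Z0-9]){re.escape(e)}(?![A-Z0-9])", name) is not None
        for e in entries
    )


# ---------------------------------------------------------------------------
# PT → SOC mapping
# ---------------------------------------------------------------------------

def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (PT, SOC) mapping table.

    The licensed MedDRA dictionary cannot be redistributed, so the mapping
    is a user input: two columns delimited by ``$`` or tab, optional header
    ("pt"/"soc").  PTs are normalised to upper case; a PT listed under
    several SOCs keeps the first listing, with a warning.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        sep = "$" if "$" in line else "\t"
        parts = line.split(sep)
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two delimited columns (PT, SOC)")
        pt, soc = parts[0].strip().upper(), parts[1].strip()
        if lineno == 1 and pt in ("PT", "PREFERRED TERM"):
            continue
        if pt in mapping and mapping[pt] != soc:
            logger.warning("%s:%d: PT %r maps to multiple SOCs; keeping first (%r)",
                           path, lineno, pt, mapping[pt])
            continue
        mapping[pt] = soc
    return mapping


# ---------------------------------------------------------------------------
# Case–PT pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CasePtPair:
    """One distinct (deduplicated case, preferred term) pair — the counting
    unit of the disproportionality analysis."""

    primaryid: str
    caseid: str
    drug_is_focal_ps: bool
    pt: str
    soc: str | None
    sex: str
    event_dt: FlexDate
    start_dt: FlexDate


def build_case_pt_pairs(demo: Sequence[DemoRecord],
                        drugs: Sequence[DrugRecord],
                        reacs: Sequence[ReacRecord],
                        kept_primaryids: Iterable[str],
                        focal_names: Iterable[str],
                        pt_soc_map: Mapping[str, str] | None = None,
                        role_filter: Iterable[str] = ("PS",),
                        focal_only: bool = True,
                        match_mode: str = "substring") -> list[CasePtPair]:
    """Build distinct (case, PT) pairs over the deduplicated database.

    A case is *focal* when it has at least one drug row whose role code is
    in ``role_filter`` (default: primary suspect only) and whose verbatim
    name matches the focal-drug name list.  PTs are deduplicated within a
    case; the SOC is attached from the mapping (unmapped PTs are retained
    with ``soc=None`` and flagged in the log).  With ``focal_only=False``
    the full pair universe — cohort plus background — is returned, which is
    what the 2×2 contingency tables are built from.

    The per-case therapy start date is the earliest *exact* START_DT among
    matching focal rows (falling back to a partial date, so that the
    time-to-onset exclusion tally can distinguish imprecise from absent).
    """
    kept = set(kept_primaryids)
    focal_list = list(focal_names)
    demo_by_pid = {r.primaryid: r for r in demo if r.primaryid in kept}
    roleset = {r.upper() for r in role_filter}

    focal_flag: dict[str, bool] = {}
    focal_start: dict[str, FlexDate] = {}
    for d in drugs:
        if d.primaryid not in demo_by_pid or d.role_code not in roleset:
            continue
        if not match_focal_drug(d.drug_name, focal_list, match_mode):
            continue
        focal_flag[d.primaryid] = True
        cur = focal_start.get(d.primaryid, MISSING_DATE)
        new = d.start_dt
        if new.is_exact and (not cur.is_exact or new.date < cur.date):
            focal_start[d.primaryid] = new
        elif new.is_partial and cur.is_missing:
            focal_start[d.primaryid] = new

    pts_by_pid: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for r in reacs:
        if r.primaryid not in demo_by_pid:
            continue
        pt = r.pt.upper()
        if (r.primaryid, pt) in seen:
            continue
        seen.add((r.primaryid, pt))
        pts_by_pid.setdefault(r.primaryid, []).append(pt)

    pairs: list[CasePtPair] = []
    n_unmapped = 0
    for pid, rec in demo_by_pid.items():
        is_focal = focal_flag.get(pid, False)
        if focal_only and not is_focal:
            continue
        start = focal_start.get(pid, MISSING_DATE)
        for pt in pts_by_pid.get(pid, ()):
            soc = pt_soc_map.get(pt) if pt_soc_map else None
            if pt_soc_map is not None and soc is None:
                n_unmapped += 1
            pairs.append(CasePtPair(pid, rec.caseid, is_focal, pt, soc,
                                    rec.sex, rec.event_dt, start))
    if n_unmapped:
        logger.warning("%d (case, PT) pairs had no SOC mapping; retained with soc=None",
                       n_unmapped)
    if focal_only and not pairs:
        logger.warning("focal-drug cohort is empty for name list %r", focal_list)
    return pairs
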