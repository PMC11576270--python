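"""Disproportionality statistics over 2×2 contingency tables.

For a drug–event pair the (case, event)-pair universe is partitioned into

=========  ===============  ================
            target event     other events
=========  ===============  ================
focal drug        a                b
other drugs       c                d
=========  ===============  ================

and four classical pharmacovigilance statistics are computed:

* **ROR** — reporting odds ratio ``ad/bc`` with a lognormal 95% CI,
* **PRR** — proportional reporting ratio ``(a/(a+b))/(c/(c+d))`` with the
  Pearson χ² statistic (no continuity correction),
* **BCPNN IC** — information component ``log2(aN/((a+b)(a+c)))`` plus the
  closed-form Bayesian expectation/variance (Bate et al. 1998) from which
  the shrunk lower bound IC025 is taken,
* **EBGM** — the simplified empirical-Bayes geometric mean
  ``aN/((a+b)(a+c))`` with a lognormal 95% CI.

Note that the simplified EBGM shares its core ratio with the raw IC, so
``EBGM = 2**IC`` identically.  A pair is a *signal* when all four criteria
hold simultaneously (ROR CI low > 1 with N ≥ 3; PRR ≥ 2 with χ² ≥ 4 and
N ≥ 3; IC025 > 0; EBGM05 > 2), optionally tightened by a Bonferroni
correction of the χ² p-value over the family of tested events.

Zero cells: point estimates are reported on the uncorrected cells whenever
defined; confidence intervals fall back to the Haldane–Anscombe +0.5
correction on all cells and the result carries a ``degenerate`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as sps

from .cohort import CasePtPair

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug–event counts; ``n_total = a+b+c+d``."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        """Swap rows and columns simultaneously (χ² is invariant under this)."""
        return ContingencyTable(self.d, self.c, self.b, self.a)


def _pair_sets(pairs: Iterable[CasePtPair], level: str):
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    focal: set[tuple[str, str]] = set()
    other: set[tuple[str, str]] = set()
    for p in pairs:
        key = p.pt if level == "PT" else p.soc
        if key is None:
            continue
        (focal if p.drug_is_focal_ps else other).add((p.caseid, key))
    return focal, other


def build_table(pairs: Iterable[CasePtPair], event: str, level: str = "PT") -> ContingencyTable:
    """Build the 2×2 table for one event at PT or SOC level.

    At SOC level an event is counted once per (case, SOC) even when several
    PTs of that SOC occur in the same case.  Raises ``ValueError`` for an
    event absent from the pair universe.
    """
    focal, other = _pair_sets(pairs, level)
    events = {k for _, k in focal} | {k for _, k in other}
    if event not in events:
        raise ValueError(f"unknown event {event!r} at level {level}")
    a = sum(1 for _, k in focal if k == event)
    c = sum(1 for _, k in other if k == event)
    return ContingencyTable(a, len(focal) - a, c, len(other) - c)


# ---------------------------------------------------------------------------
# Individual statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RorResult:
    ror: float
    ci95: tuple[float, float]
    degenerate: bool


@dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float
    p: float
    degenerate: bool


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic_e: float
    ic_v: float
    ic025: float
    degenerate: bool


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    ebgm05: float
    degenerate: bool


def _corrected(t: ContingencyTable) -> tuple[float, float, float, float]:
    return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)


def ror_with_ci(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio with lognormal 95% CI.

    ``ror = ad/bc``; ``CI = exp(ln ror ± 1.96·√(1/a+1/b+1/c+1/d))``.  With a
    zero cell the CI (and, when ``bc = 0``, the point estimate) comes from
    the +0.5-corrected cells and the result is flagged degenerate; ``a = 0``
    reports ``ror = 0``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    degenerate = min(a, b, c, d) == 0
    if b * c > 0:
        ror = (a * d) / (b * c)
    elif a == 0:
        ror = 0.0
    else:
        aa, bb, cc, dd = _corrected(t)
        ror = (aa * dd) / (bb * cc)
    aa, bb, cc, dd = _corrected(t) if degenerate else (a, b, c, d)
    center = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (center * math.exp(-_Z95 * se), center * math.exp(_Z95 * se))
    return RorResult(ror, ci, degenerate)


def prr_with_chi2(t: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio plus Pearson χ² (1 df, no continuity
    correction) and its p-value."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n_total
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0) or c == 0
    if a + b > 0 and c > 0 and c + d > 0:
        prr = (a / (a + b)) / (c / (c + d))
    else:
        prr = math.nan
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom > 0:
        chi2 = (a * d - b * c) ** 2 * n / denom
        p = float(sps.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    return PrrResult(prr, chi2, p, degenerate)


def bcpnn_ic(t: ContingencyTable) -> IcResult:
    """Information component: raw point value plus the Bate-1998 closed-form
    Bayesian expectation, variance and shrunk lower bound IC025.

    The raw IC is ``log2(aN/((a+b)(a+c)))`` and is ``-inf`` (degenerate) at
    ``a = 0``; the shrunk expectation stays finite (and negative) there,
    which is exactly the point of the Bayesian variant.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n_total
    if n == 0:
        raise ValueError("empty contingency table")
    degenerate = a == 0 or (a + b) == 0 or (a + c) == 0
    if not degenerate:
        ic = math.log2(a * n / ((a + b) * (a + c)))
    else:
        ic = -math.inf
    # Bate et al. (1998) closed-form posterior moments with the standard
    # priors alpha1 = beta1 = gamma11 = 1, alpha = beta = 2.
    a1 = b1 = g11 = 1.0
    al = be = 2.0
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    ic_e = math.log2((a + g11) * (n + al) * (n + be)
                     / ((n + gamma) * (a + b + a1) * (a + c + b1)))
    ln2sq = math.log(2) ** 2
    ic_v = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
            + (n - a - b + al - a1) / ((a + b + a1) * (1 + n + al))
            + (n - a - c + be - b1) / ((a + c + b1) * (1 + n + be))) / ln2sq
    ic025 = ic_e - 2.0 * math.sqrt(ic_v)
    return IcResult(ic, ic_e, ic_v, ic025, degenerate)


def ebgm_with_ci(t: ContingencyTable) -> EbgmResult:
    """Simplified empirical-Bayes geometric mean with lognormal lower bound.

    ``ebgm = aN/((a+b)(a+c))`` (identically ``2**IC``);
    ``ebgm05 = exp(ln ebgm − 1.96·√(1/a+1/b+1/c+1/d))``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n_total
    degenerate = min(a, b, c, d) == 0
    if (a + b) > 0 and (a + c) > 0:
        ebgm = a * n / ((a + b) * (a + c))
    else:
        ebgm = 0.0
    if degenerate:
        aa, bb, cc, dd = _corrected(t)
        nn = aa + bb + cc + dd
        center = aa * nn / ((aa + bb) * (aa + cc))
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    else:
        center = ebgm
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ebgm05 = center * math.exp(-_Z95 * se)
    return EbgmResult(ebgm, ebgm05, degenerate)


# ---------------------------------------------------------------------------
# Combined result and criteria
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    """All four algorithms' statistics and criterion flags for one pair."""

    table: ContingencyTable
    ror: float
    ror_ci95: tuple[float, float]
    prr: float
    chi2: float
    chi2_p: float
    ic: float
    ic_e: float
    ic_v: float
    ic025: float
    ebgm: float
    ebgm05: float
    n_reports: int
    degenerate: bool
    ror_sig: bool = False
    prr_sig: bool = False
    bcpnn_sig: bool = False
    mgps_sig: bool = False
    significant_all4: bool = False
    bonferroni_pass: bool | None = None


def evaluate_criteria(s: SignalResult) -> SignalResult:
    """Apply the per-algorithm signal criteria in place and return ``s``.

    ror_sig: CI low > 1 and N ≥ 3; prr_sig: PRR ≥ 2, χ² ≥ 4, N ≥ 3;
    bcpnn_sig: IC025 > 0; mgps_sig: EBGM05 > 2; significant_all4 is their
    conjunction.
    """
    n = s.n_reports
    s.ror_sig = bool(s.ror_ci95[0] > 1.0 and n >= 3)
    s.prr_sig = bool(not math.isnan(s.prr) and s.prr >= 2.0 and s.chi2 >= 4.0 and n >= 3)
    s.bcpnn_sig = bool(s.ic025 > 0.0)
    s.mgps_sig = bool(s.ebgm05 > 2.0)
    s.significant_all4 = s.ror_sig and s.prr_sig and s.bcpnn_sig and s.mgps_sig
    return s


def compute_signal(t: ContingencyTable, bonferroni_p: float | None = None) -> SignalResult:
    """Run the full four-algorithm battery on one 2×2 table.

    ``bonferroni_p`` is the corrected χ²-p threshold for the family this
    table belongs to; when given, ``bonferroni_pass = chi2_p < bonferroni_p``.
    """
    r = ror_with_ci(t)
    p = prr_with_chi2(t)
    i = bcpnn_ic(t)
    e = ebgm_with_ci(t)
    s = SignalResult(
        table=t, ror=r.ror, ror_ci95=r.ci95,
        prr=p.prr, chi2=p.chi2, chi2_p=p.p,
        ic=i.ic, ic_e=i.ic_e, ic_v=i.ic_v, ic025=i.ic025,
        ebgm=e.ebgm, ebgm05=e.ebgm05,
        n_reports=t.a,
        degenerate=r.degenerate or p.degenerate or i.degenerate or e.degenerate,
    )
    evaluate_criteria(s)
    if bonferroni_p is not None:
        s.bonferroni_pass = bool(s.chi2_p < bonferroni_p)
    return s


def bonferroni_threshold(p_nominal: float, n_tests: int) -> float:
    """Bonferroni-corrected threshold ``p_nominal / n_tests`` (n_tests ≥ 1)."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return p_nominal / n_tests


def pt_frequency(a: int, total_pairs: int) -> float:
    """Reporting frequency of one PT as a percentage of all (case, PT) pairs."""
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    if a > total_pairs:
        raise ValueError("count cannot exceed total pairs")
    return 100.0 * a / total_pairs


# ---------------------------------------------------------------------------
# Whole-database screening
# ---------------------------------------------------------------------------

def signal_table(pairs: Sequence[CasePtPair],
                 level: str = "PT",
                 p_nominal: float = 0.05,
                 min_reports: int = 3,
                 indication_exclude: Iterable[str] = ()) -> pd.DataFrame:
    """Screen every event at the chosen level and return one row per event.

    The Bonferroni family is the set of events with at least ``min_reports``
    focal reports (the χ² p-value is the only p-value the method set
    produces, so the correction applies to it).  Events named in
    ``indication_exclude`` — PTs that are plausible indications rather than
    adverse events — keep their statistics but are barred from the final
    ``signal`` column.

    Rows are sorted by report count (descending), then event name.
    """
    focal, other = _pair_sets(pairs, level)
    a_counts: dict[str, int] = {}
    c_counts: dict[str, int] = {}
    for _, k in focal:
        a_counts[k] = a_counts.get(k, 0) + 1
    for _, k in other:
        c_counts[k] = c_counts.get(k, 0) + 1
    events = sorted(set(a_counts) | set(c_counts))
    n_focal, n_other = len(focal), len(other)
    excluded = {e.upper() for e in indication_exclude}

    n_tests = sum(1 for e in events if a_counts.get(e, 0) >= min_reports)
    thresh = bonferroni_threshold(p_nominal, n_tests) if n_tests >= 1 else math.nan

    soc_of: dict[str, str | None] = {}
    if level == "PT":
        for p in pairs:
            soc_of.setdefault(p.pt, p.soc)

    rows = []
    for ev in events:
        a = a_counts.get(ev, 0)
        c = c_counts.get(ev, 0)
        t = ContingencyTable(a, n_focal - a, c, n_other - c)
        s = compute_signal(t, bonferroni_p=None if math.isnan(thresh) else thresh)
        is_excluded = ev.upper() in excluded
        rows.append({
            "event": ev,
            **({"soc": soc_of.get(ev)} if level == "PT" else {}),
            "a": a, "b": t.b, "c": c, "d": t.d,
            "ror": s.ror, "ror_lo": s.ror_ci95[0], "ror_hi": s.ror_ci95[1],
            "prr": s.prr, "chi2": s.chi2, "chi2_p": s.chi2_p,
            "ic": s.ic, "ic_e": s.ic_e, "ic025": s.ic025,
            "ebgm": s.ebgm, "ebgm05": s.ebgm05,
            "degenerate": s.degenerate,
            "ror_sig": s.ror_sig, "prr_sig": s.prr_sig,
            "bcpnn_sig": s.bcpnn_sig, "mgps_sig": s.mgps_sig,
            "significant_all4": s.significant_all4,
            "bonferroni_pass": bool(s.bonferroni_pass) if s.bonferroni_pass is not None else False,
            "indication_excluded": is_excluded,
            "signal": bool(s.significant_all4 and s.bonferroni_pass and not is_excluded),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["a", "event"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    df.attrs["n_tests"] = n_tests
    df.attrs["bonferroni_threshold"] = thresh
    df.attrs["n_focal_pairs"] = n_focal
    df.attrs["n_other_pairs"] = n_other
    return df


def significant_signals(df: pd.DataFrame) -> pd.DataFrame:
    """Significant events ranked by EBGM descending (the most stringent
    algorithm), ties broken by report count then name."""
    if df.empty:
        return df
    sig = df[df["signal"]].copy()
    return sig.sort_values(["ebgm", "a", "event"], ascending=[False, False, True],
                           kind="mergesort").reset_index(drop=True)


def fmt_est_ci(est: float, lo: float, hi: float, nd: int = 2) -> str:
    """Render "est(lo-hi)" the way signal tables conventionally print it."""
    return f"{est:.{nd}f}({lo:.{nd}f}-{hi:.{nd}f})"
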