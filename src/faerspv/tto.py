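"""Time-to-onset (TTO) analysis of adverse-event reports.

TTO is the number of days from therapy initiation (THER START_DT) to event
occurrence (DEMO EVENT_DT).  Spontaneous-report databases record these dates
at varying precision, so observations are restricted to cases where both
dates are exact calendar dates and the difference is non-negative; every
exclusion is tallied by reason.

The onset distribution is summarised three ways:

* an interval histogram (first month, 1–2 months, ... , beyond a year),
* a maximum-likelihood Weibull fit whose shape parameter β classifies the
  hazard trend — β < 1 (CI excluding 1) means the reporting hazard falls
  with time on drug ("early failure"), β > 1 a rising hazard ("wear-out"),
  a CI spanning 1 a roughly constant hazard,
* Kaplan–Meier cumulative-incidence curves by sex with a log-rank test
  (every observation is a realised event; there is no censoring in this
  design).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CasePtPair

logger = logging.getLogger(__name__)

#: Histogram bin edges in days; each bin is (lo, hi] except the first, which
#: includes day 0, so "0-30" is the first month.
TTO_BINS = ((0, 30), (30, 60), (60, 90), (90, 180), (180, 360), (360, None))
TTO_BIN_LABELS = ("0-30", "31-60", "61-90", "91-180", "181-360", ">360")


@dataclass(frozen=True)
class TtoObservation:
    """One case's onset interval in days, with the SOCs the case reported."""

    caseid: str
    days: int
    sex: str
    socs: tuple[str, ...] = ()


@dataclass(frozen=True)
class WeibullFit:
    """Weibull ML estimates with Wald CIs and hazard-trend classification."""

    shape: float                      # β
    scale: float                      # η, days
    shape_ci95: tuple[float, float]
    scale_ci95: tuple[float, float]
    n: int
    trend: str                        # "early-failure" | "random" | "wear-out"
    median: float
    q1: float
    q3: float
    min: float
    max: float

    @property
    def fitted_median(self) -> float:
        """Median of the fitted distribution, η·ln2^(1/β)."""
        return self.scale * np.log(2.0) ** (1.0 / self.shape)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_tto(pairs: Iterable[CasePtPair]) -> tuple[list[TtoObservation], Counter]:
    """Derive one TTO observation per cohort case, tallying exclusions.

    Uses each case's exact EVENT_DT and the earliest exact focal-drug
    START_DT carried on its pairs.  Exclusion reasons (first applicable
    wins): missing/partial event date, missing/partial start date, negative
    onset.  Order-invariant and idempotent: the result depends only on the
    set of cases present.
    """
    by_case: dict[str, list[CasePtPair]] = {}
    for p in pairs:
        by_case.setdefault(p.caseid, []).append(p)
    tally: Counter = Counter()
    obs: list[TtoObservation] = []
    for caseid in sorted(by_case):
        ps = by_case[caseid]
        first = ps[0]
        if first.event_dt.is_missing:
            tally["event_date_missing"] += 1
            continue
        if first.event_dt.is_partial:
            tally["event_date_partial"] += 1
            continue
        if first.start_dt.is_missing:
            tally["start_date_missing"] += 1
            continue
        if first.start_dt.is_partial:
            tally["start_date_partial"] += 1
            continue
        days = (first.event_dt.date - first.start_dt.date).days
        if days < 0:
            tally["negative_tto"] += 1
            continue
        tally["included"] += 1
        socs = tuple(sorted({p.soc for p in ps if p.soc is not None}))
        obs.append(TtoObservation(caseid, days, first.sex, socs))
    return obs, tally


# ---------------------------------------------------------------------------
# Histogram
# ---------------------------------------------------------------------------

def bin_tto(obs: Sequence[TtoObservation] | Sequence[int]) -> pd.DataFrame:
    """Histogram of onset days over the standard intervals.

    Returns columns (interval, count, percent); percentages sum to 100
    within rounding.  Empty input yields an empty frame.
    """
    days = np.asarray([o.days if isinstance(o, TtoObservation) else int(o) for o in obs])
    if days.size == 0:
        return pd.DataFrame(columns=["interval", "count", "percent"])
    counts = []
    for (lo, hi), label in zip(TTO_BINS, TTO_BIN_LABELS):
        if hi is None:
            n = int(np.sum(days > lo))
        elif lo == 0:
            n = int(np.sum((days >= 0) & (days <= hi)))
        else:
            n = int(np.sum((days > lo) & (days <= hi)))
        counts.append((label, n))
    total = days.size
    return pd.DataFrame({
        "interval": [l for l, _ in counts],
        "count": [n for _, n in counts],
        "percent": [100.0 * n / total for _, n in counts],
    })


# ---------------------------------------------------------------------------
# Weibull fit
# ---------------------------------------------------------------------------

def _weibull_nll(theta: np.ndarray, x: np.ndarray) -> float:
    k, lam = np.exp(theta)
    z = x / lam
    return -(x.size * np.log(k) - x.size * k * np.log(lam)
             + (k - 1.0) * np.sum(np.log(x)) - np.sum(z ** k))


def weibull_fit(days: Sequence[float] | np.ndarray, zero_offset: float = 0.5) -> WeibullFit:
    """Maximum-likelihood Weibull fit of onset times.

    Day-0 observations (event on the start date) are shifted to
    ``zero_offset`` days for the likelihood only, since the Weibull has
    positive support; the descriptive median/quartiles use the raw values.
    Wald 95% CIs come from the observed information on (ln β, ln η),
    computed by central finite differences at the MLE.

    Requires at least 10 observations; all-identical input is rejected.
    """
    x_raw = np.asarray(days, dtype=float)
    if x_raw.size < 10:
        raise ValueError(f"need at least 10 observations, got {x_raw.size}")
    if np.any(x_raw < 0):
        raise ValueError("onset days must be non-negative")
    if np.all(x_raw == x_raw[0]):
        raise ValueError("degenerate input: all onset values identical")
    x = np.where(x_raw == 0, zero_offset, x_raw)

    shape, _, scale = sps.weibull_min.fit(x, floc=0)
    theta = np.log([shape, scale])

    h = 1e-4
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2); ei[i] = h
            ej = np.zeros(2); ej[j] = h
            if i == j:
                hess[i, j] = (_weibull_nll(theta + ei, x) - 2 * _weibull_nll(theta, x)
                              + _weibull_nll(theta - ei, x)) / h ** 2
            else:
                hess[i, j] = (_weibull_nll(theta + ei + ej, x)
                              - _weibull_nll(theta + ei - ej, x)
                              - _weibull_nll(theta - ei + ej, x)
                              + _weibull_nll(theta - ei - ej, x)) / (4 * h ** 2)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = 1.959963984540054
    shape_ci = (float(np.exp(theta[0] - z * se[0])), float(np.exp(theta[0] + z * se[0])))
    scale_ci = (float(np.exp(theta[1] - z * se[1])), float(np.exp(theta[1] + z * se[1])))

    if shape_ci[1] < 1.0:
        trend = "early-failure"
    elif shape_ci[0] > 1.0:
        trend = "wear-out"
    else:
        trend = "random"

    q1, med, q3 = np.percentile(x_raw, [25, 50, 75])
    return WeibullFit(float(shape), float(scale), shape_ci, scale_ci,
                      int(x_raw.size), trend,
                      float(med), float(q1), float(q3),
                      float(x_raw.min()), float(x_raw.max()))


# ---------------------------------------------------------------------------
# Per-SOC summary and sex comparison
# ---------------------------------------------------------------------------

def tto_by_soc(obs: Sequence[TtoObservation]) -> pd.DataFrame:
    """Median/IQR/min/max onset per SOC (a case counts in every SOC it
    reported)."""
    rows: dict[str, list[int]] = {}
    for o in obs:
        for soc in o.socs:
            rows.setdefault(soc, []).append(o.days)
    out = []
    for soc in sorted(rows):
        v = np.asarray(rows[soc], dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out.append({"soc": soc, "n": v.size, "median": med, "q1": q1, "q3": q3,
                    "min": v.min(), "max": v.max()})
    return pd.DataFrame(out, columns=["soc", "n", "median", "q1", "q3", "min", "max"])


@dataclass
class KmResult:
    """Kaplan–Meier curves per stratum plus the log-rank comparison."""

    curves: pd.DataFrame          # columns: stratum, time, survival, cum_incidence
    statistic: float
    p_value: float


def km_by_sex(obs: Sequence[TtoObservation], strata: tuple[str, str] = ("F", "M")) -> KmResult:
    """Compare cumulative ADE incidence between two sex strata.

    All observations are realised events (no censoring), so the cumulative
    incidence is simply 1 − S(t) and S reaches 0 at the largest observed
    time.  Raises ``ValueError`` naming any empty stratum.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = {s: np.asarray([o.days for o in obs if o.sex == s], dtype=float)
              for s in strata}
    for s, v in groups.items():
        if v.size == 0:
            raise ValueError(f"stratum '{s}' has no observations")
    frames = []
    for s, v in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(v, event_observed=np.ones_like(v), label=s)
        sf = kmf.survival_function_
        frames.append(pd.DataFrame({
            "stratum": s,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf[s].to_numpy(dtype=float),
            "cum_incidence": 1.0 - sf[s].to_numpy(dtype=float),
        }))
    res = logrank_test(groups[strata[0]], groups[strata[1]],
                       event_observed_A=np.ones_like(groups[strata[0]]),
                       event_observed_B=np.ones_like(groups[strata[1]]))
    return KmResult(pd.concat(frames, ignore_index=True),
                    float(res.test_statistic), float(res.p_value))
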