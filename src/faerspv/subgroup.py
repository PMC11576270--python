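"""Sex-stratified signal detection and top-k comparison between strata.

Baseline reporting differs strongly by sex in spontaneous-report data, so
the full disproportionality battery is re-run inside each sex stratum: by
default both the focal-drug and the comparator pair universes are
restricted to the stratum, so a sex-specific reporting excess shows up only
in its own stratum.  A whole-database comparator is available behind a
flag.  The "unknown" sex stratum is not part of the two-way comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import CasePtPair
from .signal_stats import signal_table


@dataclass
class StratifiedSignalSet:
    """One stratum's full signal table plus its top-k events by report count."""

    stratum: str
    table: pd.DataFrame
    top_k: list[str]


def stratified_signals(pairs: Sequence[CasePtPair],
                       sex: str,
                       k: int = 20,
                       comparator: str = "stratum",
                       **signal_kwargs) -> StratifiedSignalSet:
    """Run the signal battery within one sex stratum.

    ``comparator="stratum"`` (default) restricts both the focal and the
    background pair universes to the stratum; ``comparator="whole"`` keeps
    the full-database background.  Top-k events are ranked by report count
    descending, ties broken by EBGM descending then event name.

    Raises ``ValueError`` when the stratum holds no focal-drug pairs.
    """
    if comparator == "stratum":
        sub = [p for p in pairs if p.sex == sex]
    elif comparator == "whole":
        sub = [p for p in pairs if p.sex == sex or not p.drug_is_focal_ps]
    else:
        raise ValueError(f"comparator must be 'stratum' or 'whole', got {comparator!r}")
    if not any(p.drug_is_focal_ps for p in sub):
        raise ValueError(f"stratum '{sex}' contains no focal-drug cases")
    df = signal_table(sub, **signal_kwargs)
    ranked = df[df["a"] > 0].sort_values(
        ["a", "ebgm", "event"], ascending=[False, False, True], kind="mergesort")
    return StratifiedSignalSet(sex, df, ranked["event"].head(k).tolist())


@dataclass
class TopKComparison:
    """Set algebra over two strata's top-k lists plus a side-by-side rank table."""

    shared: list[str]
    a_only: list[str]
    b_only: list[str]
    rank_table: pd.DataFrame      # columns: event, rank_<A>, rank_<B>


def compare_top_k(set_a: StratifiedSignalSet,
                  set_b: StratifiedSignalSet,
                  k: int = 20) -> TopKComparison:
    """Intersect and difference the two strata's top-k lists.

    Symmetric up to label swap.  Ranks in the table are 1-based positions
    within each stratum's list (absent → <NA>).
    """
    top_a, top_b = set_a.top_k[:k], set_b.top_k[:k]
    sa, sb = set(top_a), set(top_b)
    rank_a = {e: i + 1 for i, e in enumerate(top_a)}
    rank_b = {e: i + 1 for i, e in enumerate(top_b)}
    events = sorted(sa | sb, key=lambda e: (min(rank_a.get(e, k + 1), rank_b.get(e, k + 1)), e))
    table = pd.DataFrame({
        "event": events,
        f"rank_{set_a.stratum}": pd.array([rank_a.get(e) for e in events], dtype="Int64"),
        f"rank_{set_b.stratum}": pd.array([rank_b.get(e) for e in events], dtype="Int64"),
    })
    return TopKComparison(sorted(sa & sb), sorted(sa - sb), sorted(sb - sa), table)
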