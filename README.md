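# faerspv

Pharmacovigilance signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports.

The FDA Adverse Event Reporting System (FAERS) publishes quarterly
`$`-delimited tables of self-reported adverse drug events (ADEs). Mining it
for a drug's safety profile means answering: *which events are reported
disproportionately often with this drug, how soon after starting therapy do
they occur, and do they differ between men and women?* This package
implements that full workflow as a tested, reusable library for
pharmacoepidemiologists and biostatisticians:

* **Ingestion** of the FAERS ASCII dialect (DEMO, DRUG, REAC, THER, INDI,
  OUTC), with flexible-precision date parsing and unit normalisation.
* **Deduplication** by the FDA-recommended rule: per CASEID keep the latest
  FDA_DT, ties broken by the higher PRIMARYID.
* **Cohorting** by drug name (generic + brands, word-boundary matching),
  restricted to primary-suspect (PS) role codes; events are MedDRA
  preferred terms (PTs) grouped into system organ classes (SOCs) via a
  user-supplied two-column mapping.
* **Disproportionality analysis** on the 2×2 table (a, b, c, d) of
  (case, event) pairs, with four algorithms and their standard criteria:

  | method | statistic | signal criterion |
  |---|---|---|
  | ROR   | ad/bc, lognormal 95% CI | CI lower bound > 1, N ≥ 3 |
  | PRR   | (a/(a+b))/(c/(c+d)), Pearson χ² | PRR ≥ 2, χ² ≥ 4, N ≥ 3 |
  | BCPNN | IC = log₂(aN/((a+b)(a+c))), Bayesian E(IC), V(IC) | IC025 > 0 |
  | MGPS  | EBGM = aN/((a+b)(a+c)), lognormal 95% CI | EBGM05 > 2 |

  A pair is a *signal* only when all four criteria hold, the Bonferroni-
  corrected χ² p-value threshold (P/n over all PTs with N ≥ 3) is met, and
  the PT is not an indication for the drug. Note the simplified EBGM shares
  its core ratio with the raw IC, so EBGM = 2^IC identically.
* **Time to onset (TTO)**: days from therapy start (THER `START_DT`) to
  event (`EVENT_DT`), keeping only exact dates with non-negative
  differences; interval histogram, maximum-likelihood Weibull fit with Wald
  CIs (shape β < 1 with CI excluding 1 ⇒ "early failure", a hazard that
  falls with time on drug), and Kaplan–Meier cumulative incidence by sex
  with a log-rank test.
* **Sex subgroups**: the full battery re-run inside each sex stratum, plus
  a top-20 overlap comparison.
* **Synthetic data generator** that emits a multi-quarter FAERS-dialect
  database with fully known ground truth — planted reporting-rate ratios,
  injected duplicate case versions, configured sex mix and Weibull onset
  law, ~96% missing or partial event dates — so the entire pipeline is
  testable end to end without downloading anything.

## Worked example

Generate a synthetic database under the default study conditions (20,000
report versions, ~10% duplicated cases, three planted signals on the focal
drug) and run the full pipeline:

```python
from pathlib import Path
from faerspv import GeneratorConfig, RunConfig, generate_database, run

gt = generate_database(GeneratorConfig(n_reports=20_000, seed=7), "db")
print(f"{gt.n_report_versions} versions, {gt.n_cases} cases, "
      f"{gt.n_duplicated_cases} duplicated")
# 20000 versions, 18149 cases, 1851 duplicated

res = run(RunConfig(input_dir=Path("db"), output_dir=Path("out")))
print(res.pt_significant[["event", "a", "ror", "prr", "ebgm", "ebgm05"]])
```

```
                      event     a      ror      prr     ebgm   ebgm05
INCORRECT DOSE ADMINISTERED  1252 6.528869 5.726766 2.899288 2.647183
        INJECTION SITE PAIN  1089 5.863286 5.249599 2.797128 2.544379
```

The dedup step kept 18,149 of 20,000 versions (matching the generator's
ledger exactly); the cohort holds 3,753 focal-drug cases contributing 8,630
(case, PT) pairs. The two strongest planted pairs pass all four criteria
plus Bonferroni (threshold 0.05/41 ≈ 1.2×10⁻³) and are ranked by EBGM; the
weakest planted pair (nominal rate ratio 5, attenuated by weight
renormalisation) sits below the stringent EBGM05 > 2 bar at this sample
size, which is exactly the "most stringent algorithm" behaviour the ranking
is built on. The TTO bundle recovers the onset law:

```python
w = res.weibull
print(w.shape, w.shape_ci95, w.trend, w.median)
# 0.681 (0.598, 0.776) early-failure 22.0
print(res.km.p_value)       # 0.878 — no sex difference in onset, as planted
```

With only 129 dated onsets (3.6% completeness), the Weibull shape 0.68
(95% CI 0.60–0.78) correctly classifies the planted β = 0.63 law as early
failure — ADE risk concentrated in the first weeks of therapy — and the
sample median of 22 days sits next to the configured 23.

The same workflow is available from the shell:

```sh
faerspv generate --out db --n-reports 20000 --seed 7
faerspv run --input db --out out
faerspv tto --input db --out out-tto        # single-stage variants: signals, subgroup
```

## Layout

```
src/faerspv/
  faers_io.py      FAERS ASCII dialect reader/writer, typed records, dates
  cohort.py        dedup rule, drug-name matching, (case, PT) pair building
  signal_stats.py  2×2 tables, ROR/PRR/BCPNN/MGPS, criteria, Bonferroni
  tto.py           onset extraction, binning, Weibull fit, KM + log-rank
  subgroup.py      sex-stratified signals, top-k comparison
  synthetic.py     ground-truthed FAERS-dialect generator
  pipeline.py      orchestration, descriptive table, result bundle
  cli.py           click CLI (generate / run / signals / tto / subgroup)
```

See `docs/methods.md` for the statistical methods, generator design and
known limitations.
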