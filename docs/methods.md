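# Methods

This note documents the statistical procedures, the synthetic-data design,
the numerical choices and the limitations of `faerspv`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Counting units and the 2×2 table

The analysis unit is the distinct **(deduplicated case, event)** pair, at
two levels: MedDRA preferred term (PT) and system organ class (SOC). A
*case* is one safety report after version resolution; a case reporting the
same PT twice contributes one pair, and at SOC level a case reporting
several PTs of one SOC contributes one (case, SOC) pair. Two cohort-level
quantities follow: the number of focal-drug cases (reports) and the number
of focal (case, PT) pairs; PT reporting frequencies are percentages of the
latter.

For an event *e* the pair universe is partitioned into the classic cells —
a (focal drug, event *e*), b (focal drug, other events), c (other drugs,
event *e*), d (other drugs, other events) — with N = a+b+c+d.

## Deduplication

FAERS republishes case versions across quarters. Per CASEID the kept
version is the one with the latest exact FDA_DT; ties go to the higher
PRIMARYID (compared numerically when both ids are digit strings, falling
back to lexicographic order so the rule is total); versions with missing
FDA_DT lose to any dated version. The rule is deterministic, idempotent and
order-invariant, and the tests verify it against an independent
group-sort-take-last oracle.

## Drug-name matching

FAERS has no drug coding, so the cohort is found by name. Names are
upper-cased, trimmed and whitespace-collapsed; the default match accepts a
list entry (generic or brand name) anywhere in the verbatim string at word
boundaries, so dose-suffixed strings match but partial tokens do not. An
exact-equality mode is available behind a flag. Only rows whose role code
is PS (primary suspect) qualify a case for the cohort by default; the role
filter is a parameter, and cohort size is monotone in it.

## Disproportionality statistics

All four algorithms run on every event's 2×2 table:

* **ROR** = ad/bc with 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
* **PRR** = (a/(a+b))/(c/(c+d)) with the Pearson χ² statistic on 1 df,
  no continuity correction, and its p-value.
* **BCPNN**: the information component IC = log₂(aN/((a+b)(a+c))) as the
  point estimate, plus the closed-form Bayesian posterior moments E(IC)
  and V(IC) of Bate et al. (1998) (priors α₁=β₁=γ₁₁=1, α=β=2), from which
  IC025 = E(IC) − 2√V(IC). The raw IC is −∞ at a=0 and flagged; the shrunk
  expectation stays finite there, which is the point of the Bayesian form.
* **MGPS (simplified)**: EBGM = aN/((a+b)(a+c)) — the relative report rate
  — with EBGM05 = `exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d))`. The full
  DuMouchel gamma-Poisson mixture EM is deliberately out of scope; with
  this closed form EBGM = 2^IC holds identically, a relation the tests
  check on 10,000 random tables and that published signal tables using the
  same simplification satisfy at printing precision.

Useful identities: all four point estimates equal 1 on any independence
table (ad = bc); ROR ≥ PRR exactly when ROR ≥ 1; χ² is invariant under
simultaneous row/column transposition.

**Zero cells.** Point estimates are reported on the uncorrected cells
whenever defined (a=0 gives ROR = EBGM = 0); otherwise, and for all CIs
involving a zero cell, the Haldane–Anscombe +0.5 correction is applied to
every cell and the result carries a `degenerate` flag.

**Signal definition.** A pair is significant only when all four criteria
hold simultaneously: ROR CI lower bound > 1 with N ≥ 3; PRR ≥ 2 with
χ² ≥ 4 and N ≥ 3; IC025 > 0; EBGM05 > 2. The χ² p-value is the only
p-value the method set produces, so the Bonferroni correction (threshold
P/n, default P = 0.05) is applied to it over the family of all events with
N ≥ 3 — an assumption, since multiple-testing families are rarely spelled
out in published analyses. PTs that appear among the cohort's recorded
drug indications (e.g. WEIGHT DECREASED for a weight-loss drug) keep their
statistics but are barred from the significant set; the exclusion list is
a configuration input, auto-derived from the INDI rows by default.
Significant PTs are ranked by EBGM descending (the most stringent
algorithm), ties by report count then name.

## Time to onset

TTO = EVENT_DT − earliest exact focal-drug START_DT, in days, one
observation per case. Cases are excluded — and tallied by reason — when
either date is missing or partial (4- or 6-digit) or the difference is
negative. There is no censoring: spontaneous reports only contain realised
events, so the Kaplan–Meier survival reaches 0 and cumulative incidence is
1 − S(t).

* **Histogram** bins: [0–30], (30–60], (60–90], (90–180], (180–360],
  (>360] days; day 30 belongs to the first month.
* **Weibull fit**: maximum likelihood via `scipy.stats.weibull_min` with
  location fixed at 0; Wald 95% CIs from the observed information matrix
  on (ln β, ln η), computed by central finite differences (step 1e-4) at
  the MLE. Day-0 observations are shifted to 0.5 days for the likelihood
  only (the Weibull has positive support); descriptive median/quartiles
  use the raw values. At least 10 observations are required and
  all-identical input is rejected. Hazard trend: β CI entirely below 1 ⇒
  early failure (risk concentrated early in therapy); entirely above 1 ⇒
  wear-out; otherwise random. Because onset days are integers, the fitted
  shape carries a small upward discretisation bias (≈ +5% at β ≈ 0.6,
  measured on large simulated samples); parameter-recovery tests at
  n = 2,000 use a 10% relative tolerance that absorbs it.
* **Sex comparison**: Kaplan–Meier per stratum (via `lifelines`) and the
  log-rank test. The test is a package choice; published analyses often
  show the curves without naming one.

The per-case observation carries the full set of SOCs the case reported
(not a single SOC), and the per-SOC onset table counts a case once in each
of its SOCs — the one structural deviation from a strictly single-SOC
record, needed so multi-system cases are not arbitrarily assigned.

## Sex subgroups

Stratified signals rebuild the 2×2 tables entirely within a stratum: both
the focal and the comparator pair universes are restricted to that sex, so
a female-only excess cannot leak into the male stratum through a shared
background. A whole-database comparator is available behind a flag, since
published sensitivity analyses do not always state which universe they
used. The "unknown" stratum is reported but excluded from the two-way
comparison. Top-k lists are ranked by report count descending (ties: EBGM,
then name), and the comparison is plain set algebra plus a side-by-side
rank table.

## Synthetic data generator

The generator emulates the structure of a modern FAERS extract for a
recently approved injectable antidiabetic, with defaults frozen to the
cohort it mirrors:

| parameter | default | rationale |
|---|---|---|
| sex mix (F/M/unknown) | 0.688 / 0.190 / 0.122 | observed cohort shares |
| event-date completeness | 0.036 | ~96% of reports lack a full onset date |
| Weibull shape β | 0.63 | early-failure onset law |
| Weibull scale η | 23/ln2^(1/β) ≈ 41.1 d | median onset 23 days |
| PTs per report | truncated Poisson(2), min 1 | ~2.1 PTs/report multiplicity |
| quarters | 8 (2022Q2 start) | a two-year extract |
| duplicate case fraction | 0.10 | cross-quarter re-publication; not stated in the mirrored cohort, chosen as a realistic rate |
| drug vocabulary | 5 drugs, focal first | ~20% focal share keeps both cells of the table populated |
| PT vocabulary | 41 PTs over 8 SOCs | enough events for a Bonferroni family without desk-scale cost |
| start-date completeness | 0.95 | therapy dates are far better recorded than event dates |
| swapped-date fraction | 0.01 | exercises the negative-onset exclusion |

Duplicated cases are emitted as two versions with the same CASEID, distinct
PRIMARYIDs and FDA_DTs in the same or a later quarter, so the dedup rule's
winner is known and recorded in the ledger. Incomplete event dates are
emitted as 4- or 6-digit strings or blanks (1:1:2), exercising the
partial/missing distinction. The focal drug's DRUG rows use a rotating set
of verbatim aliases (generic, brands, a dose-suffixed brand string) to
exercise word-boundary matching. Age, weight, country, reporter, outcome
and indication margins mirror the heavy missingness of real extracts.

**Planted signals.** A planted reporting-rate ratio multiplies the focal
drug's weight for that PT before the per-report PT draw renormalises the
weight vector. Renormalisation and multi-PT saturation make the realised
case-level rate ratio sit ~10–15% below the nominal multiplier (e.g. ≈4.2
realised for a nominal 5 under the default vocabulary); the ledger
therefore records the nominal value and tests verify the realised ratio
empirically, within the ±20% band this attenuation was designed against.
Sex-specific multipliers stack on top for one stratum only. With nothing
planted, drug and event are independent by construction and the pair-level
RORs centre on 1.

Generation is byte-deterministic given (config, seed): one `numpy`
Generator drives a single sequential draw order.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: drug-name misspellings and free-text noise,
polypharmacy correlation structure (concomitants are drawn independently),
PT co-occurrence syndromes, country/reporter coding subtleties, MedDRA
hierarchy beyond a flat PT→SOC map, secular reporting trends (stimulated
reporting, quarter-to-quarter volume growth), and true pharmacology — a
planted rate ratio is a reporting artefact by design, not a causal effect.

## Numerical and design choices

* Dates: only 8-digit valid calendar strings are exact; 4/6-digit strings
  are partial; impossible dates (e.g. month 13) are missing, not errors.
* THER/INDI rows join to DRUG rows by (primaryid, drug sequence) when both
  sides carry sequence numbers, else by primaryid first-row-wins — the
  minimal deterministic rule.
* A PT mapped to several SOCs keeps the first listing, with a warning
  (licensed dictionaries resolve this with a primary SOC; a two-column
  user mapping cannot).
* Percentages in the descriptive table print to one decimal; top-k blocks
  (countries, indications) carry an explicit "Other" row so every
  single-valued block sums to the cohort size. Outcome counts can exceed
  the case count because a case may have several serious outcomes.
* Monte-Carlo acceptance checks state their tolerances from the sampling
  design: the family-wise error check compares a 500-replicate estimate
  against 0.05 plus a one-sided 95% binomial allowance, and uses null
  databases large enough (expected a ≈ 200 per PT) that the χ² tail
  approximation is accurate at the Bonferroni threshold — at much smaller
  cells the check would measure χ² approximation error, not Bonferroni
  control.
* Problem sizes used by the tests and the acceptance script: planted- and
  null-signal recovery at 50,000 report versions; margin calibration at
  10,000; Weibull recovery at ~2,000 complete onsets; CI coverage over
  1,000 tables; FWER over 500 null replicates.

## Limitations

* Disproportionality quantifies reporting association, never incidence or
  causation; all the usual spontaneous-report caveats (underreporting,
  stimulated reporting, confounding by indication) apply to any real-data
  use of this package.
* The simplified EBGM is not shrunk: for very small a it behaves like the
  raw relative report rate, and EBGM05 relies on a lognormal
  approximation. The stringency of the four-way conjunction, not
  shrinkage, is what controls false positives here.
* The BCPNN IC025 uses the closed-form posterior moments, not the full
  Monte-Carlo posterior; differences are negligible except at tiny counts.
* TTO analysis ignores the ~96% of cases without complete dates and is
  conditional on an event being reported — a reporting-time, not a
  time-at-risk, analysis.
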