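# Methods

## The estimation problem

Routine vital-records systems register a pregnancy at the mother's age when
the pregnancy *ends*. For surveillance of pregnancies in girls aged 10–13 —
all of which are, legally, the result of statutory rape — this truncates the
count: conceptions at 13 that end at 14 are recorded in the 14-year-old
stratum. The package estimates the full count by imputing age at conception
for age-14 outcomes, stream by stream, and reports an interval rather than a
point estimate wherever a record system lacks the field needed for exact
imputation.

## Age and date conventions

All ages are completed years under a fixed 365-day convention:
`age = ⌊days between dates / 365⌋`. No calendar-birthday logic and no
leap-day correction are applied anywhere; the eligibility filter and the
classifier share one implementation of this function, so a record can never
be judged consistent by one stage and inconsistent by another. The
convention drifts relative to calendar ages by roughly one day per four
years of age (about 3–4 days at these ages), which can flip records whose
day-difference sits within that distance of a 365-multiple boundary. The
synthetic generator constructs truth under the same convention by default
so that method fidelity is tested separately from convention bias; the
`calendar_age_truth` toggle constructs calendar-age truth instead, and the
gap between the two runs measures the convention's own error.

Period membership of a pregnancy is the calendar year of its outcome date
(delivery, fetal demise, abortion admission, maternal death); a violence
notification belongs to the year the aggression occurred. An "extra"
pregnancy recovered from the age-14 stratum is assigned to its outcome
year, not its conception year.

## Stream-specific procedures

* **Live births.** Records at recorded age 14 are excluded when gestational
  age or maternal birth date is missing or when the recomputed age differs
  from the recorded age (exact equality, no ±1-year tolerance — the record
  is unreliable either way). Reasons are tallied independently per record;
  a record is excluded once. Eligible records are classified by imputed
  conception age; because eligibility forces the recomputed delivery age to
  be exactly 14 and gestations are at most 45 weeks (315 days < 365), the
  imputed conception age is always 13 or 14 and the classification
  partitions the input.
* **Fetal deaths.** The certificate lacks the maternal birth date, so the
  live-birth conceived-at-13 proportion *p* is applied:
  `round(n₁₄ × p)`, computed from the *unrounded* p (172 × 7127/11417 =
  107.37 → 107) with ties rounded half-up. Rounding only at the end avoids
  compounding; half-up is indistinguishable from the single available
  reference value and is the documented, configurable choice.
* **Abortion admissions.** The record lacks gestational age and outcome
  date; the admission date stands in for the end of pregnancy and two
  scenario gestational ages bound the count — 6 weeks (minimum for
  sonographic identification of a gestational sac) and 21 weeks (maximum
  for classifying the outcome as an early fetal loss). For records with a
  recorded age of 14 consistent with their dates, a longer assumed
  gestation can only move the imputed conception age from 14 to 13, never
  past it, so the high scenario dominates the low one. Records missing the
  maternal birth date are skipped and tallied in a side report. No
  distribution over gestational age is averaged: the method bounds, it does
  not integrate.
* **Maternal deaths before the end of pregnancy.** Counted in the
  registered total; no extra can be estimated (no gestational age on the
  death certificate), which biases the interval slightly downward.

The registered total is the exact sum of the four streams at recorded age
10–13; the interval adds live-birth extras, the fetal-death allocation and
the abortion scenario counts. Components are retained by name in every
`EstimateInterval` so totals remain auditable.

## Indicators

Specific fertility rate = mean annual pregnancies / mean annual girls aged
10–13 × 1,000; with a common period the means cancel, so the implementation
divides period totals (the identity is asserted numerically in the tests).
Notification coverage = qualifying rape notifications (female, rape flag,
age 10–13, occurrence year in period) / pregnancies × 100; pregnancies are
a proxy denominator — not every rape causes pregnancy — so true coverage of
rapes is lower than any number reported here, and the value is deliberately
not clamped at 100% (referral services concentrate out-of-region cases).
Perinatal indicators use their conventional denominators: live births for
preterm, low birth weight, neonatal mortality (0–27 days) and the maternal
mortality ratio (×100,000); fetal deaths + live births for fetal mortality
(×1,000); notifications for the legal-abortion (ICD-10 O04) ratio. Preterm
and low-birth-weight numerators count records with a known value; the
denominator is all live births in the stratum, so missing fields shrink the
proportion rather than the stratum.

Reported rounding: rates per 1,000 at 2 decimals, percentages and the MMR
at 1 decimal, comparison ratios at 2 decimals, all half-up. Ratios are
computed from the values as given; dividing printed (already-rounded) cells
can differ by ~±0.01 from ratios of unrounded microdata, which is why the
reference maternal-mortality ratio divides to 4.31 from printed cells where
unrounded data print 4.32. Zero denominators yield explicitly undefined
cells (`None`), or a raised error for the scalar rate functions — never a
silent zero.

## Synthetic-data generator

Each simulated pregnancy receives a region and municipality, an age stratum
at outcome (10–14), an outcome type, a gestational length, and an outcome
date uniform in the period; the conception date is outcome − 7 × weeks by
construction, and the maternal birth date is back-solved so the completed-
years age at outcome equals the target, with the conception age of age-14
outcomes forced to 13 with probability *q*. Missingness, age mis-statement
and notification behaviour are injected from independent random streams
*after* ground truth is recorded, so every degradation is measurable. One
pregnancy yields one record in one outcome table and one ground-truth row;
multiple gestation is not modelled (the method counts records).

Defaults emulate the reference study conditions: period 2012–2022, 19
regions of ~985 pregnancies (ages 10–14) each, age-at-outcome mass
(0.01, 0.03, 0.06, 0.16, 0.74) over ages 10–14, outcome mix
(0.89, 0.013, 0.096, 0.001) for live birth / fetal death / abortion /
maternal death, *q* = 0.624, degradation rates (0.05, 0.03, 0.025) whose
union ≈ 10% matches the observed exclusion fraction, abortion gestations
uniform on 6–21 weeks, a birth gestational-age pmf with mode 39 and 18.5%
preterm mass, birth weights from term/preterm normal mixtures, neonatal
mortality 16.4/1,000, and a region-year population of 13,600 girls.
Per-pregnancy notification probability is 0.11: because generated
notifications attach to pregnancies at the age of conception, ~0.11 per
pregnancy reproduces a measured coverage near 30% of *registered*
pregnancies, matching the reference measurement. A small unlinked stream
(1%) and a distractor stream (5%, each failing exactly one selection
filter) exercise over-coverage and the selection logic. No distributional
information on gestational age exists for this population; the defaults are
conventional and configurable, not calibrated to microdata.

What the generator does **not** emulate: spatial autocorrelation and
realistic regional heterogeneity (regions are exchangeable), demographic
trends within the period, record linkage between systems (a girl appearing
in two streams), multiple gestation, private-sector admissions, and real
municipality coding. Passing tests therefore demonstrate that the method
recovers what it assumes — correct arithmetic, correct filtering, unbiased
recovery of *q* and of coverage under the generator's model — not that the
record systems satisfy those assumptions.

## Numerical and design choices

* Rounding is half-up throughout (`decimal`-based), since Python's builtin
  banker's rounding would turn e.g. 62.45 into 62.4.
* The conceived-at-13 proportion is carried unrounded into allocation;
  whether the reference application used 62.4% or the exact ratio is
  undecidable from one printed value (both give 107), so the exact ratio is
  used and the choice documented.
* Degenerate inputs: an empty eligible set makes the proportion undefined —
  the classifier raises; the pipeline records the condition in its manifest,
  sets the age-14 extras to zero and continues, so small runs complete.
* CSV rejects are reported, never dropped; duplicate record ids abort.
* A single static municipality→region map is required; municipalities
  created or merged mid-period must be resolved by the user before input.
* Double counting across streams (the same girl in abortion and live-birth
  tables) cannot be detected without record linkage; records are counted,
  as the streams themselves count.

## Problem sizes

Test and acceptance runs use synthetic cohorts of 1,200–15,200 pregnancies
(the parameter-recovery check sizes the cohort to ~10,000 eligible age-14
deliveries, the scale at which 3 binomial standard errors separate q = 0.6
from naive alternatives); the date-arithmetic oracle iterates 10,000 random
cases day by day. These sizes make the full suite run in seconds while
keeping binomial bounds tight enough to detect systematic errors.
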