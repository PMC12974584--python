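# gestima

Estimation of pregnancies among girls aged 10–13 from routine vital-records
extracts, with the downstream indicators used in adolescent reproductive
health surveillance: age-specific fertility rates, rape-notification
coverage and perinatal outcome comparisons.

Under the Brazilian Penal Code any sexual act with a child under 14 is
statutory rape, so every pregnancy at ages 10–13 is by definition the result
of a crime. Routine record systems, however, register a pregnancy at the age
of the mother when it *ends* — a girl who conceived at 13 and delivered at
14 is invisible in a naive 10–13 tabulation. This package implements the
record-level procedure that recovers those pregnancies and bounds the total.

## Method

Four record streams are combined, each restricted to the study period by
its outcome year and aggregated by health region of residence:

* **live births** (SINASC-like certificates), with maternal birth date and
  gestational age;
* **fetal deaths** (SIM-like certificates), which lack the maternal birth
  date;
* **hospital abortion admissions** (SIH-like records, ICD-10 O00–O08),
  which lack the gestational age;
* **maternal deaths before the end of pregnancy** (SIM-like).

**Registered pregnancies** are the exact sum of the four streams at recorded
maternal age 10–13. **Estimated pregnancies** add age-14 outcomes whose
imputed age at conception is 13, obtained per stream:

1. *Live births.* Age-14 certificates are excluded when the gestational age
   or maternal birth date is missing, or when the age recomputed from the
   dates contradicts the recorded age. For each remaining record,

   ```
   gestation days  = gestational weeks × 7
   conception date = infant birth date − gestation days
   age at conception = ⌊(conception date − mother birth date) / 365⌋
   ```

   The 365-day completed-years convention (no calendar birthdays, no
   leap-day correction) governs every age in the package.
2. *Fetal deaths.* Without a maternal birth date no conception age can be
   computed; the conceived-at-13 proportion *p* observed among eligible
   live births is applied to the age-14 fetal-death count
   (round-to-nearest, unrounded *p*).
3. *Abortion admissions.* Without a gestational age the count is bounded by
   two scenarios: 6 assumed weeks (earliest sonographic detection of a
   gestational sac) and 21 weeks (upper limit of an early fetal loss),
   giving a minimum and maximum. The admission date stands in for the end
   of pregnancy.
4. *Maternal deaths.* With neither field available, no extra is estimated;
   they enter the registered total only.

The result is an interval `[min, max]` with every named component retained.
Indicators follow: specific fertility rate (pregnancies / girl-years ×
1,000), notification coverage (rape notifications for girls 10–13 /
pregnancies × 100, a proxy that can exceed 100% where referral services
concentrate cases), and perinatal outcomes (preterm %, low birth weight %,
fetal and neonatal mortality, maternal mortality ratio, legal-abortion O04
to notification ratio) with young/adult comparison ratios.

A seeded synthetic-data module emulates all record systems with known
ground truth (true conception dates and ages, true notification status),
so the whole pipeline runs and is testable without any external data.

## Worked example

The package ships the component counts of the published reference
application of this method (Maranhão, Brazil, 2012–2022) and recomputes
every headline estimate from them:

```
$ gestima verify
                            quantity  computed  published  passed
              registered_pregnancies   4839.00    4839.00    True
             eligible_live_births_14  11417.00   11417.00    True
                 conceived_at_13_pct     62.40      62.40    True
              fetal_death_allocation    107.00     107.00    True
                 estimated_total_min  12137.00   12137.00    True
                 estimated_total_max  12354.00   12354.00    True
                     increase_factor      2.50       2.50    True
             coverage_registered_pct     29.10      29.10    True
          coverage_estimated_min_pct     11.40      11.40    True
       fertility_registered_per_1000      1.70       1.70    True
    fertility_estimated_max_per_1000      4.33       4.33    True
fetal_mortality_ratio_10_13_vs_20_29      1.28       1.28    True
all 12 reference quantities reproduced
```

Reading: 4,839 pregnancies were registered at ages 10–13 (4,317 live births
+ 64 fetal deaths + 3 maternal deaths before pregnancy end + 455 abortion
admissions). Of 12,754 age-14 birth certificates, 11,417 were usable and
62.4% of them imply conception at age 13; applying that proportion to 172
age-14 fetal deaths allocates 107, and the abortion scenarios contribute
between 64 and 281 — an estimated total of 12,137–12,354 pregnancies, 2.5×
the registered count. Coverage of rape notifications (1,410) falls from
29.1% of registered pregnancies to 11.4% of the estimated maximum, and the
fertility rate rises from 1.70 to 4.33 per 1,000.

An end-to-end synthetic run:

```
$ gestima simulate --seed 5 --outdir sim/
$ gestima report --indir sim/ --outdir out/
Registered pregnancies at ages 10-13: 4,966 (live births + fetal deaths + maternal deaths before pregnancy end + abortion admissions).
Age-14 live births: 12,134 records, 1,021 excluded, 11,113 eligible.
Conceived at 13 among eligible age-14 deliveries: 6,900 (62.1%).
Estimated pregnancies at ages 10-13 (incl. age-14 outcomes conceived at 13): between 12,397 and 12,827.
State fertility rate (registered): 1.75 per 1,000; rape-notification coverage (registered denominator): 31.1%.
```

`out/` then contains the eligible records, the exclusion report, the
interval estimate with components, a per-region indicator table and a
manifest logging record counts at every stage. `gestima clean`,
`gestima estimate`, `gestima rates`, `gestima coverage` and
`gestima outcomes` expose the individual stages.

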