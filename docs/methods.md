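# Methods

## The cohort model

The effectiveness model is a discrete-time Markov cohort model with an
annual cycle and three states: alive pre-stroke, post-stroke, and dead.
The alive profile — non-AF, DOAC-treated AF, or untreated AF — does not
change the state diagram; it selects which stroke and all-cause death
columns of the transition table apply. Transition probabilities are
annual marginals by sex and five-year age band (65–69 … 95–99, with a
terminal 100+ band whose death probabilities are 1), shipped as CSV in
`afscreen/data/`. The post-stroke death probability `p_e1e2` is the total
annual death probability in that state, not an increment over background
mortality (it exceeds same-band background mortality in every band).

Within a cycle the competing risks are ordered: death from any cause is
resolved first, and stroke strikes the survivors, so the stroke hazard is
applied as `(1 − p_death) · p_stroke`. The source tables give only annual
marginals; this ordering is a declared convention, and its residual
effect is absorbed by the convention calibration described below. An
incident stroke is acutely fatal with probability 0.057 (event before age
75) or 0.101 (75+), applied identically in all three alive profiles:
acute lethality is treated as a property of the event, and the published
fractions are indexed by age, not by treatment.

### Accrual, utilities, discounting

Utility weights: 1.0 for alive pre-stroke (the published utility table
specifies only stroke-related utilities, and the published QALY/life-year
ratios of ~0.96 are consistent with a unit baseline eroded by stroke
states); 0.68 / 0.56 post-stroke below / at-or-above age 75, keyed to the
cohort's **current** age (utilities are published by age band, not by
event time; `poststroke_utility="at_event"` freezes the utility at the
event age instead). A stroke cycle accrues `u_post(a) − 0.14 × 0.25`,
i.e. the acute decrement of 0.14 for a quarter year spread over the
cycle, for survivors a full year and for acute deaths the death credit.

Members dying within a cycle accrue a configurable fraction of it:
1 (`cycle_start`), 0 (`cycle_end`) or 0.5 (`half_cycle`). Life-years and
QALYs are both discounted at 2%/year, with a configurable exponent base
(cycle 0 undiscounted, or discounting from the first cycle).

### Convention calibration

The published results state the discount rate but not the cycle
correction or the discount exponent convention. Rather than guessing,
`calibrate_conventions` scans the six (accrual × base) pairs and keeps
the one whose DOAC-arm discounted life-years for men starting at 65 are
closest to the published anchor value 13.585. The scan selects
half-cycle accrual with 0-based discounting (anchor reproduced at
13.690). With the pair frozen, all sixteen published life-year/QALY
totals are reproduced within 0.20 and all eight QALY gains within 0.04 —
comfortably inside the package's acceptance tolerances of 0.30 and 0.05.
The calibration touches only these two discrete switches, never the
transition or utility parameters.

### Microsimulation cross-check

`microsim_cohort` simulates n individual trajectories under exactly the
same per-cycle probabilities, accrual and discounting, vectorised over
subjects. The cohort recursion computes the expectation of this process,
so sample means must agree within Monte-Carlo error; the test suite
checks all eight published sex×age cells at n = 200 000 within 3 standard
errors. This validates the recursion's bookkeeping (state splits,
accrual credits, discount indexing) independently of the closed-form
path.

### Discount-rate sensitivity

`sensitivity_discount` re-runs the comparison at any set of rates. The
gains keep their sign and ordering between 0% and 4%, but the youngest
cohorts are genuinely discount-sensitive: the treatment benefit accrues
decades after baseline, so the 65-year-old QALY gain moves from ~0.89
(2%) to ~1.21 (0%) and ~0.67 (4%) for men. Undiscounted gains of ~1.2
QALYs match the source's qualitative statement of "about 1 year" of
quality-adjusted life gained.

## Screening statistics

- Detection rates carry Clopper–Pearson 95% intervals (beta quantiles).
- `fisher_exact` implements the two-sided Fisher test directly: at fixed
  margins it sums the hypergeometric probabilities of every table no more
  probable than the observed one, with a relative tie slack of 1e-10.
  The per-margin-class form (`fisher_pvalues_by_margins`) evaluates a
  whole margin class vectorised, which lets the test suite verify the
  implementation against an exact integer-arithmetic enumeration for all
  ~628 000 tables with grand total ≤ 60, and against
  `scipy.stats.fisher_exact` on random tables (agreement to ~1e-14).
- Stratified detection keeps known treated-AF subjects and
  uninterpretable ECGs in the denominators by default, matching the
  campaign's published stratum sizes; `exclude_treated` /
  `exclude_uninterpretable` flags restrict to the at-risk interpretable
  population. Records with a missing factor status are dropped from that
  factor's table.
- The correct two-sided Fisher p for the published hypertension stratum
  (10, 618, 5, 972) is 0.0343; the campaign's printed 0.035 arises only
  from a table that uses stratum totals as the negative column, and its
  printed diabetes p of 0.90 matches a continuity-corrected chi-square
  rather than Fisher's test. The package computes the correct test and
  documents the discrepancies in the fixture and tests.
- Cohen's κ uses the standard marginal-product chance correction and is
  undefined (raises) when both raters are constant and identical.
- Scores: CHADS₂ = CHF + HTN + (age ≥ 75) + DM + 2·(stroke/TIA);
  CHA₂DS₂-VASc doubles the age-75 point and adds vascular disease, age
  65–74 and female sex. Every screened subject is 65+, so CHA₂DS₂-VASc
  ≥ 1 always.

## National projection

For each sex and single year of age 65–80 (five-year band headcounts
divided by 5, following the source's convention for Vital-Statistics
tables): `b = a · p` identified cases at detected prevalence
`p = 12/1607` (cases with CHADS₂ ≥ 1, the anticoagulation-eligible
subset), `c` the 10-year cumulative incident-stroke difference per person
(untreated − treated, acute deaths included, undiscounted) from the
Markov engine at that exact start age, `d = 1/c` the number needed to
treat and `e = b · c` strokes prevented. The same prevalence applies to
every cell, as the source's single-constant formula implies. `c` counts
strokes among all entrants, not survivors only (the alternative is a
documented interpretation, selectable by computing risks from truncated
traces). No uncertainty intervals are produced — the projection is a
deterministic extrapolation.

The published national totals require the external 2019 Vital Statistics
population; the repository ships only a clearly-labelled synthetic
population of similar size (`examples/data/population_synthetic.csv`),
on which the pipeline yields totals of the same order (~189 k identified,
~7.2 k prevented).

## Synthetic cohort generator

`generate(CohortSpec())` draws: age from a normal (72.4, 5.8) truncated
at 65; sex and comorbidities as independent Bernoullis at the published
marginal prevalences; a known-AF flag at 43/1607; untreated-AF status
with hypertension-dependent probability calibrated so the at-risk
marginal equals 15/1564 at a rate ratio of 3 (the generator raises if
the ratio forces a probability above 1); two independent ECG readers
(sensitivity 0.95, specificity 0.997 — chosen so the implied
interobserver κ at the cohort's AF prevalence is near the observed
0.853) with a third-reader tiebreak on disagreement; a device label with
its own error rates and an unclassified fraction; and an uninterpretable
fraction of 2/1607.

What the generator does **not** emulate: comorbidity correlations (only
marginals were published; independence is a documented simplification),
untreated-AF effects of factors other than hypertension, paroxysmal-AF
intermittency, and any waveform-level structure. Tests passing on
synthetic cohorts therefore demonstrate estimator correctness under the
stated sampling structure, not robustness to real-world dependence
between risk factors.

`fixture_table4()` is deterministic: 1607 records whose per-factor 2×2
tables reproduce the published stratified counts exactly. The published
tables are internally inconsistent — the hypertension stratum totals
1605 of 1607, and the published CHADS₂ breakdown of the 15 cases sums to
18 factor points while the per-factor case counts sum to 17. The fixture
follows the stratified counts: two non-case records (the two
uninterpretable traces) carry a missing hypertension status, and the
cases' score breakdown is {0: 3, 1: 8, 2: 3, 3: 1}. The discrepancy is
documented rather than resolved.

## Numerical choices and limitations

- Cohort recursion runs in float64 to extinction (occupancy < 1e-15);
  conservation of occupancy is asserted to 1e-12 per cycle.
- Problem sizes: microsimulation cross-checks use n = 200 000 (acceptance)
  and 50 000 (unit), giving standard errors of ~0.01 life-years; the
  generator recovery tests use n = 100 000.
- Band membership is closed-left (75.0 belongs to 75–79); ages ≥ 100 use
  the terminal band; the acute-fatality and post-stroke-utility age
  switches sit exactly at the 75th birthday.
- The model starts at 65 and covers screening start ages 65–80 only; no
  costs, no incidental AF detection outside screening, no treatment
  crossover (the untreated arm stays untreated for life), and no
  device-algorithm modelling.
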