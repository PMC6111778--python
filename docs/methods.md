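# Methods

## The network model

A prescription record is one prescribed item with an attached ICD-9-CM
diagnosis code. Codes are pooled into the 20 standard top-level chapters
(001–139 INFE, 140–239 NEOP, 240–279 META, 280–289 BLD, 290–319 MENT,
320–359 NERV, 360–389 SENS, 390–459 CIRC, 460–519 RESP, 520–579 DIGE,
580–629 GEN, 630–679 PREG, 680–709 SKIN, 710–739 MUSC, 740–759 CONG,
760–779 NEWB, 780–799 ILL, 800–999 INJ, V-codes SUPP, E-codes EXT);
sub-codes inherit their three-digit stem. The map ships as data
(`GroupMap`, YAML-serialisable) so alternative groupings need no code
change.

The co-prescription unit is one patient on one calendar date ("visit"
granularity). Visits are a natural unit because GP visits are weeks
apart; pooling a patient's whole multi-year history instead
(`cooccur="patient"`) saturates links and is provided only as an
alternative. Within one occasion each unordered pair of *distinct*
chapters counts once, however many records of each chapter the occasion
contains; this keeps the handshake identity Σ strengths = 2 Σ link
weights exact and self-loops impossible. Node weights count prescriptions
(not occasions), because node size is meant to read as prescriptions per
patient. Chapters with no prescriptions in a stratum are omitted rather
than kept as zero-weight nodes.

Normalization divides every node weight, link weight and strength by the
number of patients contributing at least one record to the stratum. A
record belongs to the age class of the patient's age *at the prescription
date*, so one patient can contribute to two adjacent decade classes over a
long window and is counted in each class's denominator; this keeps each
stratum's per-patient rates self-contained. Age classes are decades
(15,25], ..., (75,85] with terminal (85,110]; the first class includes
age 15, which a strictly half-open convention would orphan.

Diabetes is a patient-level label — at least one Drug prescription coded
250.00–250.99 anywhere in the history — applied uniformly across strata,
so D/ND comparisons never reclassify a patient mid-analysis.

## Uncertainty

Co-prescription counts are treated as Poisson. Single counts get the
exact Garwood interval (gamma/chi-square quantiles; lower bound 0 at
k = 0) rather than k ± 1.96√k, because per-stratum counts can be small;
the normal approximation is available via `method="normal"`. The D/ND
rate ratio uses the exact conditional construction: given the total
c_D + c_ND, c_D is binomial, its Clopper–Pearson interval is transformed
to the ratio scale by odds × n_ND/n_D. Both endpoints therefore inherit
exactness and slight conservatism; with c_ND = 0 the ratio is reported as
undefined (infinite) with an informative lower bound only. No
multiple-testing correction is applied across chapters; the ratios are
descriptive contrasts, not a testing procedure.

The representativeness check compares a sample age histogram with a
reference population per sex: r² of the class percentages (a similarity
measure) and the chi-square goodness of fit of the counts (an exact-
equality test). These deliberately answer different questions — a large
sample can have r² ≈ 1 and still reject exact equality — so both are
reported without reinterpretation.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults drawn from a published decade-long Italian GP registry
(embedded in `reference.py`): chapter mix and per-chapter
prescription-type mix from its frequency table, an overall volume near
10.5 prescriptions/patient/year, diabetes prevalence 8%.

Each patient is a renewal process of visits with inter-visit gaps uniform
in an age-class-dependent interval — within 20–70 days for non-diabetics
(younger patients toward the sparse end, older toward the frequent end)
and 17–40 days for diabetics. At each visit, chapters are drawn by two
mechanisms: independent per-chapter Bernoulli draws and coupled
pair draws that place both chapters of a pair into the same visit. Rates
are parameterised **per patient-year** and converted to per-visit
probabilities by dividing by the expected visits/year of the patient's
current age class and diabetes status (clipped at 0.95). Consequently a
base rate r yields ≈ r records/patient-year and a coupling rate c yields
≈ c co-prescription occasions/patient-year *independent of visit
frequency* — so the expected D/ND link-weight ratio of a pair equals its
configured diabetic coupling multiplier, which is what makes the
parameter-recovery experiments well-posed. Age advances during the
window (birth year is the source of truth), and the default age profile
rises monotonically through (75,85] and dips in the 85+ class,
reproducing the lower morbidity of elderly "survivor" patients.

Drawn chapters emit one record each, with a representative ICD-9-CM code
of the chapter and a prescription type from the chapter's type mix. Codes
with stem 250 are only ever emitted for diabetic patients and always as
Drug prescriptions (antidiabetic therapy), so the generator's diabetes
labels are exactly recoverable by the classification rule; non-diabetic
META records use other metabolic codes (272.0, 244.9, ...).

What the generator does **not** emulate: close repeat visits within a few
days (gaps are never below 17 days), seasonality, mortality/dropout,
pharmacologically meaningful item codes, and any dependence structure
beyond pairwise coupling. Passing tests therefore demonstrate the
pipeline's correctness and calibration under a realistic but idealised
renewal/coupling process, not the epidemiology of any real population.

### The recovery configuration

`coupling_recovery_model` isolates the coupling mechanism for estimator
validation: CIRC has no base rate and only the CIRC–META coupling is
active (0.06 occasions/patient-year for non-diabetics, multiplied by the
configured enrichment, default 15, for diabetics), while META keeps a
0.5/year base rate (×6 in diabetics) so diabetic patients accumulate the
250.xx Drug records that identify them. With no independent CIRC draws
there is no accidental CIRC–META co-occurrence, so the expected D/ND
ratio equals the enrichment exactly; the residual bias (renewal edge
effects of order 0.5 visits over ~130) is far below the ≈5% half-width
of the resulting intervals. The packaged experiment uses 5,000-patient
cohorts and 50 replicates, sized so each replicate's counts (a few
thousand) give informative intervals while the whole experiment runs in
well under a minute.

## Numerical and design notes

- All percentages and rates are kept at full precision internally;
  rounding (one decimal for percentages) happens only at rendering.
- Exports: GraphML with node `weight`/`strength` and edge `weight`
  attributes via networkx, plus a plain edge-list TSV with 6-significant-
  digit floats; both deterministic given a seed (stable sort orders
  throughout the generator and pipeline).
- The observation span used for per-patient-per-year rates is always an
  explicit input (`window_years`), defaulting to the calendar length of
  the observation window; the reference table's printed per-patient-
  per-year value corresponds to an effective span of 11 years, and that
  value is used when summarising the printed counts.
- Validation rejects rather than repairs malformed rows, counting each
  rejected row once under its first failing check; parse → write → parse
  is a fixed point on the canonical CSV dialect.
- The qualitative curve checks run at 4,000–6,000 patients, where the
  configured age increments exceed sampling noise by several standard
  errors; the statistics themselves are size-agnostic.

## Known limitations

- The visit-gap intervals are hard-bounded to the 20–70 / 17–40 day
  ranges; cohorts with other rhythms need those bounds relaxed in
  `MorbidityModel`.
- The conditional-binomial ratio interval conditions on the total count
  and treats patient denominators as fixed; patient-level heterogeneity
  beyond Poisson (e.g. frailty) would make it anti-conservative.
- Chapter grouping follows the standard ICD-9-CM chapter boundaries; no
  ICD-10 support.
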