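# Methods

## Study design being modelled

The package reproduces and generalizes a chart-review validation of a coded
diagnosis in primary-care EMRs. The unit of analysis is a patient ever
registered with the index diagnosis code (ICPC-1 L88, inflammatory
arthritis) at age 30 or older — the age floor excludes juvenile arthritis.
The reference standard is manual chart review: a patient counts as a
confirmed case when the specialist correspondence in their record contains
at least one confirmatory diagnosis term (oligoarthritis, polyarthritis,
rheumatoid arthritis, spondyloarthropathy). Sensitivity is out of scope by
design: patients whose true disease never received the index code are not
observable in this design, so only PPV and coverage are computed — no
sensitivity, specificity or NPV.

## Criteria and combinators

Three binary criteria are extracted per patient from routinely coded data:

- **C1** `has_repeat_dmard` — any prescription flagged as a repeat (issued
  without a consultation) whose ATC code falls under the DMARD/biologic
  catalog. No ICPC linkage is required on the prescription: specialists
  initiate these drugs, and the GP's repeat often carries no coded
  indication.
- **C2** `(n_index_contacts ≥ 4 OR has_index_episode) AND
  n_index_linked_non_dmard_rx ≥ 2`. Contacts on the same day count
  separately (each record is one visit); prescriptions are counted as
  distinct records without per-drug or per-date deduplication; an episode
  qualifies regardless of duration or whether it contains contacts.
- **C3** `30 ≤ age_at_first_index_event ≤ 61`, both bounds inclusive. Age is
  completed years (floor), computed from the full birth date. The cutoff of
  61 reflects that older first diagnoses are disproportionately
  osteoarthritis or gout miscoded as IA.

An algorithm is a pair (subset of criteria, threshold k): a patient is
selected when at least k of the chosen criteria hold. The standard report
evaluates the nine combinations — three singles, three pairwise unions
(k=1), and k=3, k=2, k=1 over all three — plus the no-algorithm baseline.

Tunable parameters, with defaults: index code `L88`; minimum age 30 y;
age cutoff 61 y; DMARD/biologic ATC prefixes {L04A, L01BA01, P01BA02,
A07EC01, M01CB, M01CC01}; confirmatory vocabulary as above. ICPC matching is
case-insensitive and whitespace-tolerant, with sub-rubrics (`L88.01`)
matching their parent rubric. Term matching is exact on normalized strings
(lower case, collapsed whitespace) — never substring matching, so synonyms
like "RA" must be added to the vocabulary explicitly. Any occurrence of a
confirmatory term confirms; the model has no notion of a diagnosis being
revised later, because the source data records terms, not term chronology.

## Marginal-table inversion

Per confirmation class the published table gives ten counts: the class
total, |C1|, |C2|, |C3|, |C1∪C2|, |C1∪C3|, |C2∪C3|, |C1∩C2∩C3|, and the
at-least-2 / at-least-1 rows. The reconstruction uses only the first eight:
inclusion–exclusion gives the pairwise intersections, and Möbius inversion
then determines all eight pattern counts (c1,c2,c3) ∈ {0,1}³ per class. The
system is overdetermined (10 constraints, 8 unknowns per class), so the two
at-least-k rows serve as held-out checks: for the shipped table every
residual is exactly zero, which is the internal-consistency proof that a
patient-level cohort reproducing the table exists at all. A negative
reconstructed count is raised as an inconsistency error naming the offending
pattern — no least-squares repair is attempted, because a marginal table
that admits no joint is bad data, not a fitting problem.

`materialize_fixture` then emits one patient record per unit count. Event
scaffolding is minimal but criterion-faithful: every patient gets an
index-coded contact; C1-true patients a repeat methotrexate prescription
(L04AX03); C2-true patients either four index contacts or one contact plus
an index episode (alternating by patient index, so both routes are
exercised), plus two index-linked NSAID prescriptions (M01AE01); C3 is
realized through the age at the index date. Confirmed patients carry the
term "rheumatoid arthritis", unconfirmed ones "osteoarthritis" — the
miscoding channel the study is about. Dates, age jitter within the band, and
the sex shuffle are driven by one seeded generator, so output is
byte-identical per seed; the evaluation metrics are exact functions of the
marginal table and do not depend on the seed.

## Synthetic cohort generator

The generator emulates the study population: n patients, P(confirmed) =
155/219 by default, per-class pattern probabilities equal to the
reconstructed joint normalized, 64% female, age mean 58 / SD 15 at first
index contact. In **exact** mode, class sizes and per-class pattern counts
are largest-remainder apportionments of their expectations — at n=219 with
the default probabilities every expectation is an exact integer, so the
generated cohort reproduces the published table cell-for-cell. In
**stochastic** mode each patient's (class, pattern) cell is drawn i.i.d.
from the configured joint.

**Age model.** Each patient's age must respect their C3 flag (inside 30–61
or at least 62), and the cohort must also match the published overall
moments. These constraints conflict for a single clamped normal: with 47.9%
of the cohort in the band, clamping or conditioning N(58, 15) yields an
overall mean near 61. The generator therefore draws ages from
band-conditional truncated normals whose two locations and common scale are
solved at configuration time from the overall mean/SD moment equations
(closed-form truncated-normal moments, `scipy.optimize.least_squares`).
With the defaults the solution is exact — band locations ≈ 43.2 and ≈ 66.3,
within-band SD ≈ 8.9 — so a large stochastic cohort lands on mean ≈ 58,
SD ≈ 15 up to sampling noise. Ages are rounded to integers and clipped to
their band; the upper band is capped at 95 y. The calibration adapts to any
configured moments and band weight, and raises a config error when a band
with positive probability is empty (e.g. a minimum age above the cutoff).

What the generator does *not* emulate: practice-level clustering (the real
data came from five practices), longitudinal disease progression,
comorbidity, richer prescription histories, or free-text noise. Passing
tests on synthetic cohorts therefore demonstrate correctness of the
criterion logic, combinatorics and calibration — not robustness to the
messiness of real EMR extracts.

## Numerical conventions

- Percentages are displayed rounded half-away-from-zero to one decimal
  (via `decimal.Decimal`), matching the printed table (155/219 → 70.8);
  raw counts and fractions are retained internally. Headline integer
  percentages are nearest-integer displays of the same values (77.86 → 78).
- The PPV of an empty selection is reported as absent (`None`), never 0:
  0/0 is undefined and a silent zero would corrupt PPV/coverage trade-off
  comparisons.
- Largest-remainder apportionment floors the quotas (with a 1e-9 guard
  against representation error on exact expectations) and assigns leftover
  units by descending fractional part, ties broken by category order.
- All randomness flows through one explicitly seeded
  `numpy.random.Generator` per cohort; there is no global random state.

## Problem sizes

The deterministic pipeline runs on the 219-patient cohort in well under a
second. Calibration checks of the stochastic generator use n = 10,000 with
fixed seeds and 3–4 standard-error bands, sizes at which each check runs in
a few seconds while the binomial standard errors are small enough to be
informative.

## Known limitations

- The confirmation rule treats the term set as timeless; a diagnosis later
  revised to gout would still confirm if a confirmatory term ever appears.
- The fixture realizes each criterion pattern through one minimal event
  scaffold per route; it spans both C2 routes but not the full variety of
  real coding behaviour.
- The marginal inverter requires a complete, consistent table for both
  classes; partial tables are not supported.
- Exact-mode apportionment guarantees pattern counts, not joint
  (pattern × sex) or (pattern × age) cross-tabulations beyond what the band
  structure implies.
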