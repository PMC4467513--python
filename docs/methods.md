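# Methods notes

These notes document the modelling choices behind `vacause`: the
assignment procedure and its assumptions, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical conventions at the edges.

## Record inclusion and stratification

Five criteria are applied in order, and an excluded record is logged
with the first one it fails: (1) live birth; (2) died at age 0–59
months; (3) complete VA interview; (4) sufficient age-at-death
information; (5) administered the age-appropriate questionnaire.  Two of
these need operational rules that the surrounding literature leaves
open, and we chose:

- *Complete interview*: an explicit record-level completeness flag when
  the dataset carries one; otherwise a record is complete when fewer
  than 50% of codebook items are missing.  The threshold is a package
  constant (`INCOMPLETE_MISSING_FRACTION`), not a claim about how any
  particular study screened its data.
- *Sufficient age information*: age in days is derivable from the
  days or months fields after unit conversion at 30.4375 days/month
  (hence the 59-month cap at 1826 days).  A record whose age cannot be
  parsed loads with age missing and fails criterion 4 — not criterion 2,
  which only fires on a *known* out-of-range age.
- A missing questionnaire-type field passes criterion 5; only an
  explicit mismatch (e.g. a neonatal death interviewed with the child
  instrument) excludes.

Stratification is exact on the day boundary: 0–27 days is neonatal, 28
days onward is the child stratum.

## Case-definition semantics

Predicates are finite trees over `item_equals`, `item_at_least`,
`duration_in_days` (closed interval in whole days, unbounded max
allowed) and the combinators `all_of` / `any_of` / `none_of`.  Missing
and unreported responses are equivalent and never satisfy a leaf test
("missing as absent"), which makes evaluation conservative: adding
missingness can only suppress diagnoses, never create them.  One
consequence worth knowing: `none_of` arms are satisfied *by* absence, so
a veto item (such as a recent tuberculosis diagnosis in the AIDS screen)
that was simply not asked behaves as "no veto".  We fixed this rule
globally rather than per item: a per-item switch would make evaluation
non-monotone in missingness and was not needed for any shipped
definition.

Thresholds written as "more than 1 month" are implemented as > 30 days
(i.e. a minimum of 31 whole days); the 3–27-day respiratory window is
closed on both ends.

Only the AIDS and diarrhea definitions are fixed by published text.  The
other ~14 definitions shipped in `data/case_definitions.yaml` are
reconstructions in the style of the WHO VA indicators, and deliberately
favour two-sign conjunctions (e.g. preterm birth requires both an early
delivery and small size at birth) over single-sign screens: the
hierarchy's organizing principle is that specific diagnoses come first,
and conjunctive definitions keep the early hierarchy positions from
absorbing deaths on one spuriously reported sign.  They are config, not
code: every definition can be replaced without touching the engine, and
a config that overrides one cause inherits the rest
(`extends_builtin: true`).  The diarrhea screen's symptom-presence-only
variant (for data-quality probes of the "any diarrhea symptom" rate) is
a one-line override of the same kind.

## Hierarchy and the multi-cause group

Within a stratum the order is total, so no tie-breaking rule is needed.
The engine enforces the published structural constraints as hard
validation (child: ARI before meningitis before malaria before AIDS;
neonates: no malaria, no AIDS, sepsis after the diarrhea and ARI
screens); the rest of the shipped order is a reconstruction.  We place
child diarrhea *before* the ARI–meningitis–malaria–AIDS block: the
diarrhea definition (loose stools plus a stool-count threshold) is more
specific than the AIDS screen, several of whose arms are single
symptoms, so evaluating it earlier follows the specific-first principle
and prevents the deliberately sensitive AIDS screen from absorbing
enteric deaths.  Users can supply any order; the validator rejects
constraint-violating configs unless explicitly overridden.

Group semantics: walking the order, the first firing cause outside the
measles/diarrhea/ARI group is final and stops evaluation.  Once a group
member fires, only the remaining group members are still evaluated, and
every firing member enters the provisional set; the rule trace records
exactly the evaluations performed.

Redistribution resolves multi-cause deaths using the CSMFs of the group
causes computed from deaths provisionally assigned to exactly one of
them, restricted to each record's provisional set.  The default
*fractional* mode splits the record's survey weight (deterministic, and
exactly weight-conserving; `final_cause` is set to the largest share
purely for reporting); *sample* mode draws one cause from a seeded
generator.  Both have the same expected CSMFs.  If all relevant
pre-redistribution CSMFs are zero the split is equal.

## CSMF estimation

CSMF(c) = Σᵢ wᵢ fᵢ(c) / Σᵢ wᵢ over the records of the age group, where
fᵢ(c) is record i's allocated fraction on cause c (1 for single-cause
records).  Standard errors use Taylor linearization of this ratio
estimator with the with-replacement PSU approximation: score
contributions zᵢ = wᵢ(fᵢ − p̂)/W are summed within PSU and their
between-PSU variance is accumulated within sampling strata with the
n_h/(n_h−1) factor.  A stratum with a single PSU contributes no
estimable variance (rather than an arbitrary centering rule); SEs are
reported for the algorithm causes, not for mapped categories, because
linearized SEs do not aggregate by simple addition.  Weights are used as
given; the estimator is invariant to their overall scale.

Ranking excludes "unspecified" and the residual "other" groups, because
a ranking of *single causes* is not informative about residual
categories; the exclusion set is an argument.  Ties break by hierarchy
position, then lexicographically.

## Agreement

Per-cause kappa is one-vs-rest on the 2×2 table of the two coders, with
the large-sample variance of Fleiss, Cohen & Everitt (1969).  A cause
never assigned by either coder has chance agreement 1 and an undefined
kappa; it is reported as 0.00 (0.000) with a `degenerate` flag rather
than NaN, matching the usual tabulation convention.  Deaths whose
*pre-redistribution* provisional set has more than one cause are
excluded from kappa, and survey weights are not used (individual-level
concordance); a weighted variant was considered and rejected as
non-standard.  The jackknife alternative SE was not implemented — the
closed form is exact enough at the study sizes involved and is what the
exhaustive oracle test pins down.

## Synthetic data

The generator emulates the *structure* of a DHS-linked national child VA
study: a few hundred deaths, a neonatal/post-neonatal split, lognormal
survey weights (σ = 0.5 by default), a small number of sampling strata
each with a few PSUs, symptom items speaking the case-definition
vocabulary, and an optional comparator coder driven by a cause-confusion
matrix.  Country presets carry the published sample sizes (530/126,
360/121, 188/71) and published stratum CSMFs, renormalized within
stratum, as *scenario parameters*; they are not reproductions of any
study's microdata.

Symptom generation is definition-aware.  For each cause we enumerate the
minimal satisfying assignments of its predicate (for `none_of` arms, the
subtree's items are forbidden rather than set), keep those that the full
hierarchy maps back to exactly that cause, and sample uniformly among
them.  This gives the exact-recovery guarantee: at sensitivity 1 and
false-positive rate 0 the assigned cause equals the true cause for every
record, so estimated CSMFs equal the weighted empirical truth exactly.
Noise then enters in two honest ways: with probability 1 − sensitivity a
record emits no profile and lands in "unspecified" (a uniform scale
loss across causes), and every unreported binary item flips positive
independently at the false-positive rate, which can fire an
earlier-placed definition and misclassify the record.  Because the
published AIDS screen contains single-symptom arms, item-level false
positives inflate it — that is faithful behaviour of the method, not a
generator defect, and it is why the noisy-recovery test checks major
causes (true specified-share ≥ 0.10) on the specified-renormalized
scale.  That test also runs at uniform weights to isolate
misclassification error from weight-induced design effects; weighting
behaviour is covered by the exact-recovery and conservation checks.

Not emulated: symptom covariance beyond the definition structure,
duration/count reporting noise, recall decay with time since death, and
the physician adjudication process (the comparator is a memoryless
confusion matrix).  Passing recovery tests therefore says the *pipeline*
is correct and well-calibrated under its own noise model, not that the
case definitions are valid on real interviews.

A single RNG stream with a fixed per-record draw order (stratum, cause,
weight, PSU, age, detection, profile choice, false-positive vector,
comparator) makes outputs byte-identical for identical scenarios and
seeds.  Extending n re-uses the same stream, so it does not preserve the
earlier records.

## Problem sizes in the shipped checks

The test suite exercises the kappa oracle on all ~14.6k 2×2 tables with
cells 0–10, kappa calibration on 1000 replicates of n = 500, the
hierarchy-vs-naive oracle on 10,000 randomized record×hierarchy pairs,
conservation on 100 scenarios of n = 40, exact recovery at n = 2000 and
noisy recovery at n = 5000; the acceptance script uses n = 2000
(noise-free), n = 530 (study-sized noisy run) and 1000 kappa
replicates.  These sizes give the Monte-Carlo margins stated in each
test while keeping the whole suite in the ten-second range.

## Known limitations

- The reconstructed definitions and orders are *a* faithful
  configuration, not *the* historical one; conclusions about specific
  causes should treat them as editable defaults.
- Linearized SEs assume many PSUs per stratum; with one PSU the variance
  contribution is dropped rather than approximated.
- Fractional redistribution reports a single `final_cause` (largest
  share) for convenience; individual-level analyses of redistributed
  deaths should use the weight fractions, and kappa excludes those
  deaths entirely.
- The CLI round-trips assignments through CSV; rule traces are kept only
  in memory (`CauseAssignment.rule_trace`) and are not serialized there.
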