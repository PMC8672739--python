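# Methods

## The problem and the approach

Cause-of-death (COD) attribution for stillbirths and neonatal deaths in
multi-site studies is done by expert panels reviewing heterogeneous data:
obstetric and neonatal study forms, NICU daily records, placental
pathology, and post-mortem research evaluations (complete diagnostic
autopsy where available, minimally invasive tissue sampling histology, and
multiplexed PCR). Panels are the accepted standard but are slow and prone
to between-panelist and between-meeting inconsistency when each reviewer
sees a different slice of the record.

`perimort` operationalizes a three-part remedy: (1) collapse each case
into a short, deterministic, identically structured report so every
panelist sees the same information; (2) gate panel review on data
completeness and track every case through a fixed workflow; (3) record
each reviewer's COD assignment in a standardized three-axis coding and
reconcile reviewer pairs mechanically, escalating only genuine conflicts.

## Display conventions (the report contract)

The renderer is a pure function of the case record, the derived summary,
and a template; identical inputs give byte-identical text. The contract,
enforced by golden tests:

- `label: value` per field; unanswered fields print `label: not answered`.
  Missing data are always visible — the distinction between "absent
  condition" and "unknown" is clinically material.
- Condition checklists print as positive-findings lists with sub-question
  qualifiers in parentheses (`Hypertensive disorders (Pre-eclampsia)`).
  A fully answered, all-negative list prints `none`; a fully unanswered
  one prints `not answered`. Other negatives are suppressed.
- Always-shown fields (default: GBS test, meconium at delivery — declared
  in config, not hard-coded) print whatever their value, because those
  negatives are themselves diagnostic.
- PCR: one line per tissue sample naming only positive organisms; a clean
  sample prints `tissue: none`. The count of printed organism names equals
  the count of positive results (a conservation property under test).
- An omitted form (consent not obtained, sample not collected) prints
  exactly two lines: section title, `Not available: <reason>`.
- Section 4 (NICU/home death) is skipped entirely for stillbirths.

The 8-section split is an interpretation: the narrative description names
a death summary, obstetric data, a fetal/neonatal description, a
conditional NICU/home section, and trailing research evaluations; we
partition the research block as placental pathology / CDA / MITS histology
/ PCR+laboratory to reach eight, and keep the whole template
config-overridable (8 sections, death summary first, is enforced).

A "page" is defined as 60 rendered lines. The printed-page notion the
2–3-page figure refers to is a print artifact; 60 lines/page is the
package's stated metric and is configurable in the template.

## Derived values

- **Age at death**: floor of elapsed time in whole days. Whether clinical
  usage means calendar days or completed 24-hour periods is genuinely
  ambiguous; floor-of-elapsed-time was chosen and is documented here.
  Death before birth raises a chronology error naming the case.
- **Total NICU days**: inclusive calendar counting (admission day = day 1;
  a same-day admission/discharge counts 1). Matches clinical "days in
  NICU" usage; makes `total ≥ number of stays` an invariant.
- **SGA**: strict inequality at the 10th percentile — the percentile is
  treated as the lower bound of normal, so exactly-at-percentile is not
  small for gestational age.
- **Reference lookups**: exact per completed gestational week, no
  interpolation (published standards are tabulated per completed week).
  Out-of-range weeks or missing sex degrade to a displayed
  `(reference unavailable)`; lookups never abort a report.

Real growth standards (e.g. INTERGROWTH-21st) are not redistributed; the
bundled table is synthetic (monotone by construction, labelled as such in
its provenance field and filename) and any real table can be supplied as
CSV (`ga_weeks, sex, measure, grams`), monotonicity-checked on load.

## Workflow model

States: registered → sent_to_site → site_reviewed → finalized →
assigned_to_pair → determined, with assigned_to_pair → escalated →
panel_determined as the conflict path. Events are named after their
destination state (plus `conflict`); illegal events are rejected without
mutating the entry. Assignment to a reviewer pair requires the
completeness gate: every form complete or omitted-with-reason. Whether
studies eventually review incomplete cases with documented gaps is not
specified by the workflow we model; here the gate simply blocks until the
forms resolve, which is the conservative reading.

Timestamps are caller-supplied, never wall-clock, so ledgers are
reproducible. The ledger is CSV (one row per case: ids, state, dates,
per-form completeness, batch id) and round-trips losslessly; batching
packs cases into groups of 7 by default (midpoint of the observed 6–8
cases per one-hour meeting) without ever splitting a pregnancy across
batches — twins are reviewed together.

## COD coding and reconciliation

Each determination carries up to three primary causes (maternal,
placental, fetal/neonatal — an empty axis means "no cause identified
there"), any number of contributing causes per axis, a certainty grade,
and a preventability judgement. Maternal and fetal/neonatal codes follow
ICD-PM-style groupings; the placental axis is a project extension since
ICD-PM has no placental chapter. The bundled vocabulary is a coarse
starter (5 maternal, 6 placental, 8 fetal/neonatal groups) with no claim
of official-code fidelity; full code books load from CSV.

Certainty is a 3-level ordinal scale — laboratory_confirmed >
clinically_supported > presumed — covering the two evidentiary poles
(laboratory findings vs clinical symptoms) plus a default; the
reconciled grade is the weaker of the pair's two (conservative).

Pair reconciliation: agreement requires all three primaries to match
(both-empty counts as agreement) and, by default, matching preventability;
any primary conflict escalates, naming the disagreeing axes. Contributing
causes never escalate under the default policy — the union is kept, so no
reviewer's noted cause is lost; `intersection` is available via
`ReconcilePolicy`. Reconciliation is symmetric in its arguments (ensured
by canonical sorting of merged contributing causes and reviewer ids) and
is property-tested against a brute-force oracle that enumerates every
primary-assignment pair over a small vocabulary. Escalations resolve via
`record_panel_resolution`, which re-validates the panel's determination;
every final determination therefore traces to either one agreeing pair or
one escalation plus one resolution.

## Synthetic data: what it does and does not emulate

The generator exists so every pipeline stage is testable without real
data. Defaults encode the study conditions: an exact 50/50
stillbirth/neonatal-death split (the study enrolled 700 of each; the split
is allocated deterministically, not by Bernoulli draws, so configured
counts reproduce exactly), 3% twin pregnancies, 5% field-level
missingness, form-level omission rates of 60% (CDA — only hospital
neonatal deaths were eligible for autopsy; stillbirths always omit it),
15% (MITS), 15% (PCR) and 5% (placenta) with reasons drawn from
{consent not obtained, sample not collected}, NICU stay lengths geometric
(p=0.35, mean ≈ 2.9 days, 1–2 stays per admitted neonate), 2% PCR
positivity per organism, and a 20% reviewer-pair disagreement rate. Where
the emulated study reports no value (twin rate, missingness, prevalences,
PCR positivity), defaults were set once at values a perinatal
epidemiologist would call plausible for a South-Asian referral-hospital
preterm cohort, and are all configurable.

Reproducibility: one cohort seed fans out into independent per-case
substreams, so case *i* is identical whether generated alone or within
any cohort. The organism panel mixes 20 genuine perinatal pathogens with
60 placeholder names (`Synthetic organism NN`) to fill the 80-slot card.

What passing tests on synthetic data do **not** show: the generator draws
conditions independently (no comorbidity structure), uses uncalibrated
prevalences, makes no attempt to reproduce any real cause-of-death
distribution, and its reference table is invented. Tests on it establish
the *mechanics* — validation, rendering rules, gating, reconciliation —
not epidemiological realism.

## Problem sizes and numerical notes

The test suite and the acceptance script run at deliberately small scale:
cohorts of 10–400 cases for unit/property tests, 50 cases for the
report-length summary, and the full 1400-case manifest (types and ids
only, no case bodies) for the cohort-split check; these sizes make the
whole suite run in seconds while still exercising every code path.
Everything numeric is exact integer/rational arithmetic except the mean
page count; no tolerances are needed. Degenerate inputs are pinned by
tests: zero report lines → zero pages; an empty stay list → zero NICU
days; an empty tally → an empty table; `paginate` rejects a page size
below 1 and `estimate_panel_hours` a non-positive rate.

## Known limitations

- The form inventory is a configurable stand-in, not a reconstruction of
  any study's actual variable list (which is not public).
- The renderer emits plain UTF-8 text only (golden-testable); no PDF.
- XLSX ledger export is not implemented; the CSV ledger is canonical.
- No algorithmic COD inference (no verbal-autopsy-style modeling): the
  package records and reconciles human judgments only.
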