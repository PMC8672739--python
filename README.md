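# perimort

Standardized case reports and cause-of-death (COD) panel workflow for
stillbirth and neonatal-death surveillance studies.

Determining why a stillbirth or neonatal death occurred usually requires an
expert panel to weigh data from many sources — obstetric history, the
neonatal clinical course, placental pathology, and post-mortem evaluations
such as minimally invasive tissue sampling (MITS) histology and multiplexed
PCR panels. Reviewing raw records case by case is slow and inconsistent.
`perimort` implements the infrastructure that makes such reviews fast and
unbiased:

- **Case data model** (`perimort.case_model`) — a validated per-case record
  covering maternal/obstetric forms, fetal/neonatal forms, NICU daily
  records, placental pathology, complete diagnostic autopsy (CDA), MITS
  histology, and PCR TaqMan-card results (80 organisms × up to 8 tissue
  samples), with explicit "not answered" semantics and per-form
  completeness statuses.
- **Derived values** (`perimort.derivations`) — age at death, total NICU
  days (inclusive counting), and comparisons against growth-reference
  tables: the 10th-percentile birthweight for gestational age and sex
  (small-for-gestational-age = strictly below it) and the mean placental
  weight for gestational age.
- **Report renderer** (`perimort.report_renderer`) — a deterministic
  plain-text report in 8 fixed sections (~1–3 pages at 60 lines/page).
  Missing variables print as `not answered`; all-negative checklists
  collapse to `none`; always-informative negatives (GBS test, meconium at
  delivery) are shown regardless of result; only positive PCR results are
  listed; an omitted form prints only its section title and the reason.
- **Workflow tracker** (`perimort.workflow_tracker`) — a state machine from
  registration through site review, finalization, reviewer-pair assignment
  (gated on completeness), and determination or full-panel escalation, with
  a lossless CSV ledger and multiple-birth-aware batching.
- **COD panel** (`perimort.cod_panel`) — reviewer determinations on three
  axes (primary maternal, placental, and fetal/neonatal cause; the coding
  follows ICD-PM with a project placental extension), contributing causes,
  a 3-level certainty grade, and preventability; pair reconciliation
  escalates any primary-cause conflict to the full panel.
- **Synthetic cohorts** (`perimort.synthetic_cases`) — a seeded generator
  of realistic case records, reference tables, and paired reviewer
  determinations, so the whole pipeline is testable without any real data.

## Worked example

```python
from perimort import (CaseType, GeneratorConfig, assemble_report,
                      derive_summary, generate_cohort)

cohort = generate_cohort(GeneratorConfig(n_cases=20, seed=11),
                         with_determinations=False)
case = next(c for c in cohort.cases
            if c.case_type is CaseType.neonatal_death and c.nicu_stays)
report = assemble_report(case, derive_summary(case, cohort.reference))
print(report.text)
```

prints (abridged):

```
Standardized case report — C00003

1. Summary of death
...
birth weight (grams): not answered
gestational age (weeks): 33
...
2. Obstetric history and maternal course
...
GBS test: negative
meconium at delivery: present
Medical and obstetric disorders: none
Positive tests: Hepatitis B

4. NICU course and home death
NICU stay 1: admitted 2021-04-12, discharged 2021-04-13 (2 days)
Day 1: signs/symptoms: grunting, hypothermia; treatments: surfactant
Day 2: diagnoses: Asphyxia; treatments: oxygen, surfactant

5. Placental pathology
placental weight (grams): 307
placental weight vs reference mean (grams): 307 vs 304
...
8. PCR and laboratory results
liver: Synthetic organism 52
blood: none
CSF: Group B Streptococcus
placenta: none
```

Reading the output: `not answered` marks genuinely missing data (distinct
from an answered negative); `Medical and obstetric disorders: none` means
every checklist question was answered "no"; the placental line puts the
observed 307 g next to the reference mean of 304 g for 33 weeks; and the
PCR section lists only positive organisms per tissue (`blood: none` = all
80 organisms negative on that sample). This report is 58 lines, i.e. 1
page at 60 lines/page.

See `examples/` for runnable scripts covering cohort generation, report
rendering, the workflow ledger, and determination reconciliation, and try
the CLI: `perimort synth --n 20 --seed 11 -o cohort/`, then
`perimort validate cohort/cases` and
`perimort render cohort/cases/C00001.json --refs cohort/refs.csv`.

## Caveats

The bundled reference table (`src/perimort/data/synthetic_reference_table.csv`)
is a clearly labelled **synthetic** monotone stand-in, not published growth
standards — load your own CSV for real analyses. Likewise the bundled cause
vocabulary is a coarse starter list, not an official ICD-PM code book.
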