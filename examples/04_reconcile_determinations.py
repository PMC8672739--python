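"""Reconcile paired reviewer determinations and tally final causes.

Generates a cohort with paired determinations (20% of pairs disagree on a
primary axis), reconciles each pair, resolves the escalations as a mock
full panel would (here: adopting the first reviewer's assignment), and
tabulates the primary fetal/neonatal causes.
"""

from perimort import (
    Axis,
    FinalDetermination,
    GeneratorConfig,
    generate_cohort,
    load_vocabulary,
    reconcile_pair,
    record_panel_resolution,
    tally_causes,
)

cohort = generate_cohort(GeneratorConfig(n_cases=60, seed=11))
vocab = load_vocabulary()

finals, escalated = [], 0
for a, b in cohort.determinations.values():
    result = reconcile_pair(a, b)
    if isinstance(result, FinalDetermination):
        finals.append(result)
    else:
        escalated += 1
        resolution = result.determinations[0].model_copy(
            update={"reviewer_id": "FULL-PANEL"})
        finals.append(record_panel_resolution(result, resolution, vocab))

print(f"{len(finals) - escalated} pair agreements, {escalated} escalations "
      f"resolved by the full panel")
print(tally_causes(finals, Axis.fetal_neonatal).to_string())
# Counts are primary fetal/neonatal causes across all final determinations;
# codes are the bundled starter vocabulary's coarse ICD-PM-style groups.
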