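# Default 8-section report template.
#
# The section split is a documented interpretation: the narrative names a
# death summary, obstetric data, fetal/neonatal description, a NICU/home
# section for admitted or home deaths, and the research evaluations (CDA,
# MITS, laboratory) last; the research block is split here into placental
# pathology, CDA, MITS histology, and PCR/laboratory to reach 8 sections.
# Override with your own YAML to change titles, ordering inside the
# constraints (8 sections, death summary first), or the always-shown list.
lines_per_page: 60
always_shown:
  - "GBS test"
  - "meconium at delivery"
sections:
  - index: 1
    title: "1. Summary of death"
    source: death_summary
    form: birth_characteristics
  - index: 2
    title: "2. Obstetric history and maternal course"
    source: obstetric
    form: obstetric
  - index: 3
    title: "3. Fetal/neonatal description"
    source: fetal_neonatal
    form: fetal_neonatal
  - index: 4
    title: "4. NICU course and home death"
    source: nicu
    form: nicu
    applicable: nicu_or_home
  - index: 5
    title: "5. Placental pathology"
    source: placenta
    form: placenta
  - index: 6
    title: "6. Complete diagnostic autopsy"
    source: cda
    form: cda
  - index: 7
    title: "7. MITS histology"
    source: mits
    form: mits
  - index: 8
    title: "8. PCR and laboratory results"
    source: pcr
    form: pcr
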