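# Default study-form inventory.
#
# The variables deemed essential for cause-of-death review are a project
# decision, not a fixed standard, so this inventory is configuration: it
# lists the forms, the fields each must carry, and the condition checklists
# rendered as positive-findings lists.  "always_shown" names the fields
# displayed regardless of a negative/absent result.
version: "1.0"
pcr_panel_size: 80
pcr_max_samples: 8
always_shown:
  - "GBS test"
  - "meconium at delivery"
forms:
  - name: birth_characteristics
    title: "Summary of death"
    required_fields:
      - "birth weight (grams)"
      - "gestational age (weeks)"
      - "gender"
      - "date/time of delivery"
      - "date/time of death"
      - "multiple-birth order"
      - "place of death"
  - name: obstetric
    title: "Obstetric history and maternal course"
    required_fields:
      - "maternal age (years)"
      - "parity"
      - "antenatal care visits"
      - "mode of delivery"
      - "GBS test"
      - "meconium at delivery"
    condition_lists:
      "Medical and obstetric disorders":
        - "Hypertensive disorders"
        - "Clinical chorioamnionitis"
        - "Antepartum hemorrhage"
        - "Diabetes mellitus"
        - "Severe anemia"
        - "Obstructed labor"
      "Positive tests":
        - "Rh factor"
        - "Active tuberculosis"
        - "Syphilis"
        - "HIV"
        - "Hepatitis B"
        - "Malaria smear"
  - name: fetal_neonatal
    title: "Fetal/neonatal description"
    required_fields:
      - "Apgar score (5 min)"
      - "resuscitation attempted"
      - "congenital anomaly noted"
    condition_lists:
      "Neonatal conditions":
        - "Respiratory distress syndrome"
        - "Asphyxia"
        - "Suspected sepsis"
        - "Jaundice"
        - "Seizures"
        - "Hypothermia"
  - name: nicu
    title: "NICU course and home death"
    required_fields: []
  - name: placenta
    title: "Placental pathology"
    required_fields:
      - "placental weight (grams)"
  - name: cda
    title: "Complete diagnostic autopsy"
    required_fields: []
  - name: mits
    title: "MITS histology"
    required_fields: []
  - name: pcr
    title: "PCR and laboratory results"
    required_fields: []
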