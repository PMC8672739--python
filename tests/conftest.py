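"""Shared fixtures: a hand-built complete case of each type, the bundled
configs, and a tiny hand-written reference table with known rows."""

from datetime import date

import pytest

from perimort import (
    CaseRecord,
    CaseType,
    ConditionEntry,
    FieldValue,
    FormSection,
    FormStatus,
    FormStatusValue,
    HistologyFinding,
    NICUDayRecord,
    NICUStay,
    PCRResult,
    PCRSampleResult,
    ReferenceTable,
    load_form_inventory,
    load_template,
    load_vocabulary,
)
from perimort.case_model import PlacentaSection
from perimort.synthetic_cases import organism_panel


@pytest.fixture(scope="session")
def inventory():
    return load_form_inventory()


@pytest.fixture(scope="session")
def template():
    return load_template()


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def tiny_reference():
    """Hand-written table: (32 weeks, male) -> 1200 g, placenta 36 wk -> 450 g."""
    male = {30: 1000, 31: 1100, 32: 1200, 33: 1300, 34: 1400, 35: 1500, 36: 1600}
    bw = {}
    for w, g in male.items():
        bw[(w, "male")] = g
        bw[(w, "female")] = g - 50
    placental = {w: 450 - 10 * (36 - w) for w in range(30, 37)}
    table = ReferenceTable(birthweight_p10=bw, placental_mean=placental,
                           provenance="hand-written test fixture")
    table.validate_monotone()
    return table


def _pcr_sample(sample_id: str, tissue: str, positives: list[str]) -> PCRSampleResult:
    results = {org: (PCRResult.positive if org in positives else PCRResult.negative)
               for org in organism_panel(80)}
    return PCRSampleResult(sample_id=sample_id, tissue=tissue,
                           organism_results=results)


def make_complete_case(case_type: CaseType = CaseType.stillbirth,
                       case_id: str = "T0001",
                       pregnancy_id: str = "PT001",
                       inventory=None) -> CaseRecord:
    """A fully populated case whose every form is complete (or, for the
    stillbirth autopsy form, omitted with a documented reason)."""
    inventory = inventory or load_form_inventory()
    is_nnd = case_type is CaseType.neonatal_death
    birth = "2020-03-01T08:00:00"
    death = "2020-03-04T07:00:00" if is_nnd else birth

    nicu = []
    if is_nnd:
        nicu = [NICUStay(
            admission_date=date(2020, 3, 1), discharge_date=date(2020, 3, 3),
            days=[
                NICUDayRecord(day_index=1, date=date(2020, 3, 1),
                              diagnoses=["Respiratory distress syndrome"],
                              treatments=["CPAP"]),
                NICUDayRecord(day_index=2, date=date(2020, 3, 2),
                              signs_symptoms=["grunting"], treatments=["oxygen"]),
                NICUDayRecord(day_index=3, date=date(2020, 3, 3),
                              appearance=["cyanotic"], treatments=["surfactant"]),
            ])]

    statuses = []
    for form in inventory.form_names:
        if form == "cda" and not is_nnd:
            statuses.append(FormStatus(form_name=form, status=FormStatusValue.omitted,
                                       omission_reason="sample not collected"))
        else:
            statuses.append(FormStatus(form_name=form, status=FormStatusValue.complete))

    return CaseRecord(
        case_id=case_id,
        pregnancy_id=pregnancy_id,
        case_type=case_type,
        site="India-A",
        birth_characteristics=[
            FieldValue(label="birth weight (grams)", value=1100),
            FieldValue(label="gestational age (weeks)", value=32),
            FieldValue(label="gender", value="male"),
            FieldValue(label="date/time of delivery", value=birth),
            FieldValue(label="date/time of death", value=death),
            FieldValue(label="multiple-birth order", value="1 of 1"),
            FieldValue(label="place of death",
                       value="hospital" if is_nnd else "intrauterine"),
        ],
        obstetric=FormSection(
            fields=[
                FieldValue(label="maternal age (years)", value=27),
                FieldValue(label="parity", value=2),
                FieldValue(label="antenatal care visits", value=4),
                FieldValue(label="mode of delivery", value="vaginal"),
                FieldValue(label="GBS test", value="negative"),
                FieldValue(label="meconium at delivery", value="absent"),
            ],
            condition_lists={
                "Medical and obstetric disorders": [
                    ConditionEntry(name="Hypertensive disorders", present=True,
                                   qualifier="Pre-eclampsia"),
                    ConditionEntry(name="Clinical chorioamnionitis", present=True),
                    ConditionEntry(name="Antepartum hemorrhage"),
                    ConditionEntry(name="Diabetes mellitus"),
                    ConditionEntry(name="Severe anemia"),
                    ConditionEntry(name="Obstructed labor"),
                ],
                "Positive tests": [
                    ConditionEntry(name="Rh factor", present=True),
                    ConditionEntry(name="Active tuberculosis", present=True),
                    ConditionEntry(name="Syphilis"),
                    ConditionEntry(name="HIV"),
                    ConditionEntry(name="Hepatitis B"),
                    ConditionEntry(name="Malaria smear"),
                ],
            }),
        fetal_neonatal=FormSection(
            fields=[
                FieldValue(label="Apgar score (5 min)", value=0 if not is_nnd else 4),
                FieldValue(label="resuscitation attempted",
                           value="yes" if is_nnd else "no"),
                FieldValue(label="congenital anomaly noted", value="no"),
            ],
            condition_lists={
                "Neonatal conditions": [
                    ConditionEntry(name="Respiratory distress syndrome",
                                   present=is_nnd),
                    ConditionEntry(name="Asphyxia", present=True),
                    ConditionEntry(name="Suspected sepsis"),
                    ConditionEntry(name="Jaundice"),
                    ConditionEntry(name="Seizures"),
                    ConditionEntry(name="Hypothermia"),
                ],
            }),
        nicu_stays=nicu,
        cda=([HistologyFinding(organ="lung", finding="hyaline membrane disease")]
             if is_nnd else []),
        mits_histology=[
            HistologyFinding(organ="lung", finding="hyaline membrane disease"),
            HistologyFinding(organ="liver", normal=True),
            HistologyFinding(organ="brain", normal=True),
        ],
        pcr=[
            _pcr_sample("S1", "lung", ["Group B Streptococcus", "Escherichia coli"]),
            _pcr_sample("S2", "blood", []),
        ],
        placenta=PlacentaSection(
            weight=FieldValue(label="placental weight (grams)", value=210),
            findings=[HistologyFinding(
                organ="placenta", finding="maternal vascular malperfusion lesions")],
        ),
        form_statuses=statuses,
    )


@pytest.fixture
def stillbirth_case(inventory):
    return make_complete_case(CaseType.stillbirth, inventory=inventory)


@pytest.fixture
def neonatal_case(inventory):
    return make_complete_case(CaseType.neonatal_death, case_id="T0002",
                              pregnancy_id="PT002", inventory=inventory)
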