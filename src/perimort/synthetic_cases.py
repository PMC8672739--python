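"""Seeded generator of synthetic study data.

No real study data are distributed, so this module fabricates everything
the rest of the package consumes: case records with realistic structure
and missingness, growth-reference tables, and paired reviewer
determinations.  All names, prevalences and reference values are synthetic:
the condition and organism lists mix genuine perinatal vocabulary
(pre-eclampsia, clinical chorioamnionitis, group B Streptococcus, hyaline
membrane disease, asphyxia) with placeholder organisms used purely to fill
the 80-slot PCR card, and the reference table is a monotone synthetic
stand-in for published growth standards, not a copy of them.

Reproducibility: a single cohort seed is fanned out into independent
per-case substreams (``SeedSequence(seed).spawn``-style keys), so case *i*
of a given config is byte-identical whether generated alone or as part of
the cohort, and regardless of cohort size.

The default configuration mirrors the study conditions: an even split of
stillbirths and neonatal deaths (the study enrolled 700 of each), a few
percent twin pregnancies reviewed together, neonatal deaths carrying one or
two NICU stays with daily records, up to 8 PCR samples per case on an
80-organism card, and form-level omissions documented as "consent not
obtained" or "sample not collected".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .case_model import (
    CaseRecord,
    CaseType,
    ConditionEntry,
    FieldValue,
    FormInventory,
    FormSection,
    FormStatus,
    FormStatusValue,
    HistologyFinding,
    NICUDayRecord,
    NICUStay,
    PCRResult,
    PCRSampleResult,
    PlacentaSection,
    load_form_inventory,
)
from .cod_panel import (
    AXIS_ORDER,
    Axis,
    Certainty,
    ContributingCause,
    Determination,
    Preventability,
    VocabularySet,
    load_vocabulary,
)
from .derivations import ReferenceTable

OMISSION_REASONS = ("consent not obtained", "sample not collected")

TISSUES = ("lung", "liver", "brain", "blood", "CSF", "placenta", "rectal",
           "nasopharyngeal")

# Real perinatal pathogens up front; the rest of the 80-organism card is
# filled with clearly synthetic placeholder names.
_REAL_ORGANISMS = (
    "Group B Streptococcus", "Escherichia coli", "Klebsiella pneumoniae",
    "Acinetobacter baumannii", "Staphylococcus aureus", "Enterococcus faecalis",
    "Streptococcus pneumoniae", "Haemophilus influenzae", "Listeria monocytogenes",
    "Ureaplasma urealyticum", "Mycoplasma hominis", "Chlamydia trachomatis",
    "Treponema pallidum", "Cytomegalovirus", "Herpes simplex virus",
    "Parvovirus B19", "Rubella virus", "Enterovirus", "Candida albicans",
    "Toxoplasma gondii",
)


def organism_panel(size: int = 80) -> list[str]:
    """The PCR card's organism list: real perinatal pathogens padded with
    synthetic placeholders to the configured card size."""
    names = list(_REAL_ORGANISMS[:size])
    i = len(names) + 1
    while len(names) < size:
        names.append(f"Synthetic organism {i:02d}")
        i += 1
    return names


class GeneratorConfig(BaseModel):
    """Knobs for the synthetic cohort.

    Defaults are the study conditions: a 50/50 stillbirth / neonatal-death
    split, ~3% twin pregnancies, modest field-level missingness, and
    form-level omission rates highest for the autopsy-based evaluations.
    """

    n_cases: int = 100
    stillbirth_fraction: float = 0.5
    twin_rate: float = 0.03
    field_absent_prob: float = 0.05
    form_omission_probs: dict[str, float] = Field(default_factory=lambda: {
        "cda": 0.6, "mits": 0.15, "pcr": 0.15, "placenta": 0.05})
    form_missing_probs: dict[str, float] = Field(default_factory=dict)
    condition_prevalences: dict[str, float] = Field(default_factory=lambda: {
        "Hypertensive disorders": 0.15,
        "Clinical chorioamnionitis": 0.10,
        "Antepartum hemorrhage": 0.08,
        "Diabetes mellitus": 0.06,
        "Severe anemia": 0.12,
        "Obstructed labor": 0.05,
        "Rh factor": 0.05,
        "Active tuberculosis": 0.02,
        "Syphilis": 0.02,
        "HIV": 0.01,
        "Hepatitis B": 0.02,
        "Malaria smear": 0.03,
        "Respiratory distress syndrome": 0.35,
        "Asphyxia": 0.25,
        "Suspected sepsis": 0.20,
        "Jaundice": 0.15,
        "Seizures": 0.08,
        "Hypothermia": 0.10,
    })
    pcr_positive_rate: float = 0.02
    pcr_not_tested_rate: float = 0.03
    nicu_stay_geom_p: float = 0.35
    home_death_rate: float = 0.08
    disagreement_rate: float = 0.2
    seed: int = 42

    @field_validator("n_cases")
    @classmethod
    def _n_pos(cls, v):
        if v < 1:
            raise ValueError("n_cases must be >= 1")
        return v

    @field_validator("stillbirth_fraction", "twin_rate", "field_absent_prob",
                     "pcr_positive_rate", "pcr_not_tested_rate",
                     "nicu_stay_geom_p", "home_death_rate", "disagreement_rate")
    @classmethod
    def _prob(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {v} outside [0, 1]")
        return v

    @field_validator("form_omission_probs", "form_missing_probs",
                     "condition_prevalences")
    @classmethod
    def _prob_map(cls, v):
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} for {k!r} outside [0, 1]")
        return v


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------


def generate_reference_tables(seed: int, male_offset_g: float = 40.0,
                              weeks: range = range(22, 43)) -> ReferenceTable:
    """A synthetic, monotone growth-reference table for weeks 22-42.

    Female 10th-percentile birthweights rise by a random positive increment
    each week; male values sit a fixed offset above female ones, so the
    male curve is monotone too and male >= female at every week.  Placental
    mean weights rise the same way.  Shapes are plausible for the preterm
    range; the numbers are NOT published standards.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EF]))
    bw: dict[tuple[int, str], float] = {}
    female = 380.0 + rng.uniform(0, 20)
    for w in weeks:
        bw[(w, "female")] = round(female, 0)
        bw[(w, "male")] = round(female + male_offset_g, 0)
        female += rng.uniform(45, 95)
    pl: dict[int, float] = {}
    mean = 140.0 + rng.uniform(0, 15)
    for w in weeks:
        pl[w] = round(mean, 0)
        mean += rng.uniform(10, 22)
    table = ReferenceTable(birthweight_p10=bw, placental_mean=pl,
                           provenance=f"synthetic (seed={seed})")
    table.validate_monotone()
    return table


# ---------------------------------------------------------------------------
# cohort plan: case types, pregnancies, twins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _PlanRow:
    case_type: CaseType
    pregnancy_id: str
    birth_order: int
    n_siblings: int


def _cohort_plan(config: GeneratorConfig) -> list[_PlanRow]:
    """Deterministic assignment of case types and pregnancies.

    Case-type counts are exact (``round(n * stillbirth_fraction)``
    stillbirths), not Bernoulli draws, so a configured split is reproduced
    exactly; twin membership is a seeded draw per pregnancy.
    """
    n = config.n_cases
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
    n_still = int(round(n * config.stillbirth_fraction))
    types = np.array([CaseType.stillbirth] * n_still
                     + [CaseType.neonatal_death] * (n - n_still), dtype=object)
    rng.shuffle(types)

    rows: list[_PlanRow] = []
    preg = 0
    i = 0
    while i < n:
        preg += 1
        pid = f"P{preg:05d}"
        is_twin = (i + 1 < n) and (rng.random() < config.twin_rate)
        size = 2 if is_twin else 1
        for order in range(1, size + 1):
            rows.append(_PlanRow(case_type=types[i], pregnancy_id=pid,
                                 birth_order=order, n_siblings=size))
            i += 1
    return rows


# ---------------------------------------------------------------------------
# single-case generation
# ---------------------------------------------------------------------------


def _case_rng(config: GeneratorConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 7, index]))


def _site_for(config: GeneratorConfig, index: int) -> str:
    # own substream so the manifest-only path reproduces the same site
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, index]))
    return str(rng.choice(["India-A", "India-B", "Pakistan-A"]))


def _maybe(rng, config: GeneratorConfig, label: str, value) -> FieldValue:
    """An answered field, unless the field-missingness draw says otherwise."""
    if rng.random() < config.field_absent_prob:
        return FieldValue(label=label)
    return FieldValue(label=label, value=value)


def _conditions(rng, config: GeneratorConfig, names: list[str],
                case_type: CaseType,
                qualifiers: Optional[dict[str, list[str]]] = None
                ) -> list[ConditionEntry]:
    qualifiers = qualifiers or {}
    out = []
    for name in names:
        if rng.random() < config.field_absent_prob:
            out.append(ConditionEntry(name=name, answered=False))
            continue
        p = config.condition_prevalences.get(name, 0.05)
        if case_type is CaseType.stillbirth and name == "Respiratory distress syndrome":
            p = 0.0  # RDS is a disease of live-born infants
        present = bool(rng.random() < p)
        qual = None
        if present and name in qualifiers and rng.random() < 0.6:
            qual = str(rng.choice(qualifiers[name]))
        out.append(ConditionEntry(name=name, present=present, qualifier=qual))
    return out


_DIAGNOSES = ["Respiratory distress syndrome", "Sepsis", "Asphyxia", "Jaundice",
              "Necrotizing enterocolitis", "Intraventricular hemorrhage"]
_APPEARANCE = ["lethargic", "pale", "cyanotic", "mottled"]
_SIGNS = ["grunting", "apnea", "poor feeding", "fever", "hypothermia"]
_TREATMENTS = ["CPAP", "oxygen", "antibiotics", "phototherapy", "surfactant",
               "IV fluids"]


def _pick(rng, pool: list[str], p_any: float) -> list[str]:
    if rng.random() >= p_any:
        return []
    k = int(rng.integers(1, 3))
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return [pool[i] for i in sorted(idx)]


def _nicu_stays(rng, config: GeneratorConfig, birth_dt: datetime,
                death_dt: datetime) -> list[NICUStay]:
    stays: list[NICUStay] = []
    n_stays = 1 if rng.random() < 0.8 else 2
    cursor = birth_dt.date()
    last_day = death_dt.date()
    for s in range(n_stays):
        if cursor > last_day:
            break
        length = int(min(rng.geometric(config.nicu_stay_geom_p),
                         (last_day - cursor).days + 1))
        admission = cursor
        discharge = admission + timedelta(days=length - 1)
        days = []
        for di in range(length):
            d = admission + timedelta(days=di)
            days.append(NICUDayRecord(
                day_index=di + 1, date=d,
                diagnoses=_pick(rng, _DIAGNOSES, 0.7),
                appearance=_pick(rng, _APPEARANCE, 0.5),
                signs_symptoms=_pick(rng, _SIGNS, 0.6),
                treatments=_pick(rng, _TREATMENTS, 0.8),
            ))
        stays.append(NICUStay(admission_date=admission, discharge_date=discharge,
                              days=days))
        cursor = discharge + timedelta(days=int(rng.integers(1, 4)))
    return stays


def _histology(rng, organs: dict[str, list[str]], p_normal: float
               ) -> list[HistologyFinding]:
    out = []
    for organ, pool in organs.items():
        if rng.random() < p_normal:
            out.append(HistologyFinding(organ=organ, normal=True))
        else:
            out.append(HistologyFinding(organ=organ,
                                        finding=str(rng.choice(pool))))
    return out


_MITS_ORGANS = {
    "lung": ["hyaline membrane disease", "aspirated amniotic fluid and meconium",
             "congestion", "pneumonia"],
    "liver": ["congestion", "hepatocellular necrosis"],
    "brain": ["hypoxic-ischemic changes", "germinal matrix hemorrhage"],
}

_PLACENTA_FINDINGS = ["maternal vascular malperfusion lesions",
                      "acute chorioamnionitis", "villous infarction",
                      "retroplacental hemorrhage"]


def _pcr_samples(rng, config: GeneratorConfig, panel: list[str]
                 ) -> list[PCRSampleResult]:
    n_samples = int(rng.integers(1, 9))
    tissue_idx = rng.choice(len(TISSUES), size=n_samples, replace=False)
    samples = []
    for j, ti in enumerate(sorted(tissue_idx), start=1):
        results = {}
        for org in panel:
            u = rng.random()
            if u < config.pcr_positive_rate:
                results[org] = PCRResult.positive
            elif u < config.pcr_positive_rate + config.pcr_not_tested_rate:
                results[org] = PCRResult.not_tested
            else:
                results[org] = PCRResult.negative
        samples.append(PCRSampleResult(sample_id=f"S{j}", tissue=TISSUES[ti],
                                       organism_results=results))
    return samples


def generate_case(config: GeneratorConfig, index: int,
                  inventory: Optional[FormInventory] = None,
                  _plan: Optional[list[_PlanRow]] = None) -> CaseRecord:
    """Generate case ``index`` of the configured cohort.

    Deterministic in ``(config.seed, index)``; the result always passes
    :func:`perimort.case_model.validate_case` against the inventory used.
    """
    if not 0 <= index < config.n_cases:
        raise IndexError(f"index {index} outside cohort of {config.n_cases}")
    inventory = inventory or load_form_inventory()
    plan = _plan if _plan is not None else _cohort_plan(config)
    row = plan[index]
    rng = _case_rng(config, index)
    case_type = row.case_type
    case_id = f"C{index + 1:05d}"

    # form statuses first: omitted forms carry no data
    statuses: list[FormStatus] = []
    for form in inventory.form_names:
        p_omit = config.form_omission_probs.get(form, 0.0)
        p_miss = config.form_missing_probs.get(form, 0.0)
        if form == "cda" and case_type is CaseType.stillbirth:
            # the autopsy arm only enrolled hospital neonatal deaths
            statuses.append(FormStatus(form_name=form, status=FormStatusValue.omitted,
                                       omission_reason="sample not collected"))
            continue
        u = rng.random()
        if u < p_omit:
            statuses.append(FormStatus(
                form_name=form, status=FormStatusValue.omitted,
                omission_reason=str(rng.choice(OMISSION_REASONS))))
        elif u < p_omit + p_miss:
            statuses.append(FormStatus(form_name=form, status=FormStatusValue.missing))
        else:
            statuses.append(FormStatus(form_name=form, status=FormStatusValue.complete))
    status_of = {s.form_name: s.status for s in statuses}

    ga = int(rng.integers(24, 37)) if case_type is CaseType.neonatal_death \
        else int(rng.integers(22, 41))
    sex = str(rng.choice(["male", "female"]))
    bw = int(max(200, 110 * (ga - 20) + rng.normal(0, 140)))

    birth_day = date(2019, 1, 1) + timedelta(days=int(rng.integers(0, 900)))
    birth_dt = datetime.combine(birth_day, datetime.min.time()) \
        + timedelta(minutes=int(rng.integers(0, 1440)))
    home = case_type is CaseType.neonatal_death and rng.random() < config.home_death_rate
    if case_type is CaseType.stillbirth:
        death_dt = birth_dt
    else:
        age_days = int(min(rng.geometric(0.12) - 1, 27))
        death_dt = birth_dt + timedelta(days=age_days,
                                        minutes=int(rng.integers(0, 1440)))

    birth_fields = [
        _maybe(rng, config, "birth weight (grams)", bw),
        _maybe(rng, config, "gestational age (weeks)", ga),
        _maybe(rng, config, "gender", sex),
        _maybe(rng, config, "date/time of delivery", birth_dt.isoformat()),
        _maybe(rng, config, "date/time of death", death_dt.isoformat()),
        FieldValue(label="multiple-birth order",
                   value=f"{row.birth_order} of {row.n_siblings}"),
        _maybe(rng, config, "place of death",
               "home" if home else ("hospital" if case_type is CaseType.neonatal_death
                                    else "intrauterine")),
    ]

    obstetric = FormSection(
        fields=[
            _maybe(rng, config, "maternal age (years)", int(rng.integers(18, 41))),
            _maybe(rng, config, "parity", int(rng.integers(0, 6))),
            _maybe(rng, config, "antenatal care visits", int(rng.integers(0, 9))),
            _maybe(rng, config, "mode of delivery",
                   str(rng.choice(["vaginal", "cesarean"]))),
            _maybe(rng, config, "GBS test",
                   "positive" if rng.random() < 0.15 else "negative"),
            _maybe(rng, config, "meconium at delivery",
                   "present" if rng.random() < 0.30 else "absent"),
        ],
        condition_lists={
            "Medical and obstetric disorders": _conditions(
                rng, config,
                ["Hypertensive disorders", "Clinical chorioamnionitis",
                 "Antepartum hemorrhage", "Diabetes mellitus", "Severe anemia",
                 "Obstructed labor"],
                case_type,
                qualifiers={"Hypertensive disorders": ["Pre-eclampsia", "Eclampsia",
                                                       "Chronic hypertension"]}),
            "Positive tests": _conditions(
                rng, config,
                ["Rh factor", "Active tuberculosis", "Syphilis", "HIV",
                 "Hepatitis B", "Malaria smear"], case_type),
        },
    )

    apgar = 0 if case_type is CaseType.stillbirth else int(rng.integers(0, 10))
    fetal = FormSection(
        fields=[
            _maybe(rng, config, "Apgar score (5 min)", apgar),
            _maybe(rng, config, "resuscitation attempted",
                   "no" if case_type is CaseType.stillbirth
                   else str(rng.choice(["yes", "no"]))),
            _maybe(rng, config, "congenital anomaly noted",
                   "yes" if rng.random() < 0.07 else "no"),
        ],
        condition_lists={
            "Neonatal conditions": _conditions(
                rng, config,
                ["Respiratory distress syndrome", "Asphyxia", "Suspected sepsis",
                 "Jaundice", "Seizures", "Hypothermia"], case_type),
        },
    )

    nicu = []
    home_death_fields: list[FieldValue] = []
    if case_type is CaseType.neonatal_death:
        if home:
            home_death_fields = [
                FieldValue(label="circumstances",
                           value="found unresponsive at home"),
                FieldValue(label="care sought before death",
                           value=str(rng.choice(["yes", "no"]))),
            ]
        else:
            nicu = _nicu_stays(rng, config, birth_dt, death_dt)

    placenta = PlacentaSection()
    if status_of["placenta"] is FormStatusValue.complete:
        pw = int(max(80, 0.22 * bw + rng.normal(0, 40)))
        placenta = PlacentaSection(
            weight=_maybe(rng, config, "placental weight (grams)", pw),
            findings=_histology(rng, {"placenta": _PLACENTA_FINDINGS}, 0.5),
        )

    mits = _histology(rng, _MITS_ORGANS, 0.6) \
        if status_of["mits"] is FormStatusValue.complete else []
    cda = _histology(rng, _MITS_ORGANS, 0.6) \
        if status_of["cda"] is FormStatusValue.complete else []
    pcr = _pcr_samples(rng, config, organism_panel(inventory.pcr_panel_size)) \
        if status_of["pcr"] is FormStatusValue.complete else []

    return CaseRecord(
        case_id=case_id,
        pregnancy_id=row.pregnancy_id,
        case_type=case_type,
        site=_site_for(config, index),
        birth_characteristics=birth_fields,
        obstetric=obstetric,
        fetal_neonatal=fetal,
        nicu_stays=nicu,
        home_death=home_death_fields,
        cda=cda,
        mits_histology=mits,
        pcr=pcr,
        placenta=placenta,
        form_statuses=statuses,
    )


# ---------------------------------------------------------------------------
# reviewer determinations
# ---------------------------------------------------------------------------

_REVIEWERS = [f"R{i:02d}" for i in range(1, 9)]

_AXIS_POPULATE_P = {Axis.maternal: 0.6, Axis.placental: 0.7,
                    Axis.fetal_neonatal: 0.85}


def _random_determination(rng, case: CaseRecord, reviewer: str,
                          vocab: VocabularySet) -> Determination:
    primaries: dict[Axis, Optional[str]] = {}
    for axis in AXIS_ORDER:
        if rng.random() < _AXIS_POPULATE_P[axis]:
            codes = [c for c, _ in vocab[axis].codes]
            primaries[axis] = str(rng.choice(codes))
        else:
            primaries[axis] = None
    if all(v is None for v in primaries.values()):
        codes = [c for c, _ in vocab[Axis.fetal_neonatal].codes]
        primaries[Axis.fetal_neonatal] = str(rng.choice(codes))
    contributing = []
    for axis in AXIS_ORDER:
        if rng.random() < 0.3:
            codes = [c for c, _ in vocab[axis].codes if c != primaries[axis]]
            contributing.append(ContributingCause(axis=axis,
                                                  code=str(rng.choice(codes))))
    return Determination(
        case_id=case.case_id, reviewer_id=reviewer,
        primary_maternal=primaries[Axis.maternal],
        primary_placental=primaries[Axis.placental],
        primary_fetal_neonatal=primaries[Axis.fetal_neonatal],
        contributing=contributing,
        certainty=Certainty(str(rng.choice([c.value for c in Certainty]))),
        preventable=Preventability(str(rng.choice([p.value for p in Preventability]))),
    )


def generate_determination_pair(config: GeneratorConfig, case: CaseRecord,
                                index: int, vocab: Optional[VocabularySet] = None
                                ) -> tuple[Determination, Determination]:
    """Two reviewers' determinations for one case; with probability
    ``disagreement_rate`` the second differs from the first on at least one
    primary axis (forcing escalation on reconciliation)."""
    vocab = vocab or load_vocabulary()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, index]))
    ra, rb = [ _REVIEWERS[i] for i in
               rng.choice(len(_REVIEWERS), size=2, replace=False) ]
    a = _random_determination(rng, case, ra, vocab)
    b = a.model_copy(deep=True, update={
        "reviewer_id": rb,
        "certainty": Certainty(str(rng.choice([c.value for c in Certainty]))),
    })
    if rng.random() < config.disagreement_rate:
        axis = AXIS_ORDER[int(rng.integers(0, 3))]
        codes = [c for c, _ in vocab[axis].codes if c != a.primary(axis)]
        update = {
            Axis.maternal: "primary_maternal",
            Axis.placental: "primary_placental",
            Axis.fetal_neonatal: "primary_fetal_neonatal",
        }[axis]
        b = b.model_copy(update={update: str(rng.choice(codes))})
    return a, b


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    cases: list[CaseRecord]
    manifest: pd.DataFrame
    determinations: dict[str, tuple[Determination, Determination]]
    reference: ReferenceTable
    config: GeneratorConfig = field(repr=False, default=None)


def generate_manifest(config: GeneratorConfig) -> pd.DataFrame:
    """The cohort manifest (case_id, pregnancy_id, case_type, site) without
    generating full case bodies — cheap even for the full study size."""
    plan = _cohort_plan(config)
    rows = []
    for i, p in enumerate(plan):
        rows.append({
            "case_id": f"C{i + 1:05d}",
            "pregnancy_id": p.pregnancy_id,
            "case_type": p.case_type.value,
            "site": _site_for(config, i),
        })
    return pd.DataFrame(rows, columns=["case_id", "pregnancy_id", "case_type", "site"])


def generate_cohort(config: GeneratorConfig,
                    inventory: Optional[FormInventory] = None,
                    with_determinations: bool = True) -> SyntheticCohort:
    """Generate the full synthetic cohort: cases, manifest, paired reviewer
    determinations, and a reference table (all from ``config.seed``)."""
    inventory = inventory or load_form_inventory()
    plan = _cohort_plan(config)
    vocab = load_vocabulary() if with_determinations else None
    cases = [generate_case(config, i, inventory=inventory, _plan=plan)
             for i in range(config.n_cases)]
    manifest = pd.DataFrame(
        [{"case_id": c.case_id, "pregnancy_id": c.pregnancy_id,
          "case_type": c.case_type.value, "site": c.site} for c in cases],
        columns=["case_id", "pregnancy_id", "case_type", "site"])
    dets: dict[str, tuple[Determination, Determination]] = {}
    if with_determinations:
        for i, c in enumerate(cases):
            dets[c.case_id] = generate_determination_pair(config, c, i, vocab)
    return SyntheticCohort(cases=cases, manifest=manifest, determinations=dets,
                           reference=generate_reference_tables(config.seed),
                           config=config)
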