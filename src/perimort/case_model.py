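"""Structured per-case data model for stillbirths and neonatal deaths.

One :class:`CaseRecord` holds everything the study collected about a single
death: maternal/obstetric data, fetal or neonatal data, NICU daily records,
placental pathology, and the post-mortem research evaluations (complete
diagnostic autopsy, minimally invasive tissue sampling histology, and
multiplexed PCR panel results).

Two conventions run through the whole model:

* **Answered vs. not answered.**  A field whose value is ``None`` was *not
  answered* on the study form.  This is deliberately distinct from an empty
  string (an answered, empty value) and from a negative finding (an answered
  value of "absent"/"negative").  JSON ``null`` and a key missing from the
  file both map to not-answered.
* **Form-level completeness.**  Data are organized by study form.  A form is
  ``complete`` (all required fields exist, possibly as not-answered),
  ``omitted`` (not done for a documented reason, e.g. consent not obtained),
  or ``missing`` (simply never filled in).  Downstream, only cases whose
  forms are all complete-or-omitted are released to review panels.

The model is validated in two layers: pydantic guarantees structural shape
at parse time, while :func:`validate_case` checks the domain invariants and
returns a report of violations instead of raising, so a batch of imperfect
real-world files can be triaged in one pass.
"""

from __future__ import annotations

import json
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from ._resources import data_path

Scalar = Union[int, float, str, date, datetime]


class CaseType(str, Enum):
    stillbirth = "stillbirth"
    neonatal_death = "neonatal_death"


class FormStatusValue(str, Enum):
    complete = "complete"
    omitted = "omitted"
    missing = "missing"


class CompletionStatus(str, Enum):
    complete = "complete"
    incomplete = "incomplete"


class FieldValue(BaseModel):
    """A labelled datum from a study form; ``value=None`` means not answered."""

    model_config = ConfigDict(frozen=True)

    label: str
    value: Optional[Scalar] = None

    @property
    def answered(self) -> bool:
        return self.value is not None


class ConditionEntry(BaseModel):
    """One yes/no condition from a checklist, with an optional sub-question
    qualifier (e.g. Hypertensive disorders -> Pre-eclampsia).

    ``answered=False`` means the question was never answered, in which case
    ``present`` carries no information and the entry counts as missing data.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    present: bool = False
    qualifier: Optional[str] = None
    answered: bool = True


class FormStatus(BaseModel):
    form_name: str
    status: FormStatusValue
    omission_reason: Optional[str] = None


class NICUDayRecord(BaseModel):
    day_index: int
    date: date
    diagnoses: list[str] = Field(default_factory=list)
    appearance: list[str] = Field(default_factory=list)
    signs_symptoms: list[str] = Field(default_factory=list)
    treatments: list[str] = Field(default_factory=list)


class NICUStay(BaseModel):
    admission_date: date
    discharge_date: date
    days: list[NICUDayRecord] = Field(default_factory=list)


class PCRResult(str, Enum):
    positive = "positive"
    negative = "negative"
    not_tested = "not_tested"


class PCRSampleResult(BaseModel):
    """TaqMan array card results for one tissue sample.

    ``organism_results`` maps every organism on the configured card (80 by
    default) to positive / negative / not tested.
    """

    sample_id: str
    tissue: str
    organism_results: dict[str, PCRResult] = Field(default_factory=dict)

    def positives(self) -> list[str]:
        return [o for o, r in self.organism_results.items() if r is PCRResult.positive]


class HistologyFinding(BaseModel):
    organ: str
    finding: str = ""
    normal: bool = False


class FormSection(BaseModel):
    """Fields plus named condition checklists belonging to one study form."""

    fields: list[FieldValue] = Field(default_factory=list)
    condition_lists: dict[str, list[ConditionEntry]] = Field(default_factory=dict)

    def get_field(self, label: str) -> Optional[FieldValue]:
        for f in self.fields:
            if f.label == label:
                return f
        return None


class PlacentaSection(BaseModel):
    weight: FieldValue = Field(
        default_factory=lambda: FieldValue(label="placental weight (grams)")
    )
    findings: list[HistologyFinding] = Field(default_factory=list)


class CaseRecord(BaseModel):
    case_id: str
    pregnancy_id: str
    case_type: CaseType
    site: str = ""
    birth_characteristics: list[FieldValue] = Field(default_factory=list)
    obstetric: FormSection = Field(default_factory=FormSection)
    fetal_neonatal: FormSection = Field(default_factory=FormSection)
    nicu_stays: list[NICUStay] = Field(default_factory=list)
    home_death: list[FieldValue] = Field(default_factory=list)
    cda: list[HistologyFinding] = Field(default_factory=list)
    mits_histology: list[HistologyFinding] = Field(default_factory=list)
    pcr: list[PCRSampleResult] = Field(default_factory=list)
    placenta: PlacentaSection = Field(default_factory=PlacentaSection)
    form_statuses: list[FormStatus] = Field(default_factory=list)

    def get_birth_field(self, label: str) -> Optional[FieldValue]:
        for f in self.birth_characteristics:
            if f.label == label:
                return f
        return None

    def form_status(self, form_name: str) -> Optional[FormStatus]:
        for fs in self.form_statuses:
            if fs.form_name == form_name:
                return fs
        return None


# ---------------------------------------------------------------------------
# form inventory (configuration)
# ---------------------------------------------------------------------------


class FormSpec(BaseModel):
    name: str
    title: str
    required_fields: list[str] = Field(default_factory=list)
    condition_lists: dict[str, list[str]] = Field(default_factory=dict)


class FormInventory(BaseModel):
    """The configured inventory of study forms and their required content.

    The set of variables judged essential for cause-of-death review is a
    project decision, so it ships as a versioned config file rather than
    being hard-coded; the bundled default covers the instrument areas the
    reports draw on.
    """

    version: str = "1.0"
    forms: list[FormSpec]
    always_shown: list[str] = Field(default_factory=list)
    pcr_panel_size: int = 80
    pcr_max_samples: int = 8

    def form(self, name: str) -> Optional[FormSpec]:
        for f in self.forms:
            if f.name == name:
                return f
        return None

    @property
    def form_names(self) -> list[str]:
        return [f.name for f in self.forms]


def load_form_inventory(path: Optional[Union[str, Path]] = None) -> FormInventory:
    """Load a form inventory from YAML; defaults to the bundled inventory."""
    p = Path(path) if path is not None else data_path("form_inventory.yaml")
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return FormInventory.model_validate(raw)


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------


class CaseParseError(ValueError):
    """Raised when a case file cannot be parsed; names the file and record."""

    def __init__(self, source: str, detail: str):
        self.source = source
        self.detail = detail
        super().__init__(f"cannot parse case data from {source}: {detail}")


def parse_case(data: Union[str, bytes, dict], source: str = "<memory>") -> CaseRecord:
    """Parse one case from a JSON document or an already-decoded mapping."""
    if isinstance(data, (str, bytes)):
        try:
            data = json.loads(data)
        except json.JSONDecodeError as exc:
            raise CaseParseError(source, f"invalid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise CaseParseError(source, "top-level JSON value must be an object")
    try:
        return CaseRecord.model_validate(data)
    except Exception as exc:  # pydantic.ValidationError
        rec = data.get("case_id", "<unknown case_id>")
        raise CaseParseError(source, f"record {rec}: {exc}") from exc


def load_case(path: Union[str, Path]) -> CaseRecord:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise CaseParseError(str(path), str(exc)) from exc
    return parse_case(text, source=str(path))


def dump_case(case: CaseRecord, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a case to JSON; round-trips through :func:`parse_case`."""
    text = case.model_dump_json(indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


class Violation(BaseModel):
    case_id: str
    form: str = ""
    field: str = ""
    rule: str
    message: str


class ValidationReport(BaseModel):
    case_id: str
    violations: list[Violation] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


_SECTION_FORMS = {
    "birth_characteristics": "birth_characteristics",
    "obstetric": "obstetric",
    "fetal_neonatal": "fetal_neonatal",
}


def _check_field_labels(case_id, form, fields, out) -> None:
    seen: set[str] = set()
    for f in fields:
        if not f.label.strip():
            out.append(Violation(case_id=case_id, form=form, rule="label-nonempty",
                                 message="field label is empty"))
        if f.label in seen:
            out.append(Violation(case_id=case_id, form=form, field=f.label,
                                 rule="label-unique",
                                 message=f"duplicate field label {f.label!r}"))
        seen.add(f.label)


def _section_fields(case: CaseRecord, form_name: str) -> Optional[list[FieldValue]]:
    if form_name == "birth_characteristics":
        return case.birth_characteristics
    if form_name == "obstetric":
        return case.obstetric.fields
    if form_name == "fetal_neonatal":
        return case.fetal_neonatal.fields
    if form_name == "placenta":
        return [case.placenta.weight]
    return None


def validate_case(case: CaseRecord, inventory: FormInventory) -> ValidationReport:
    """Check every domain invariant; returns a report, never raises.

    Violations carry the case id, the form, the offending field where it has
    one, and a short machine-friendly rule name.
    """
    v: list[Violation] = []
    cid = case.case_id

    if not cid.strip():
        v.append(Violation(case_id=cid, rule="case-id-nonempty",
                           message="case_id is empty"))

    # stillbirths are fetal deaths: no NICU course can exist
    if case.case_type is CaseType.stillbirth and case.nicu_stays:
        v.append(Violation(case_id=cid, form="nicu", rule="stillbirth-no-nicu",
                           message="stillbirth has NICU data"))

    # field labels unique and non-empty within each form
    _check_field_labels(cid, "birth_characteristics", case.birth_characteristics, v)
    _check_field_labels(cid, "obstetric", case.obstetric.fields, v)
    _check_field_labels(cid, "fetal_neonatal", case.fetal_neonatal.fields, v)
    _check_field_labels(cid, "home_death", case.home_death, v)

    # condition entries: qualifier only when present; unanswered => missing
    for form_name, section in (("obstetric", case.obstetric),
                               ("fetal_neonatal", case.fetal_neonatal)):
        for list_label, entries in section.condition_lists.items():
            for e in entries:
                if e.qualifier and not e.present:
                    v.append(Violation(
                        case_id=cid, form=form_name, field=f"{list_label}/{e.name}",
                        rule="qualifier-requires-present",
                        message="qualifier given for a condition not marked present"))

    # NICU chronology
    for i, stay in enumerate(case.nicu_stays, start=1):
        where = f"stay {i}"
        if stay.admission_date > stay.discharge_date:
            v.append(Violation(case_id=cid, form="nicu", field=where,
                               rule="nicu-admission-before-discharge",
                               message="admission date after discharge date"))
        prev_idx, prev_date = 0, None
        for day in stay.days:
            if day.day_index <= prev_idx:
                v.append(Violation(case_id=cid, form="nicu", field=where,
                                   rule="nicu-day-index-increasing",
                                   message="day_index not strictly increasing"))
            if prev_date is not None and day.date <= prev_date:
                v.append(Violation(case_id=cid, form="nicu", field=where,
                                   rule="nicu-day-date-increasing",
                                   message="day dates not strictly increasing"))
            if not (stay.admission_date <= day.date <= stay.discharge_date):
                v.append(Violation(case_id=cid, form="nicu", field=where,
                                   rule="nicu-day-within-stay",
                                   message="day date outside the stay interval"))
            prev_idx, prev_date = day.day_index, day.date

    # PCR panel shape
    if len(case.pcr) > inventory.pcr_max_samples:
        v.append(Violation(case_id=cid, form="pcr", rule="pcr-max-samples",
                           message=f"more than {inventory.pcr_max_samples} samples"))
    for s in case.pcr:
        if len(s.organism_results) != inventory.pcr_panel_size:
            v.append(Violation(
                case_id=cid, form="pcr", field=s.sample_id, rule="pcr-panel-size",
                message=(f"sample tests {len(s.organism_results)} organisms, "
                         f"panel is {inventory.pcr_panel_size}")))

    # histology findings: description required when abnormal
    for form_name, findings in (("cda", case.cda),
                                ("mits", case.mits_histology),
                                ("placenta", case.placenta.findings)):
        for h in findings:
            if not h.normal and not h.finding.strip():
                v.append(Violation(case_id=cid, form=form_name, field=h.organ,
                                   rule="histology-finding-nonempty",
                                   message="abnormal histology without a finding"))

    # always-shown fields must exist (possibly as not-answered)
    for label in inventory.always_shown:
        found = any(_find_field(case, label))
        if not found:
            v.append(Violation(case_id=cid, field=label, rule="always-shown-present",
                               message=f"always-shown field {label!r} missing"))

    # form statuses: inventory coverage, one status per form, reasons
    status_names = [fs.form_name for fs in case.form_statuses]
    for name in inventory.form_names:
        n = status_names.count(name)
        if n != 1:
            v.append(Violation(case_id=cid, form=name, rule="form-status-exactly-once",
                               message=f"form appears {n} times in form_statuses"))
    for fs in case.form_statuses:
        if fs.form_name not in inventory.form_names:
            v.append(Violation(case_id=cid, form=fs.form_name,
                               rule="form-status-known-form",
                               message="status for a form not in the inventory"))
            continue
        if fs.status is FormStatusValue.omitted and not (fs.omission_reason or "").strip():
            v.append(Violation(case_id=cid, form=fs.form_name,
                               rule="omitted-requires-reason",
                               message="omitted form without an omission reason"))
        if fs.status is FormStatusValue.complete:
            spec = inventory.form(fs.form_name)
            fields = _section_fields(case, fs.form_name)
            if spec is not None and fields is not None:
                present = {f.label for f in fields}
                for req in spec.required_fields:
                    if req not in present:
                        v.append(Violation(
                            case_id=cid, form=fs.form_name, field=req,
                            rule="complete-requires-fields",
                            message=f"complete form lacks required field {req!r}"))

    return ValidationReport(case_id=cid, violations=v)


def _find_field(case: CaseRecord, label: str) -> Iterable[FieldValue]:
    for pool in (case.birth_characteristics, case.obstetric.fields,
                 case.fetal_neonatal.fields, case.home_death):
        for f in pool:
            if f.label == label:
                yield f


def validate_cohort(cases: list[CaseRecord], inventory: FormInventory) -> list[ValidationReport]:
    """Validate many cases; additionally flags duplicate case ids."""
    reports = [validate_case(c, inventory) for c in cases]
    seen: set[str] = set()
    for case, rep in zip(cases, reports):
        if case.case_id in seen:
            rep.violations.append(Violation(
                case_id=case.case_id, rule="case-id-unique",
                message="duplicate case_id in cohort"))
        seen.add(case.case_id)
    return reports


def completion_status(
    case: CaseRecord,
) -> tuple[CompletionStatus, dict[str, FormStatusValue]]:
    """Overall completeness plus the per-form breakdown.

    A case is complete when every study form is either complete or omitted
    with a documented reason; any missing form (or omission without a
    reason) makes the case incomplete.  Only complete cases are released to
    the review panels.
    """
    breakdown = {fs.form_name: fs.status for fs in case.form_statuses}
    ok = all(
        fs.status is FormStatusValue.complete
        or (fs.status is FormStatusValue.omitted and (fs.omission_reason or "").strip())
        for fs in case.form_statuses
    )
    status = CompletionStatus.complete if ok and case.form_statuses else CompletionStatus.incomplete
    return status, breakdown
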