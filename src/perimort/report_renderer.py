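"""Deterministic rendering of the standardized 8-section case report.

Each case is summarized in a consistent plain-text layout so that every
panelist reviews exactly the same information in exactly the same order:

1. summary of the death and birth characteristics,
2. obstetric history and maternal course,
3. fetal/neonatal description,
4. NICU course and home death (admitted neonatal deaths / home deaths only),
5. placental pathology,
6. complete diagnostic autopsy,
7. MITS histology,
8. PCR and laboratory results.

Display rules (these are the contract golden tests pin down):

* a field renders as ``label: value``; an unanswered field as
  ``label: not answered`` — missing data are always visible, never blank;
* condition checklists render as a positive-findings list, e.g.
  ``Medical and obstetric disorders: Hypertensive disorders (Pre-eclampsia),
  Clinical chorioamnionitis``; all-negative answered lists collapse to
  ``label: none``; negatives are otherwise suppressed;
* fields on the configured always-shown list (GBS test, meconium at
  delivery) appear even when negative/absent, because the absence of such
  a finding is itself informative;
* PCR lines list only the positive organisms per tissue sample; a sample
  with no positives renders ``tissue: none``;
* a form omitted for a documented reason renders as just the section title
  plus ``Not available: <reason>``.

Rendering is a pure function of its inputs: the same case, derived summary,
template, and config always produce byte-identical output.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Optional, Union

import yaml
from pydantic import BaseModel, Field

from ._resources import data_path
from .case_model import (
    CaseRecord,
    CaseType,
    ConditionEntry,
    FieldValue,
    FormStatus,
    FormStatusValue,
    PCRSampleResult,
    HistologyFinding,
)
from .derivations import DerivedSummary, summarize_nicu_days

DEFAULT_LINES_PER_PAGE = 60
NOT_ANSWERED = "not answered"


class SectionSpec(BaseModel):
    """One of the 8 report sections: its title, which study form gates it,
    which content block fills it, and when it applies at all."""

    index: int
    title: str
    source: str
    form: str
    applicable: str = "always"  # or "nicu_or_home"


class ReportTemplate(BaseModel):
    sections: list[SectionSpec]
    lines_per_page: int = DEFAULT_LINES_PER_PAGE
    always_shown: list[str] = Field(default_factory=list)


class TemplateError(ValueError):
    pass


def load_template(path: Optional[Union[str, Path]] = None) -> ReportTemplate:
    """Load a report template from YAML; defaults to the bundled 8-section
    template.  A template must define exactly 8 sections, section 1 being
    the death summary, with the research evaluations (CDA, MITS, PCR) last."""
    p = Path(path) if path is not None else data_path("report_template.yaml")
    with open(p, "r", encoding="utf-8") as fh:
        tpl = ReportTemplate.model_validate(yaml.safe_load(fh))
    if len(tpl.sections) != 8:
        raise TemplateError(f"template defines {len(tpl.sections)} sections, need 8")
    if [s.index for s in tpl.sections] != list(range(1, 9)):
        raise TemplateError("section indices must be 1..8 in order")
    if tpl.sections[0].source != "death_summary":
        raise TemplateError("section 1 must be the death summary")
    return tpl


class CaseReport(BaseModel):
    case_id: str
    lines: list[str]
    page_count: int

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


# ---------------------------------------------------------------------------
# line-level renderers
# ---------------------------------------------------------------------------


def _fmt_value(value) -> str:
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    s = str(value)
    return s.strip()


def render_field(field: FieldValue) -> str:
    """``label: value``; an unanswered field renders ``label: not answered``."""
    if not field.answered:
        return f"{field.label}: {NOT_ANSWERED}"
    return f"{field.label}: {_fmt_value(field.value)}"


def render_positive_list(label: str, entries: list[ConditionEntry]) -> str:
    """Positive-findings list: only conditions marked present are named,
    with their qualifier in parentheses.  All answered and none present
    collapses to ``label: none``; nothing answered to ``label: not answered``."""
    if entries and all(not e.answered for e in entries):
        return f"{label}: {NOT_ANSWERED}"
    positives = [e for e in entries if e.answered and e.present]
    if not positives:
        return f"{label}: none"
    parts = []
    for e in positives:
        if e.qualifier:
            parts.append(f"{e.name} ({e.qualifier})")
        else:
            parts.append(e.name)
    return f"{label}: " + ", ".join(parts)


def render_pcr(samples: list[PCRSampleResult]) -> list[str]:
    """One line per tissue sample naming only the positive organisms;
    negatives and untested organisms are never listed."""
    lines = []
    for s in samples:
        positives = s.positives()
        if positives:
            lines.append(f"{s.tissue}: " + ", ".join(positives))
        else:
            lines.append(f"{s.tissue}: none")
    return lines


def render_always_shown(field: FieldValue) -> str:
    """Render a field from the always-shown list; unlike suppressed
    negatives these appear whatever their value (``GBS test: negative``)."""
    return render_field(field)


def render_histology(findings: list[HistologyFinding]) -> list[str]:
    if not findings:
        return ["findings: none"]
    return [f"{h.organ}: normal" if h.normal else f"{h.organ}: {h.finding.strip()}"
            for h in findings]


def render_omitted_section(spec: SectionSpec, status: FormStatus) -> list[str]:
    """An omitted form prints only its section title and the reason why."""
    reason = (status.omission_reason or "").strip()
    return [spec.title, f"Not available: {reason}"]


def render_reference_line(observed: Optional[float], reference: Optional[float],
                          kind: str) -> str:
    """Observed value next to the published reference standard, so panelists
    can judge the case against it; an uncovered lookup degrades to
    ``(reference unavailable)`` instead of aborting the report."""
    labels = {
        "birthweight_p10": "birth weight vs 10th percentile (grams)",
        "placental_mean": "placental weight vs reference mean (grams)",
    }
    label = labels.get(kind, kind)
    obs = NOT_ANSWERED if observed is None else _fmt_value(observed)
    if reference is None:
        return f"{label}: {obs} (reference unavailable)"
    return f"{label}: {obs} vs {_fmt_value(reference)}"


def paginate(lines: list[str], lines_per_page: int = DEFAULT_LINES_PER_PAGE) -> int:
    """Page count at a fixed number of rendered lines per page."""
    if lines_per_page < 1:
        raise ValueError(f"lines_per_page must be >= 1, got {lines_per_page}")
    return math.ceil(len(lines) / lines_per_page)


# ---------------------------------------------------------------------------
# section bodies
# ---------------------------------------------------------------------------


def _body_death_summary(case: CaseRecord, derived: DerivedSummary,
                        tpl: ReportTemplate) -> list[str]:
    lines = [f"case id: {case.case_id}",
             f"type of death: {case.case_type.value.replace('_', ' ')}",
             f"site: {case.site}" if case.site else "site: not answered"]
    for f in case.birth_characteristics:
        lines.append(render_field(f))
    if case.case_type is CaseType.neonatal_death:
        if derived.age_at_death_days is not None:
            lines.append(f"age at death (days): {derived.age_at_death_days}")
        else:
            lines.append(f"age at death (days): {NOT_ANSWERED}")
        lines.append(f"total days in the NICU: {derived.total_nicu_days}")
    bw = case.get_birth_field("birth weight (grams)")
    obs = bw.value if bw is not None and bw.answered else None
    lines.append(render_reference_line(
        _num(obs), derived.birthweight_p10_value, "birthweight_p10"))
    if derived.sga_flag is not None:
        lines.append("small for gestational age: " + ("yes" if derived.sga_flag else "no"))
    return lines


def _num(value) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _body_form_section(section, tpl: ReportTemplate) -> list[str]:
    lines = [render_field(f) for f in section.fields]
    for label, entries in section.condition_lists.items():
        lines.append(render_positive_list(label, entries))
    return lines


def _body_obstetric(case, derived, tpl):
    return _body_form_section(case.obstetric, tpl)


def _body_fetal_neonatal(case, derived, tpl):
    return _body_form_section(case.fetal_neonatal, tpl)


def _body_nicu(case: CaseRecord, derived: DerivedSummary,
               tpl: ReportTemplate) -> list[str]:
    lines: list[str] = []
    for i, stay in enumerate(case.nicu_stays, start=1):
        ndays = (stay.discharge_date - stay.admission_date).days + 1
        lines.append(
            f"NICU stay {i}: admitted {stay.admission_date.isoformat()}, "
            f"discharged {stay.discharge_date.isoformat()} ({ndays} day{'s' if ndays != 1 else ''})")
        lines.extend(summarize_nicu_days(stay))
    if case.home_death:
        lines.append("Home death:")
        lines.extend(render_field(f) for f in case.home_death)
    if not lines:
        lines.append("no NICU admission recorded")
    return lines


def _body_placenta(case: CaseRecord, derived: DerivedSummary,
                   tpl: ReportTemplate) -> list[str]:
    lines = [render_field(case.placenta.weight)]
    obs = case.placenta.weight.value if case.placenta.weight.answered else None
    lines.append(render_reference_line(
        _num(obs), derived.placental_mean_value, "placental_mean"))
    lines.extend(render_histology(case.placenta.findings))
    return lines


def _body_cda(case, derived, tpl):
    return render_histology(case.cda)


def _body_mits(case, derived, tpl):
    return render_histology(case.mits_histology)


def _body_pcr(case: CaseRecord, derived: DerivedSummary,
              tpl: ReportTemplate) -> list[str]:
    if not case.pcr:
        return ["no samples tested"]
    return render_pcr(case.pcr)


_SECTION_BODIES: dict[str, Callable] = {
    "death_summary": _body_death_summary,
    "obstetric": _body_obstetric,
    "fetal_neonatal": _body_fetal_neonatal,
    "nicu": _body_nicu,
    "placenta": _body_placenta,
    "cda": _body_cda,
    "mits": _body_mits,
    "pcr": _body_pcr,
}


def _section_applies(spec: SectionSpec, case: CaseRecord) -> bool:
    if spec.applicable == "always":
        return True
    if spec.applicable == "nicu_or_home":
        if case.case_type is CaseType.stillbirth:
            return False
        return True
    raise TemplateError(f"unknown applicability predicate {spec.applicable!r}")


def assemble_report(case: CaseRecord, derived: DerivedSummary,
                    template: Optional[ReportTemplate] = None) -> CaseReport:
    """Assemble the full report: sections in template order, inapplicable
    sections skipped entirely, omitted forms collapsed to a two-line block."""
    tpl = template if template is not None else load_template()
    lines: list[str] = [f"Standardized case report — {case.case_id}", ""]
    for spec in tpl.sections:
        if not _section_applies(spec, case):
            continue
        status = case.form_status(spec.form)
        if status is not None and status.status is FormStatusValue.omitted:
            lines.extend(render_omitted_section(spec, status))
            lines.append("")
            continue
        body_fn = _SECTION_BODIES.get(spec.source)
        if body_fn is None:
            raise TemplateError(f"unknown section source {spec.source!r}")
        lines.append(spec.title)
        lines.extend(body_fn(case, derived, tpl))
        lines.append("")
    while lines and lines[-1] == "":
        lines.pop()
    return CaseReport(case_id=case.case_id, lines=lines,
                      page_count=paginate(lines, tpl.lines_per_page))
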