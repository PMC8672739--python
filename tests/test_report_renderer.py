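"""Report rendering: display conventions, coverage of missing data,
section applicability, pagination, and byte-level determinism."""

import pytest

from perimort import (
    CaseType,
    ConditionEntry,
    FieldValue,
    FormStatus,
    FormStatusValue,
    assemble_report,
    derive_summary,
    paginate,
    render_field,
    render_omitted_section,
    render_pcr,
    render_positive_list,
    render_reference_line,
)
from perimort.report_renderer import SectionSpec, render_always_shown
from perimort.case_model import PCRResult

from conftest import make_complete_case


class TestRenderField:
    def test_label_colon_value(self):
        line = render_field(FieldValue(label="birth weight (grams)", value=1800))
        assert line == "birth weight (grams): 1800"

    def test_unanswered_renders_not_answered(self):
        assert render_field(FieldValue(label="gender")) == "gender: not answered"

    def test_whitespace_is_trimmed(self):
        line = render_field(FieldValue(label="gender", value="  male  "))
        assert line == "gender: male"


class TestRenderPositiveList:
    def test_lists_only_present_conditions(self):
        entries = [ConditionEntry(name="Rh factor", present=True),
                   ConditionEntry(name="Syphilis", present=False),
                   ConditionEntry(name="Active tuberculosis", present=True)]
        assert (render_positive_list("Positive tests", entries)
                == "Positive tests: Rh factor, Active tuberculosis")

    def test_qualifier_in_parentheses(self):
        entries = [ConditionEntry(name="Hypertensive disorders", present=True,
                                  qualifier="Pre-eclampsia"),
                   ConditionEntry(name="Clinical chorioamnionitis", present=True)]
        assert (render_positive_list("Medical and obstetric disorders", entries)
                == "Medical and obstetric disorders: "
                   "Hypertensive disorders (Pre-eclampsia), Clinical chorioamnionitis")

    def test_all_negative_collapses_to_none(self):
        entries = [ConditionEntry(name="Rh factor"),
                   ConditionEntry(name="Syphilis")]
        assert (render_positive_list("Medical and obstetric disorders", entries)
                == "Medical and obstetric disorders: none")

    def test_nothing_answered_is_not_answered(self):
        entries = [ConditionEntry(name="Rh factor", answered=False),
                   ConditionEntry(name="Syphilis", answered=False)]
        assert (render_positive_list("Positive tests", entries)
                == "Positive tests: not answered")


class TestAlwaysShown:
    def test_negative_gbs_is_still_shown(self):
        line = render_always_shown(FieldValue(label="GBS test", value="negative"))
        assert line == "GBS test: negative"

    def test_absent_meconium_is_still_shown(self):
        line = render_always_shown(
            FieldValue(label="meconium at delivery", value="absent"))
        assert line == "meconium at delivery: absent"

    def test_unanswered_still_follows_missing_rule(self):
        assert render_always_shown(FieldValue(label="GBS test")) == \
            "GBS test: not answered"


class TestRenderPcr:
    def test_only_positives_listed(self, stillbirth_case):
        lines = render_pcr(stillbirth_case.pcr)
        assert lines[0] == "lung: Group B Streptococcus, Escherichia coli"

    def test_zero_positive_sample_renders_none(self, stillbirth_case):
        assert render_pcr(stillbirth_case.pcr)[1] == "blood: none"

    def test_positive_count_conservation(self, stillbirth_case):
        n_positive = sum(
            1 for s in stillbirth_case.pcr
            for r in s.organism_results.values() if r is PCRResult.positive)
        lines = render_pcr(stillbirth_case.pcr)
        printed = sum(len(ln.split(": ", 1)[1].split(", "))
                      for ln in lines if not ln.endswith(": none"))
        assert printed == n_positive == 2


class TestOmittedSection:
    def test_two_line_block_with_reason(self):
        spec = SectionSpec(index=7, title="7. MITS histology", source="mits",
                           form="mits")
        status = FormStatus(form_name="mits", status=FormStatusValue.omitted,
                            omission_reason="consent not obtained")
        block = render_omitted_section(spec, status)
        assert block == ["7. MITS histology", "Not available: consent not obtained"]

    def test_cda_sample_not_collected(self):
        spec = SectionSpec(index=6, title="6. Complete diagnostic autopsy",
                           source="cda", form="cda")
        status = FormStatus(form_name="cda", status=FormStatusValue.omitted,
                            omission_reason="sample not collected")
        block = render_omitted_section(spec, status)
        assert len(block) == 2
        assert block[1] == "Not available: sample not collected"


class TestReferenceLine:
    def test_contains_both_numbers(self):
        line = render_reference_line(210, 450, "placental_mean")
        assert "210" in line and "450" in line

    def test_unavailable_reference_suffix(self):
        line = render_reference_line(210, None, "placental_mean")
        assert line.endswith("(reference unavailable)")

    def test_deterministic(self):
        assert (render_reference_line(1800, 1620, "birthweight_p10")
                == render_reference_line(1800, 1620, "birthweight_p10"))


class TestPaginate:
    @pytest.mark.parametrize("n_lines,per_page,pages", [
        (120, 60, 2), (121, 60, 3), (0, 60, 0), (1, 60, 1), (60, 60, 1)])
    def test_ceiling_division(self, n_lines, per_page, pages):
        assert paginate([""] * n_lines, per_page) == pages

    def test_rejects_nonpositive_page_size(self):
        with pytest.raises(ValueError, match="lines_per_page"):
            paginate(["x"], 0)


class TestAssembleReport:
    def test_neonatal_report_has_nicu_day_lines(self, neonatal_case,
                                                tiny_reference, template):
        report = assemble_report(
            neonatal_case, derive_summary(neonatal_case, tiny_reference), template)
        assert "4. NICU course and home death" in report.lines
        assert any(ln.startswith("Day 1:") for ln in report.lines)

    def test_stillbirth_report_has_no_nicu_section(self, stillbirth_case,
                                                   tiny_reference, template):
        report = assemble_report(
            stillbirth_case, derive_summary(stillbirth_case, tiny_reference),
            template)
        assert all("NICU" not in ln for ln in report.lines)

    def test_rendering_twice_is_byte_identical(self, neonatal_case,
                                               tiny_reference, template):
        d = derive_summary(neonatal_case, tiny_reference)
        a = assemble_report(neonatal_case, d, template)
        b = assemble_report(neonatal_case, d, template)
        assert a.text == b.text

    def test_omitted_form_collapses_to_title_and_reason(self, neonatal_case,
                                                        tiny_reference, template):
        for i, fs in enumerate(neonatal_case.form_statuses):
            if fs.form_name == "mits":
                neonatal_case.form_statuses[i] = FormStatus(
                    form_name="mits", status=FormStatusValue.omitted,
                    omission_reason="consent not obtained")
        report = assemble_report(
            neonatal_case, derive_summary(neonatal_case, tiny_reference), template)
        i = report.lines.index("7. MITS histology")
        assert report.lines[i + 1] == "Not available: consent not obtained"
        # no histology body lines follow the omission notice
        assert report.lines[i + 2] == ""

    def test_missing_variable_coverage(self, stillbirth_case, tiny_reference,
                                       template):
        """Every required variable of an included non-omitted section appears
        either rendered, as "not answered", or inside a positive list."""
        for i, f in enumerate(stillbirth_case.obstetric.fields):
            if f.label == "parity":
                stillbirth_case.obstetric.fields[i] = FieldValue(label="parity")
        report = assemble_report(
            stillbirth_case, derive_summary(stillbirth_case, tiny_reference),
            template)
        assert "parity: not answered" in report.lines
        labels = [f.label for f in stillbirth_case.obstetric.fields]
        for label in labels:
            assert any(ln.startswith(f"{label}:") for ln in report.lines)

    def test_report_page_count_matches_paginate(self, neonatal_case,
                                                tiny_reference, template):
        report = assemble_report(
            neonatal_case, derive_summary(neonatal_case, tiny_reference), template)
        assert report.page_count == paginate(report.lines, template.lines_per_page)

    def test_every_section_title_present_for_complete_neonatal_case(
            self, neonatal_case, tiny_reference, template):
        report = assemble_report(
            neonatal_case, derive_summary(neonatal_case, tiny_reference), template)
        for spec in template.sections:
            assert spec.title in report.lines
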