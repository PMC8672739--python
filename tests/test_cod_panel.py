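"""Determinations: vocabulary validation, pair reconciliation (with an
exhaustive brute-force oracle), panel resolution, and cause tallies."""

import itertools

import pytest

from perimort import (
    Axis,
    Certainty,
    ContributingCause,
    Determination,
    EscalationRecord,
    FinalDetermination,
    FinalSource,
    Preventability,
    ReconcilePolicy,
    reconcile_pair,
    record_panel_resolution,
    tally_causes,
    validate_determination,
)
from perimort.cod_panel import CauseVocabulary, weaker_certainty


def _det(case="C1", reviewer="R1", m=None, p=None, f="F4", **kw) -> Determination:
    return Determination(case_id=case, reviewer_id=reviewer,
                         primary_maternal=m, primary_placental=p,
                         primary_fetal_neonatal=f, **kw)


class TestValidateDetermination:
    def test_valid_determination_passes(self, vocab):
        d = _det(m="M2", p="P1", f="F4",
                 contributing=[ContributingCause(axis=Axis.placental, code="P3")])
        assert validate_determination(d, vocab) == []

    def test_cross_axis_code_is_flagged(self, vocab):
        d = _det(m="F4")  # fetal-axis code on the maternal axis
        rules = {v.rule for v in validate_determination(d, vocab)}
        assert "primary-in-vocabulary" in rules

    def test_contributing_duplicating_primary_is_flagged(self, vocab):
        d = _det(f="F4",
                 contributing=[ContributingCause(axis=Axis.fetal_neonatal, code="F4")])
        rules = {v.rule for v in validate_determination(d, vocab)}
        assert "contributing-distinct-from-primary" in rules

    def test_no_primary_on_any_axis_is_flagged(self, vocab):
        d = Determination(case_id="C1", reviewer_id="R1")
        rules = {v.rule for v in validate_determination(d, vocab)}
        assert "at-least-one-primary" in rules

    def test_unknown_code_is_flagged(self, vocab):
        d = _det(p="P99")
        assert any("P99" in v.message for v in validate_determination(d, vocab))


class TestReconcilePair:
    def test_identical_determinations_agree(self):
        a = _det(reviewer="R1", m="M2", p="P1", f="F4",
                 certainty=Certainty.clinically_supported,
                 preventable=Preventability.yes)
        b = _det(reviewer="R2", m="M2", p="P1", f="F4",
                 certainty=Certainty.clinically_supported,
                 preventable=Preventability.yes)
        final = reconcile_pair(a, b)
        assert isinstance(final, FinalDetermination)
        assert final.source is FinalSource.pair_agreement
        assert final.primary_placental == "P1"

    def test_primary_conflict_escalates_naming_the_axis(self):
        a = _det(reviewer="R1", f="F4")
        b = _det(reviewer="R2", f="F6")
        esc = reconcile_pair(a, b)
        assert isinstance(esc, EscalationRecord)
        assert esc.disagreeing_axes == [Axis.fetal_neonatal]

    def test_both_absent_on_an_axis_counts_as_agreement(self):
        a = _det(reviewer="R1", m=None, f="F4")
        b = _det(reviewer="R2", m=None, f="F4")
        assert isinstance(reconcile_pair(a, b), FinalDetermination)

    def test_contributing_sets_union_under_default_policy(self):
        ca = ContributingCause(axis=Axis.maternal, code="M3")
        cb = ContributingCause(axis=Axis.placental, code="P3")
        a = _det(reviewer="R1", f="F4", contributing=[ca])
        b = _det(reviewer="R2", f="F4", contributing=[cb])
        final = reconcile_pair(a, b)
        assert isinstance(final, FinalDetermination)
        assert set(final.contributing) == {ca, cb}

    def test_certainty_reconciles_to_the_weaker_grade(self):
        a = _det(reviewer="R1", certainty=Certainty.laboratory_confirmed)
        b = _det(reviewer="R2", certainty=Certainty.presumed)
        final = reconcile_pair(a, b)
        assert final.certainty is Certainty.presumed

    def test_preventability_mismatch_escalates_by_default(self):
        a = _det(reviewer="R1", preventable=Preventability.yes)
        b = _det(reviewer="R2", preventable=Preventability.no)
        esc = reconcile_pair(a, b)
        assert isinstance(esc, EscalationRecord)
        assert esc.preventability_conflict and esc.disagreeing_axes == []

    def test_preventability_escalation_can_be_disabled(self):
        a = _det(reviewer="R1", preventable=Preventability.yes)
        b = _det(reviewer="R2", preventable=Preventability.no)
        policy = ReconcilePolicy(escalate_on_preventability_mismatch=False)
        assert isinstance(reconcile_pair(a, b, policy), FinalDetermination)

    def test_different_cases_are_a_usage_error(self):
        with pytest.raises(ValueError, match="different cases"):
            reconcile_pair(_det(case="C1"), _det(case="C2", reviewer="R2"))

    def test_same_reviewer_twice_is_a_usage_error(self):
        with pytest.raises(ValueError, match="R1"):
            reconcile_pair(_det(reviewer="R1"), _det(reviewer="R1"))

    def test_symmetry_on_exhaustive_small_vocabulary(self):
        """Brute force over every pair of primary assignments from a 2-code
        3-axis vocabulary: reconcile(a,b) and reconcile(b,a) must make the
        same agree/escalate call, and the escalate decision must equal the
        naive predicate "some axis differs"."""
        options = {
            Axis.maternal: [None, "M1", "M2"],
            Axis.placental: [None, "P1", "P2"],
            Axis.fetal_neonatal: [None, "F1", "F2"],
        }
        combos = [c for c in itertools.product(options[Axis.maternal],
                                               options[Axis.placental],
                                               options[Axis.fetal_neonatal])
                  if any(v is not None for v in c)]
        for pa, pb in itertools.product(combos, repeat=2):
            a = _det(reviewer="R1", m=pa[0], p=pa[1], f=pa[2])
            b = _det(reviewer="R2", m=pb[0], p=pb[1], f=pb[2])
            ab, ba = reconcile_pair(a, b), reconcile_pair(b, a)
            should_escalate = pa != pb  # independent oracle
            assert isinstance(ab, EscalationRecord) == should_escalate
            assert type(ab) is type(ba)
            if isinstance(ab, EscalationRecord):
                assert ab.disagreeing_axes == ba.disagreeing_axes
            else:
                assert ab == ba


class TestPanelResolution:
    def test_escalated_case_resolves_as_full_panel(self, vocab):
        esc = reconcile_pair(_det(reviewer="R1", f="F4"),
                             _det(reviewer="R2", f="F6"))
        resolved = _det(reviewer="PANEL", f="F4")
        final = record_panel_resolution(esc, resolved, vocab)
        assert final.source is FinalSource.full_panel
        assert final.primary_fetal_neonatal == "F4"

    def test_resolution_for_wrong_case_is_rejected(self, vocab):
        esc = reconcile_pair(_det(reviewer="R1", f="F4"),
                             _det(reviewer="R2", f="F6"))
        with pytest.raises(ValueError, match="C2"):
            record_panel_resolution(esc, _det(case="C2", reviewer="PANEL"), vocab)

    def test_resolution_is_revalidated_against_vocabulary(self, vocab):
        esc = reconcile_pair(_det(reviewer="R1", f="F4"),
                             _det(reviewer="R2", f="F6"))
        with pytest.raises(ValueError, match="validation"):
            record_panel_resolution(esc, _det(reviewer="PANEL", f="BOGUS"), vocab)


class TestTally:
    def _finals(self):
        mk = lambda cid, p: FinalDetermination(
            case_id=cid, source=FinalSource.pair_agreement,
            reviewer_ids=["R1", "R2"], primary_placental=p,
            primary_fetal_neonatal="F4")
        return [mk("C1", "P1"), mk("C2", "P1"), mk("C3", "P3")]

    def test_counts_and_ordering(self):
        counts = tally_causes(self._finals(), Axis.placental)
        assert counts.index.tolist() == ["P1", "P3"]
        assert counts.tolist() == [2, 1]

    def test_empty_input_gives_empty_table(self):
        assert len(tally_causes([], Axis.maternal)) == 0

    def test_conservation_of_populated_axis_count(self):
        finals = self._finals()
        for axis in Axis:
            populated = sum(1 for f in finals if f.primary(axis) is not None)
            assert int(tally_causes(finals, axis).sum()) == populated


class TestVocabulary:
    def test_bundled_vocabulary_covers_all_axes(self, vocab):
        assert set(vocab) == set(Axis)
        assert "P1" in vocab[Axis.placental]
        assert vocab[Axis.placental].label("P1") == "Maternal vascular malperfusion"

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CauseVocabulary(axis=Axis.maternal,
                            codes=[("M1", "a"), ("M1", "b")])

    def test_weaker_certainty_is_commutative_and_ordered(self):
        grades = list(Certainty)
        for a, b in itertools.product(grades, repeat=2):
            assert weaker_certainty(a, b) == weaker_certainty(b, a)
        assert weaker_certainty(Certainty.laboratory_confirmed,
                                Certainty.clinically_supported) \
            is Certainty.clinically_supported
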