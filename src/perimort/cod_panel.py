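"""Cause-of-death determinations on three axes, and reviewer reconciliation.

Each reviewer assigns, for one case, up to three *primary* causes — one
maternal, one placental, one fetal/neonatal — so that, say, maternal
pre-eclampsia, placental vascular malperfusion, and a fetal asphyxia
episode can all be captured without forcing a choice among them.  Any
number of *contributing* causes may be added per axis.  The coding follows
the ICD-10 application to perinatal mortality (ICD-PM) for the maternal and
fetal/neonatal axes; the placental axis is a project extension, since
ICD-PM has no placental chapter.  Each determination also carries a
certainty grade (laboratory-confirmed > clinically supported > presumed)
and a judgement of theoretical preventability.

Two reviewers assess every case independently.  If their three primaries
agree (including agreeing that an axis has no cause), the pair's verdict is
final; any primary-cause conflict escalates the case to the full panel,
whose resolution is then final.  Under the default policy contributing
causes never escalate — the reconciled record takes their union — and the
reconciled certainty is the weaker (more conservative) of the two grades.
"""

from __future__ import annotations

import csv
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field

from ._resources import data_path


class Axis(str, Enum):
    maternal = "maternal"
    placental = "placental"
    fetal_neonatal = "fetal_neonatal"


AXIS_ORDER = (Axis.maternal, Axis.placental, Axis.fetal_neonatal)


class Certainty(str, Enum):
    laboratory_confirmed = "laboratory_confirmed"
    clinically_supported = "clinically_supported"
    presumed = "presumed"


# higher rank = stronger evidence; reconciliation keeps the weaker grade
_CERTAINTY_STRENGTH = {
    Certainty.presumed: 0,
    Certainty.clinically_supported: 1,
    Certainty.laboratory_confirmed: 2,
}


def weaker_certainty(a: Certainty, b: Certainty) -> Certainty:
    return a if _CERTAINTY_STRENGTH[a] <= _CERTAINTY_STRENGTH[b] else b


class Preventability(str, Enum):
    yes = "yes"
    no = "no"
    undetermined = "undetermined"


class CauseVocabulary(BaseModel):
    """The permitted (code, label) pairs for one causal axis."""

    axis: Axis
    codes: list[tuple[str, str]]
    version: str = ""

    def model_post_init(self, __context) -> None:
        ids = [c for c, _ in self.codes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate codes in {self.axis.value} vocabulary")

    def __contains__(self, code: str) -> bool:
        return any(c == code for c, _ in self.codes)

    def label(self, code: str) -> Optional[str]:
        for c, lab in self.codes:
            if c == code:
                return lab
        return None


VocabularySet = dict[Axis, CauseVocabulary]


def load_vocabulary(path: Optional[Union[str, Path]] = None) -> VocabularySet:
    """Load axis vocabularies from a CSV with columns axis, code, label,
    version.  Defaults to the bundled starter vocabulary: coarse ICD-PM
    group headings for the maternal and fetal/neonatal axes and a
    project-defined placental lesion list (no claim of official-code
    fidelity — supply your own code book for production coding)."""
    p = Path(path) if path is not None else data_path("cause_vocabulary.csv")
    rows: dict[Axis, list[tuple[str, str]]] = {a: [] for a in Axis}
    versions: dict[Axis, str] = {a: "" for a in Axis}
    with open(p, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            axis = Axis(row["axis"])
            rows[axis].append((row["code"].strip(), row["label"].strip()))
            versions[axis] = row.get("version", "").strip()
    return {a: CauseVocabulary(axis=a, codes=rows[a], version=versions[a])
            for a in Axis if rows[a]}


class ContributingCause(BaseModel):
    model_config = {"frozen": True}
    axis: Axis
    code: str


class Determination(BaseModel):
    """One reviewer's full cause-of-death assignment for one case.

    A primary of ``None`` means "no cause identified on this axis"; at
    least one axis must carry a primary cause.
    """

    case_id: str
    reviewer_id: str
    primary_maternal: Optional[str] = None
    primary_placental: Optional[str] = None
    primary_fetal_neonatal: Optional[str] = None
    contributing: list[ContributingCause] = Field(default_factory=list)
    certainty: Certainty = Certainty.presumed
    preventable: Preventability = Preventability.undetermined

    def primary(self, axis: Axis) -> Optional[str]:
        return {
            Axis.maternal: self.primary_maternal,
            Axis.placental: self.primary_placental,
            Axis.fetal_neonatal: self.primary_fetal_neonatal,
        }[axis]

    def primaries(self) -> dict[Axis, Optional[str]]:
        return {a: self.primary(a) for a in AXIS_ORDER}


class DeterminationViolation(BaseModel):
    case_id: str
    reviewer_id: str
    axis: Optional[Axis] = None
    rule: str
    message: str


def validate_determination(d: Determination,
                           vocab: VocabularySet) -> list[DeterminationViolation]:
    """Check a determination against the vocabularies; empty list iff valid."""
    v: list[DeterminationViolation] = []

    def _bad(axis, rule, msg):
        v.append(DeterminationViolation(case_id=d.case_id, reviewer_id=d.reviewer_id,
                                        axis=axis, rule=rule, message=msg))

    primaries = d.primaries()
    if all(code is None for code in primaries.values()):
        _bad(None, "at-least-one-primary", "no primary cause on any axis")
    for axis, code in primaries.items():
        if code is None:
            continue
        vb = vocab.get(axis)
        if vb is None or code not in vb:
            _bad(axis, "primary-in-vocabulary",
                 f"code {code!r} not in the {axis.value} vocabulary")
    seen: set[tuple[Axis, str]] = set()
    for c in d.contributing:
        vb = vocab.get(c.axis)
        if vb is None or c.code not in vb:
            _bad(c.axis, "contributing-in-vocabulary",
                 f"code {c.code!r} not in the {c.axis.value} vocabulary")
        if primaries.get(c.axis) == c.code:
            _bad(c.axis, "contributing-distinct-from-primary",
                 f"contributing cause {c.code!r} duplicates the {c.axis.value} primary")
        if (c.axis, c.code) in seen:
            _bad(c.axis, "contributing-unique",
                 f"contributing cause {c.code!r} listed twice on {c.axis.value}")
        seen.add((c.axis, c.code))
    return v


class FinalSource(str, Enum):
    pair_agreement = "pair_agreement"
    full_panel = "full_panel"


class FinalDetermination(BaseModel):
    case_id: str
    source: FinalSource
    reviewer_ids: list[str]
    primary_maternal: Optional[str] = None
    primary_placental: Optional[str] = None
    primary_fetal_neonatal: Optional[str] = None
    contributing: list[ContributingCause] = Field(default_factory=list)
    certainty: Certainty = Certainty.presumed
    preventable: Preventability = Preventability.undetermined

    def primary(self, axis: Axis) -> Optional[str]:
        return {
            Axis.maternal: self.primary_maternal,
            Axis.placental: self.primary_placental,
            Axis.fetal_neonatal: self.primary_fetal_neonatal,
        }[axis]


class EscalationRecord(BaseModel):
    """A pair conflict: the case goes to the full panel for resolution."""

    case_id: str
    reviewer_ids: list[str]
    disagreeing_axes: list[Axis]
    preventability_conflict: bool = False
    determinations: list[Determination]


class ReconcilePolicy(BaseModel):
    """Knobs for pair reconciliation.  ``contributing`` is ``union`` (keep
    everything either reviewer noted) or ``intersection``; escalation on a
    preventability mismatch is on by default."""

    contributing: str = "union"
    escalate_on_preventability_mismatch: bool = True


def _merge_contributing(a: Determination, b: Determination,
                        policy: ReconcilePolicy) -> list[ContributingCause]:
    sa, sb = set(a.contributing), set(b.contributing)
    merged = sa | sb if policy.contributing == "union" else sa & sb
    axis_rank = {ax: i for i, ax in enumerate(AXIS_ORDER)}
    return sorted(merged, key=lambda c: (axis_rank[c.axis], c.code))


def reconcile_pair(a: Determination, b: Determination,
                   policy: Optional[ReconcilePolicy] = None
                   ) -> Union[FinalDetermination, EscalationRecord]:
    """Reconcile a reviewer pair's determinations for one case.

    Agreement requires the three primaries to match exactly (an axis left
    empty by both reviewers is agreement that no cause was identified) and,
    by default, the preventability judgements to match.  The result is
    symmetric in its two arguments.
    """
    if a.case_id != b.case_id:
        raise ValueError(f"determinations are for different cases "
                         f"({a.case_id!r} vs {b.case_id!r})")
    if a.reviewer_id == b.reviewer_id:
        raise ValueError(f"case {a.case_id}: both determinations are from "
                         f"reviewer {a.reviewer_id!r}")
    policy = policy or ReconcilePolicy()
    reviewers = sorted([a.reviewer_id, b.reviewer_id])

    disagree = [ax for ax in AXIS_ORDER if a.primary(ax) != b.primary(ax)]
    prev_conflict = (policy.escalate_on_preventability_mismatch
                     and a.preventable != b.preventable)
    if disagree or prev_conflict:
        return EscalationRecord(
            case_id=a.case_id, reviewer_ids=reviewers,
            disagreeing_axes=disagree, preventability_conflict=prev_conflict,
            determinations=sorted([a, b], key=lambda d: d.reviewer_id))
    return FinalDetermination(
        case_id=a.case_id, source=FinalSource.pair_agreement,
        reviewer_ids=reviewers,
        primary_maternal=a.primary_maternal,
        primary_placental=a.primary_placental,
        primary_fetal_neonatal=a.primary_fetal_neonatal,
        contributing=_merge_contributing(a, b, policy),
        certainty=weaker_certainty(a.certainty, b.certainty),
        preventable=a.preventable,
    )


def record_panel_resolution(esc: EscalationRecord, resolved: Determination,
                            vocab: Optional[VocabularySet] = None
                            ) -> FinalDetermination:
    """Turn a full-panel resolution of an escalated case into the final
    determination (source ``full_panel``).  The resolution is re-validated
    against the vocabulary when one is supplied."""
    if resolved.case_id != esc.case_id:
        raise ValueError(f"resolution is for case {resolved.case_id!r}, "
                         f"escalation is for {esc.case_id!r}")
    if vocab is not None:
        problems = validate_determination(resolved, vocab)
        if problems:
            raise ValueError(
                f"case {esc.case_id}: panel resolution fails validation: "
                + "; ".join(p.message for p in problems))
    return FinalDetermination(
        case_id=esc.case_id, source=FinalSource.full_panel,
        reviewer_ids=[resolved.reviewer_id],
        primary_maternal=resolved.primary_maternal,
        primary_placental=resolved.primary_placental,
        primary_fetal_neonatal=resolved.primary_fetal_neonatal,
        contributing=list(resolved.contributing),
        certainty=resolved.certainty,
        preventable=resolved.preventable,
    )


def tally_causes(finals: Sequence[FinalDetermination], axis: Axis) -> pd.Series:
    """Frequency table of primary causes on one axis, most common first
    (ties broken by code).  The counts sum to the number of final
    determinations with that axis populated."""
    codes = [f.primary(axis) for f in finals if f.primary(axis) is not None]
    if not codes:
        return pd.Series(dtype=int, name=f"n_{axis.value}")
    counts = pd.Series(codes).value_counts()
    counts = counts.iloc[
        sorted(range(len(counts)),
               key=lambda i: (-int(counts.iloc[i]), str(counts.index[i])))]
    counts.name = f"n_{axis.value}"
    return counts
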