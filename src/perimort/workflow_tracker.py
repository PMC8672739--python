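"""Case-flow ledger: from registration through panel determination.

Every death moves through a fixed pipeline: the draft report goes to the
local site for a completeness/accuracy review, is finalized, and — only
once every study form is complete or omitted-with-reason — is assigned to a
two-reviewer pair.  The pair's agreed determination is final; a conflict
escalates the case to the full panel.  The ledger records where each case
stands, the dates it was circulated, and per-form completeness, and
round-trips losslessly through CSV so the audit trail is diff-able.

Two structural rules are enforced here rather than by convention:

* the completeness gate — a case cannot be assigned to reviewers while any
  form is simply missing;
* multiple-birth grouping — deaths sharing a pregnancy are always reviewed
  in the same batch.
"""

from __future__ import annotations

import csv
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

from pydantic import BaseModel, Field

from .case_model import CaseRecord, CompletionStatus, FormStatusValue, completion_status


class State(str, Enum):
    registered = "registered"
    sent_to_site = "sent_to_site"
    site_reviewed = "site_reviewed"
    finalized = "finalized"
    assigned_to_pair = "assigned_to_pair"
    determined = "determined"
    escalated = "escalated"
    panel_determined = "panel_determined"


# event -> (required current state, next state); escalation may only follow
# pair assignment, and a panel determination only follows an escalation
TRANSITIONS: dict[str, tuple[State, State]] = {
    "sent_to_site": (State.registered, State.sent_to_site),
    "site_reviewed": (State.sent_to_site, State.site_reviewed),
    "finalized": (State.site_reviewed, State.finalized),
    "assigned_to_pair": (State.finalized, State.assigned_to_pair),
    "determined": (State.assigned_to_pair, State.determined),
    "conflict": (State.assigned_to_pair, State.escalated),
    "panel_determined": (State.escalated, State.panel_determined),
}


class TransitionError(ValueError):
    def __init__(self, case_id: str, current: State, event: str):
        self.case_id, self.current, self.event = case_id, current, event
        super().__init__(
            f"case {case_id}: event {event!r} is illegal from state {current.value!r}")


class GateError(ValueError):
    pass


class LedgerEntry(BaseModel):
    case_id: str
    pregnancy_id: str
    state: State = State.registered
    date_sent_to_site: Optional[date] = None
    date_sent_to_panel: Optional[date] = None
    forms_complete: dict[str, bool] = Field(default_factory=dict)
    review_batch_id: str = ""


class ReviewBatch(BaseModel):
    batch_id: str
    case_ids: list[str]
    reviewer_pair: Optional[tuple[str, str]] = None
    meeting_date: Optional[date] = None

    def model_post_init(self, __context) -> None:
        if self.reviewer_pair is not None and self.reviewer_pair[0] == self.reviewer_pair[1]:
            raise ValueError(f"batch {self.batch_id}: reviewer ids must be distinct")


def advance_state(entry: LedgerEntry, event: str,
                  on: Optional[date] = None) -> LedgerEntry:
    """Apply one workflow event, returning a new entry (the input is never
    mutated, so a rejected transition leaves the ledger untouched).

    Timestamps are supplied by the caller via ``on`` rather than read from
    the wall clock, keeping replays and tests deterministic.
    """
    if event not in TRANSITIONS:
        raise TransitionError(entry.case_id, entry.state, event)
    required, nxt = TRANSITIONS[event]
    if entry.state is not required:
        raise TransitionError(entry.case_id, entry.state, event)
    updates: dict = {"state": nxt}
    if nxt is State.sent_to_site and on is not None:
        updates["date_sent_to_site"] = on
    if nxt is State.assigned_to_pair:
        if not entry.forms_complete or not all(entry.forms_complete.values()):
            raise GateError(
                f"case {entry.case_id}: cannot assign to a reviewer pair "
                f"before every form is complete or omitted-with-reason")
        if on is not None:
            updates["date_sent_to_panel"] = on
    new = entry.model_copy(update=updates)
    if (new.date_sent_to_panel is not None and new.date_sent_to_site is not None
            and new.date_sent_to_panel < new.date_sent_to_site):
        raise TransitionError(entry.case_id, entry.state, event)
    return new


def gate_for_panel(entry: LedgerEntry, case: CaseRecord) -> bool:
    """Completeness gate: true only when every form is complete or omitted
    with a documented reason.  As a side effect the entry's per-form
    completeness map is refreshed from the case record."""
    status, breakdown = completion_status(case)
    entry.forms_complete = {
        form: st in (FormStatusValue.complete, FormStatusValue.omitted)
        for form, st in breakdown.items()
    }
    return status is CompletionStatus.complete


def group_multiples(cases: Sequence[CaseRecord],
                    batch_size: int = 7) -> list[ReviewBatch]:
    """Partition cases into review batches such that no pregnancy spans two
    batches — both infants of a multiple birth are always reviewed together.

    ``batch_size`` defaults to 7 cases, matching a one-hour meeting at the
    observed review pace; a multiple-birth group larger than the batch size
    still stays together (the batch simply runs long).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for c in cases:
        if c.pregnancy_id not in groups:
            groups[c.pregnancy_id] = []
            order.append(c.pregnancy_id)
        groups[c.pregnancy_id].append(c.case_id)

    batches: list[ReviewBatch] = []
    current: list[str] = []
    for pid in order:
        grp = groups[pid]
        if current and len(current) + len(grp) > batch_size:
            batches.append(ReviewBatch(batch_id=f"B{len(batches) + 1:03d}",
                                       case_ids=current))
            current = []
        current.extend(grp)
    if current:
        batches.append(ReviewBatch(batch_id=f"B{len(batches) + 1:03d}",
                                   case_ids=current))
    return batches


def validate_batches(batches: Sequence[ReviewBatch],
                     cases: Sequence[CaseRecord]) -> list[str]:
    """Return descriptions of grouping violations (pregnancies split across
    batches, cases batched more than once); empty when the grouping is legal."""
    pregnancy_of = {c.case_id: c.pregnancy_id for c in cases}
    batch_of: dict[str, str] = {}
    problems: list[str] = []
    for b in batches:
        for cid in b.case_ids:
            if cid in batch_of:
                problems.append(f"case {cid} appears in batches {batch_of[cid]} and {b.batch_id}")
            batch_of[cid] = b.batch_id
    seen: dict[str, str] = {}
    for cid, bid in batch_of.items():
        pid = pregnancy_of.get(cid)
        if pid is None:
            continue
        if pid in seen and seen[pid] != bid:
            problems.append(f"pregnancy {pid} is split across batches {seen[pid]} and {bid}")
        seen.setdefault(pid, bid)
    return problems


def estimate_panel_hours(n_cases: int, cases_per_hour: float) -> float:
    """Panel time needed to review a caseload at a given pace (cases/hour)."""
    if cases_per_hour <= 0:
        raise ValueError(f"cases_per_hour must be positive, got {cases_per_hour}")
    return n_cases / cases_per_hour


# ---------------------------------------------------------------------------
# CSV ledger
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["case_id", "pregnancy_id", "state", "date_sent_to_site",
                  "date_sent_to_panel", "review_batch_id"]


def export_ledger(entries: Sequence[LedgerEntry], path: Union[str, Path]) -> None:
    """Write the ledger as CSV: one row per case with ids, state, dates
    (ISO-8601) and one ``form:<name>`` completeness column per form."""
    form_cols: list[str] = []
    for e in entries:
        for form in e.forms_complete:
            if form not in form_cols:
                form_cols.append(form)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_FIXED_COLUMNS + [f"form:{f}" for f in form_cols])
        for e in entries:
            row = [e.case_id, e.pregnancy_id, e.state.value,
                   e.date_sent_to_site.isoformat() if e.date_sent_to_site else "",
                   e.date_sent_to_panel.isoformat() if e.date_sent_to_panel else "",
                   e.review_batch_id]
            for f in form_cols:
                if f in e.forms_complete:
                    row.append("true" if e.forms_complete[f] else "false")
                else:
                    row.append("")
            w.writerow(row)


def import_ledger(path: Union[str, Path]) -> list[LedgerEntry]:
    entries: list[LedgerEntry] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            forms = {}
            for col, val in row.items():
                if col.startswith("form:") and val != "":
                    forms[col[len("form:"):]] = val == "true"
            entries.append(LedgerEntry(
                case_id=row["case_id"],
                pregnancy_id=row["pregnancy_id"],
                state=State(row["state"]),
                date_sent_to_site=date.fromisoformat(row["date_sent_to_site"])
                if row["date_sent_to_site"] else None,
                date_sent_to_panel=date.fromisoformat(row["date_sent_to_panel"])
                if row["date_sent_to_panel"] else None,
                forms_complete=forms,
                review_batch_id=row["review_batch_id"],
            ))
    return entries
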