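"""Derived summary values and reference-standard comparisons.

The case report embeds a handful of values that are computed rather than
copied from the study forms: age at death, total NICU days, and comparisons
against published growth standards (10th-percentile birthweight by
gestational age and sex; mean placental weight by gestational age).  The
comparison lets panelists judge, e.g., whether a histologically normal but
light placenta suggests maternal vascular malperfusion.

Conventions, stated here because the underlying clinical usage is ambiguous:

* age at death is the floor of elapsed time in whole days (birth at 08:00,
  death 71 hours later -> 2 days);
* NICU days are counted inclusively (admission day is day 1, so a stay
  admitted and discharged on the same date counts 1 day);
* small-for-gestational-age uses a strict inequality: birthweight exactly
  at the 10th percentile is *not* SGA;
* reference lookups are exact per completed week, with no interpolation,
  and an out-of-range lookup degrades to "reference unavailable" rather
  than aborting report generation.
"""

from __future__ import annotations

import csv
from datetime import datetime
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel

from .case_model import CaseRecord, CaseType, NICUDayRecord, NICUStay


class ChronologyError(ValueError):
    """Death recorded before birth."""

    def __init__(self, case_id: str, birth: datetime, death: datetime):
        self.case_id = case_id
        super().__init__(
            f"case {case_id}: death {death.isoformat()} precedes birth {birth.isoformat()}"
        )


class ReferenceTableError(ValueError):
    pass


class ReferenceTable(BaseModel):
    """Growth standards keyed by completed gestational week.

    ``birthweight_p10`` maps (week, sex) to the 10th-percentile birthweight
    in grams; ``placental_mean`` maps week to the mean placental weight in
    grams.  Both must be strictly increasing in gestational age over a
    contiguous week range — the monotonicity check catches transcription
    errors in user-supplied tables.
    """

    birthweight_p10: dict[tuple[int, str], float]
    placental_mean: dict[int, float]
    provenance: str = ""

    def validate_monotone(self) -> None:
        by_sex: dict[str, dict[int, float]] = {}
        for (week, sex), grams in self.birthweight_p10.items():
            by_sex.setdefault(sex, {})[week] = grams
        for sex, rows in by_sex.items():
            weeks = sorted(rows)
            if weeks != list(range(weeks[0], weeks[-1] + 1)):
                raise ReferenceTableError(
                    f"birthweight weeks for sex {sex!r} are not contiguous")
            vals = [rows[w] for w in weeks]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ReferenceTableError(
                    f"birthweight p10 not strictly increasing for sex {sex!r}")
        weeks = sorted(self.placental_mean)
        if weeks:
            if weeks != list(range(weeks[0], weeks[-1] + 1)):
                raise ReferenceTableError("placental weeks are not contiguous")
            vals = [self.placental_mean[w] for w in weeks]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ReferenceTableError("placental mean not strictly increasing")


def load_reference_table(path: Optional[Union[str, Path]] = None) -> ReferenceTable:
    """Load a reference CSV with columns ga_weeks, sex, measure, grams.

    ``measure`` is ``bw_p10`` or ``placenta_mean``; placental rows use sex
    ``any``.  The loaded table is monotonicity-checked before use.  With no
    path, the bundled *synthetic* table is loaded — a labelled stand-in,
    not published standards.
    """
    if path is None:
        from ._resources import data_path
        path = data_path("synthetic_reference_table.csv")
    bw: dict[tuple[int, str], float] = {}
    pl: dict[int, float] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            week = int(row["ga_weeks"])
            grams = float(row["grams"])
            measure = row["measure"].strip()
            if measure == "bw_p10":
                bw[(week, row["sex"].strip())] = grams
            elif measure == "placenta_mean":
                pl[week] = grams
            else:
                raise ReferenceTableError(f"unknown measure {measure!r} in {path}")
    table = ReferenceTable(birthweight_p10=bw, placental_mean=pl,
                           provenance=str(path))
    table.validate_monotone()
    return table


def save_reference_table(table: ReferenceTable, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ga_weeks", "sex", "measure", "grams"])
        for (week, sex), grams in sorted(table.birthweight_p10.items()):
            w.writerow([week, sex, "bw_p10", f"{grams:g}"])
        for week, grams in sorted(table.placental_mean.items()):
            w.writerow([week, "any", "placenta_mean", f"{grams:g}"])


def compute_age_at_death(birth: datetime, death: datetime, case_id: str = "") -> int:
    """Age at death in whole days (floor of elapsed time)."""
    if death < birth:
        raise ChronologyError(case_id or "<unknown>", birth, death)
    return int((death - birth).total_seconds() // 86400)


def compute_total_nicu_days(stays: list[NICUStay]) -> int:
    """Total calendar days across stays, counting inclusively."""
    return sum((s.discharge_date - s.admission_date).days + 1 for s in stays)


def lookup_birthweight_p10(table: ReferenceTable, ga_weeks: Optional[int],
                           sex: Optional[str]) -> Optional[float]:
    """10th-percentile birthweight in grams, or None when unavailable."""
    if ga_weeks is None or sex is None:
        return None
    return table.birthweight_p10.get((int(ga_weeks), str(sex)))


def lookup_mean_placental_weight(table: ReferenceTable,
                                 ga_weeks: Optional[int]) -> Optional[float]:
    """Mean placental weight in grams, or None when unavailable."""
    if ga_weeks is None:
        return None
    return table.placental_mean.get(int(ga_weeks))


def classify_sga(birthweight_g: float, p10_g: float) -> bool:
    """Small for gestational age: strictly below the 10th percentile."""
    return birthweight_g < p10_g


_DAY_CATEGORIES = (
    ("diagnoses", "diagnoses"),
    ("appearance", "appearance"),
    ("signs_symptoms", "signs/symptoms"),
    ("treatments", "treatments"),
)


def summarize_nicu_day(day: NICUDayRecord) -> str:
    parts = []
    for attr, label in _DAY_CATEGORIES:
        items = getattr(day, attr)
        if items:
            parts.append(f"{label}: {', '.join(items)}")
    if not parts:
        return f"Day {day.day_index}: no findings recorded"
    return f"Day {day.day_index}: " + "; ".join(parts)


def summarize_nicu_days(stay: NICUStay) -> list[str]:
    """One line per NICU day in date order: day index, then the non-empty
    categories (diagnoses; appearance; signs/symptoms; treatments)."""
    return [summarize_nicu_day(d) for d in sorted(stay.days, key=lambda d: d.date)]


class DerivedSummary(BaseModel):
    """Computed values the report embeds alongside the form data.

    Every member may be None: a value is undefined whenever its inputs were
    not answered (or, for reference values, the table does not cover the
    case's gestational week).  ``sga_flag`` is defined exactly when
    birthweight, gestational age, and sex are all answered and the table
    covers that week.
    """

    age_at_death_days: Optional[int] = None
    total_nicu_days: int = 0
    sga_flag: Optional[bool] = None
    birthweight_p10_value: Optional[float] = None
    placental_mean_value: Optional[float] = None


def _as_datetime(value) -> Optional[datetime]:
    if isinstance(value, datetime):
        return value
    if isinstance(value, str):
        try:
            return datetime.fromisoformat(value)
        except ValueError:
            return None
    return None


def _as_number(value) -> Optional[float]:
    if isinstance(value, (int, float)):
        return float(value)
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def derive_summary(case: CaseRecord, table: Optional[ReferenceTable] = None) -> DerivedSummary:
    """Compute the full derived summary for one case.

    Missing inputs degrade to undefined values; this function never raises
    for absent data, only for a death recorded before birth.
    """
    out = DerivedSummary()

    if case.case_type is CaseType.neonatal_death:
        b = case.get_birth_field("date/time of delivery")
        d = case.get_birth_field("date/time of death")
        bt = _as_datetime(b.value) if b else None
        dt = _as_datetime(d.value) if d else None
        if bt is not None and dt is not None:
            out.age_at_death_days = compute_age_at_death(bt, dt, case.case_id)
        out.total_nicu_days = compute_total_nicu_days(case.nicu_stays)

    if table is not None:
        ga_f = case.get_birth_field("gestational age (weeks)")
        sex_f = case.get_birth_field("gender")
        bw_f = case.get_birth_field("birth weight (grams)")
        ga = int(_as_number(ga_f.value)) if ga_f and _as_number(ga_f.value) is not None else None
        sex = str(sex_f.value) if sex_f and sex_f.answered else None
        bw = _as_number(bw_f.value) if bw_f and bw_f.answered else None
        out.birthweight_p10_value = lookup_birthweight_p10(table, ga, sex)
        out.placental_mean_value = lookup_mean_placental_weight(table, ga)
        if bw is not None and out.birthweight_p10_value is not None:
            out.sga_flag = classify_sga(bw, out.birthweight_p10_value)
    return out
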