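"""Data model and tabular I/O for longitudinal child growth records.

A cohort is a collection of children, each with dated height/weight visits.
Heights are stored in cm in raw form and as log(height in metres) on the
model scale, so that log(BMI) = log(weight) - 2*log(height_m) is a linear
contrast of the modelled outcome vector.  Registers record many visits per
child per year; the analysis keeps one representative measurement per
age-year (birthday-to-birthday), the one closest after the birthday.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

# closed integer age-year windows for the two models, and the age each
# model's intercept refers to
MODEL1_WINDOW = (2, 5)
MODEL2_WINDOW = (6, 11)
MODEL1_CENTER = 2.0
MODEL2_CENTER = 6.0

DEFAULT_DIALECT = {
    "child_id": "child_id",
    "birth_date": "birth_date",
    "visit_date": "visit_date",
    "height_cm": "height_cm",
    "weight_kg": "weight_kg",
}


def age_in_years(birth_date: date, visit_date: date) -> float:
    """Age as exact day count / 365.25 (deterministic, leap-safe)."""
    return (visit_date - birth_date).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class Measurement:
    """One child-visit with raw and log-scale outcomes.

    ``log_height`` is log of height in metres so that the BMI contrast
    applies directly; ``log_weight`` is log of weight in kg.
    """

    child_id: str
    birth_date: date
    visit_date: date
    height_cm: float
    weight_kg: float

    @property
    def age(self) -> float:
        return age_in_years(self.birth_date, self.visit_date)

    @property
    def age_year(self) -> int:
        """Integer age-year the visit belongs to (floor of age)."""
        return int(math.floor(self.age))

    @property
    def log_height(self) -> float:
        return math.log(self.height_cm / 100.0)

    @property
    def log_weight(self) -> float:
        return math.log(self.weight_kg)


@dataclass
class ChildRecord:
    """All retained measurements of one child, ascending in age."""

    child_id: str
    birth_date: date
    measurements: list[Measurement] = field(default_factory=list)

    @property
    def T_i(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class GroupAssignment:
    """Contribution / target flags for one child.

    ``in_contributing``: >= 2 measurements at distinct age-years inside the
    contributing calendar window.  ``in_target``: measured in the target
    year at a target age.  ``in_contributing_2021``: both.  Model
    membership: at least one retained contributing-window measurement in
    the model's age window.
    """

    child_id: str
    in_contributing: bool
    in_target: bool
    in_contributing_2021: bool
    model_membership: frozenset[str]
    age_in_2021: int | None

    def __post_init__(self):
        if self.in_contributing_2021 != (self.in_contributing and self.in_target):
            raise ValueError("in_contributing_2021 must equal in_contributing AND in_target")


class CohortConfigError(ValueError):
    """Raised for unusable column mappings or group definitions."""


def read_cohort(path, dialect: dict | None = None) -> list[ChildRecord]:
    """Read a delimited visit table into ChildRecords.

    One row per visit; dates ISO-8601.  Rows with non-positive height or
    weight, or unparseable fields, are rejected and logged with their line
    number.  Missing required columns raise :class:`CohortConfigError`.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    children: dict[str, ChildRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = [v for v in dialect.values() if v not in reader.fieldnames]
        if missing:
            raise CohortConfigError(f"missing required columns: {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                m = Measurement(
                    child_id=row[dialect["child_id"]],
                    birth_date=date.fromisoformat(row[dialect["birth_date"]]),
                    visit_date=date.fromisoformat(row[dialect["visit_date"]]),
                    height_cm=float(row[dialect["height_cm"]]),
                    weight_kg=float(row[dialect["weight_kg"]]),
                )
                if m.height_cm <= 0 or m.weight_kg <= 0:
                    raise ValueError("non-positive height or weight")
                if m.visit_date < m.birth_date:
                    raise ValueError("visit before birth")
            except (ValueError, KeyError) as exc:
                logger.warning("rejected row at line %d: %s", lineno, exc)
                continue
            rec = children.setdefault(m.child_id, ChildRecord(m.child_id, m.birth_date))
            rec.measurements.append(m)
    for rec in children.values():
        rec.measurements.sort(key=lambda m: (m.age, m.visit_date))
    return list(children.values())


def write_cohort(path, cohort: list[ChildRecord], dialect: dict | None = None) -> None:
    """Write a cohort back to the visit-table CSV form read by read_cohort."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    cols = [dialect[k] for k in ("child_id", "birth_date", "visit_date", "height_cm", "weight_kg")]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in cohort:
            for m in rec.measurements:
                writer.writerow(
                    [m.child_id, m.birth_date.isoformat(), m.visit_date.isoformat(),
                     format(m.height_cm, "g"), format(m.weight_kg, "g")]
                )


def select_annual_measurements(visits: list[Measurement]) -> list[Measurement]:
    """Keep one measurement per integer age-year: the one closest after the
    preceding birthday; ties broken by earlier visit date.  Idempotent."""
    best: dict[int, Measurement] = {}
    for m in visits:
        y = m.age_year
        cur = best.get(y)
        if cur is None:
            best[y] = m
            continue
        key_new = (m.age - y, m.visit_date)
        key_cur = (cur.age - y, cur.visit_date)
        if key_new < key_cur:
            best[y] = m
    return [best[y] for y in sorted(best)]


def _age_at_year(birth_date: date, year: int) -> int:
    """Integer age attained during calendar `year` (age at that birthday)."""
    return year - birth_date.year


def assign_groups(
    cohort: list[ChildRecord],
    contributing_years: tuple[int, int] = (2014, 2020),
    target_year: int = 2021,
    target_ages: tuple[int, int] = (4, 11),
) -> list[GroupAssignment]:
    """Assign contribution / target flags to each child.

    Contributing: >=2 retained measurements at distinct age-years with visit
    dates inside [contributing_years].  Target: a visit in target_year at an
    integer age within target_ages.  Model membership is per age window
    within the contributing years.
    """
    lo, hi = contributing_years
    if lo <= target_year <= hi:
        raise CohortConfigError("target_year must lie outside contributing_years")
    out = []
    for rec in cohort:
        retained = select_annual_measurements(rec.measurements)
        contrib = [m for m in retained if lo <= m.visit_date.year <= hi]
        contrib_age_years = {m.age_year for m in contrib}
        in_contributing = len(contrib_age_years) >= 2
        target_visits = [
            m for m in retained
            if m.visit_date.year == target_year
            and target_ages[0] <= m.age_year <= target_ages[1]
        ]
        in_target = bool(target_visits)
        age_in_2021 = target_visits[0].age_year if in_target else None
        membership = set()
        if in_contributing:
            if any(MODEL1_WINDOW[0] <= y <= MODEL1_WINDOW[1] for y in contrib_age_years):
                membership.add("model1")
            if any(MODEL2_WINDOW[0] <= y <= MODEL2_WINDOW[1] for y in contrib_age_years):
                membership.add("model2")
        out.append(
            GroupAssignment(
                child_id=rec.child_id,
                in_contributing=in_contributing,
                in_target=in_target,
                in_contributing_2021=in_contributing and in_target,
                model_membership=frozenset(membership),
                age_in_2021=age_in_2021,
            )
        )
    return out


def write_groups(path, groups: list[GroupAssignment]) -> None:
    rows = [
        {
            "child_id": g.child_id,
            "in_contributing": int(g.in_contributing),
            "in_target": int(g.in_target),
            "in_contributing_2021": int(g.in_contributing_2021),
            "model1": int("model1" in g.model_membership),
            "model2": int("model2" in g.model_membership),
            "age_in_2021": "" if g.age_in_2021 is None else g.age_in_2021,
        }
        for g in groups
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def to_model_frame(
    cohort: list[ChildRecord],
    window: tuple[int, int],
    centering_age: float,
    contributing_years: tuple[int, int] = (2014, 2020),
    groups: list[GroupAssignment] | None = None,
) -> pd.DataFrame:
    """Stacked observation table for one age-window model.

    Rows: retained contributing-window measurements of contributing children
    whose integer age-year falls in `window`.  Columns: child_id, age,
    age_year, a (= age - centering_age), log_height, log_weight.
    """
    if groups is None:
        groups = assign_groups(cohort, contributing_years=contributing_years)
    contributing_ids = {g.child_id for g in groups if g.in_contributing}
    lo_y, hi_y = contributing_years
    rows = []
    for rec in cohort:
        if rec.child_id not in contributing_ids:
            continue
        for m in select_annual_measurements(rec.measurements):
            if not (lo_y <= m.visit_date.year <= hi_y):
                continue
            if not (window[0] <= m.age_year <= window[1]):
                continue
            rows.append(
                {
                    "child_id": m.child_id,
                    "age": m.age,
                    "age_year": m.age_year,
                    "a": m.age - centering_age,
                    "log_height": m.log_height,
                    "log_weight": m.log_weight,
                }
            )
    if not rows:
        raise ValueError(f"no observations in age window {window}")
    frame = pd.DataFrame(rows).sort_values(["child_id", "age"], kind="stable")
    return frame.reset_index(drop=True)


def measurements_from_row(child_id: str, birth: date, age: float,
                          height_cm: float, weight_kg: float) -> Measurement:
    """Build a Measurement from a fractional age (helper for simulation)."""
    visit = birth + timedelta(days=round(age * DAYS_PER_YEAR))
    return Measurement(child_id, birth, visit, height_cm, weight_kg)
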