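"""Calculated variables derived from raw registration and visit inputs:
age, BMI, gestational age, estimated delivery date, shock index."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

__all__ = [
    "DomainError",
    "DerivedVars",
    "age_years",
    "bmi",
    "gestational_age_days",
    "estimated_delivery_date",
    "shock_index",
    "compute_derived",
]

GESTATION_DAYS = 280  # Naegele rule: EDD = LMP + 280 days


class DomainError(ValueError):
    """An input is outside the domain of a derived-variable formula."""


@dataclass(frozen=True)
class DerivedVars:
    age: int  # completed years at the visit
    bmi: float  # kg/m^2
    gestational_age_days: int  # completed days since LMP at the visit
    edd: date
    shock_index: float  # heart_rate / sbp
    postpartum_day: Optional[int] = None  # days since delivery, if delivered


def age_years(date_of_birth: date, reference_date: date) -> int:
    """Completed years at ``reference_date`` (floor; birthday not yet reached
    in the reference year subtracts one)."""
    if reference_date < date_of_birth:
        raise DomainError("reference_date before date_of_birth")
    years = reference_date.year - date_of_birth.year
    if (reference_date.month, reference_date.day) < (date_of_birth.month, date_of_birth.day):
        years -= 1
    return years


def bmi(weight: float, height: float) -> float:
    """Body mass index, weight [kg] / height [m] squared."""
    if height <= 0:
        raise DomainError("height must be positive")
    return weight / (height * height)


def gestational_age_days(lmp_date: date, on_date: date) -> int:
    """Calendar days elapsed since the last menstrual period."""
    if on_date < lmp_date:
        raise DomainError("on_date before lmp_date")
    return (on_date - lmp_date).days


def estimated_delivery_date(lmp_date: date) -> date:
    return lmp_date + timedelta(days=GESTATION_DAYS)


def shock_index(heart_rate: float, sbp: float) -> float:
    """Heart rate divided by systolic blood pressure; undefined for sbp <= 0
    (an error, never infinity)."""
    if sbp <= 0:
        raise DomainError("sbp must be positive for shock index")
    return heart_rate / sbp


def compute_derived(participant, visit) -> DerivedVars:
    """Assemble all derived variables for one visit of one participant.

    BMI uses the booking weight/height; postpartum_day is present only when
    the woman has delivered on or before the visit date.
    """
    postpartum_day = None
    if participant.delivery_date is not None and visit.visit_date >= participant.delivery_date:
        postpartum_day = (visit.visit_date - participant.delivery_date).days
    return DerivedVars(
        age=age_years(participant.date_of_birth, visit.visit_date),
        bmi=bmi(participant.weight, participant.height),
        gestational_age_days=gestational_age_days(participant.lmp_date, visit.visit_date),
        edd=estimated_delivery_date(participant.lmp_date),
        shock_index=shock_index(visit.heart_rate, visit.sbp),
        postpartum_day=postpartum_day,
    )
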