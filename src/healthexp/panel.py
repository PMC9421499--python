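"""Panel data containers: individuals, dated waves, derived states.

All dates are Gregorian; the month is the finest dated unit of the analysis
(day-of-month is kept on wave dates because the whitespace interchange
dialect requires it, and it participates in rounding ages to whole months).
State codes: 0 disability-free, 1 disabled, 2 dead, -1 unknown.
"""

from __future__ import annotations

import copy
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

UNKNOWN: int = -1
STATE_FREE: int = 0
STATE_DISABLED: int = 1
STATE_DEAD: int = 2

#: analysis covariates carried by every record
COVARIATE_FIELDS = ("education", "obese", "smoker", "exercise")


def month_index(year: int, month: int) -> int:
    """Serial month number (year * 12 + month - 1)."""
    return year * 12 + (month - 1)


def age_in_months(birth_year: int, birth_month: int, date: dt.date) -> int:
    """Age at ``date`` rounded to whole months.

    The birth day is not modelled; a wave on or after the 16th of a month
    rounds up to the next whole month of age.
    """
    t = month_index(date.year, date.month) - month_index(birth_year, birth_month)
    return t + (1 if date.day >= 16 else 0)


@dataclass(slots=True)
class WaveObservation:
    """One survey wave for one individual.

    ``state`` is the derived 3-level code (-1 while underivable); the raw
    ingredients (physical-functioning score, needs-help flag) and any
    wave-level covariate reports used for backfilling ride along.
    """

    date: dt.date
    pf_score: float | None = None
    needs_help: bool | None = None
    state: int = UNKNOWN
    education: int | None = None
    obese: int | None = None
    smoker: int | None = None
    exercise: int | None = None
    bmi: float | None = None


@dataclass(slots=True)
class IndividualRecord:
    """One individual: identity, vital dates, baseline covariates, waves."""

    id: str
    birth_month: int
    birth_year: int
    death_month: int | None = None
    death_year: int | None = None
    education: int | None = None
    obese: int | None = None
    smoker: int | None = None
    exercise: int | None = None
    bmi: float | None = None
    waves: list[WaveObservation] = field(default_factory=list)

    @property
    def died(self) -> bool:
        return self.death_year is not None

    def covariate(self, name: str) -> int | None:
        if name not in COVARIATE_FIELDS:
            raise KeyError(name)
        return getattr(self, name)

    def death_age_months(self) -> int | None:
        """Age in whole months at the month of death (month precision)."""
        if not self.died:
            return None
        return (month_index(self.death_year, self.death_month)
                - month_index(self.birth_year, self.birth_month))

    def validate(self) -> None:
        if not 1 <= self.birth_month <= 12:
            raise ValueError(f"{self.id}: birth_month {self.birth_month}")
        if (self.death_month is None) != (self.death_year is None):
            raise ValueError(f"{self.id}: death month/year must come together")
        dates = [w.date for w in self.waves]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"{self.id}: wave dates must be strictly increasing")
        for w in self.waves:
            if w.state not in (UNKNOWN, STATE_FREE, STATE_DISABLED):
                raise ValueError(f"{self.id}: invalid wave state {w.state}")
            if w.pf_score is not None and not 0.0 <= w.pf_score <= 100.0:
                raise ValueError(f"{self.id}: pf_score outside [0, 100]")
        if self.died and dates:
            last = dates[-1]
            if (month_index(self.death_year, self.death_month)
                    < month_index(last.year, last.month)):
                raise ValueError(f"{self.id}: death precedes last wave month")


@dataclass
class PanelDataset:
    """A collection of individuals plus a provenance/exclusion log."""

    individuals: list[IndividualRecord] = field(default_factory=list)
    exclusion_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[IndividualRecord]:
        return iter(self.individuals)

    def validate(self) -> None:
        seen = set()
        for rec in self.individuals:
            if rec.id in seen:
                raise ValueError(f"duplicate individual id {rec.id!r}")
            seen.add(rec.id)
            rec.validate()

    def copy(self) -> "PanelDataset":
        return copy.deepcopy(self)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per wave (individuals without waves
        contribute a single row with missing wave fields)."""
        rows = []
        for rec in self.individuals:
            base = dict(
                id=rec.id, birth_month=rec.birth_month, birth_year=rec.birth_year,
                death_month=rec.death_month, death_year=rec.death_year,
                education=rec.education, obese=rec.obese, smoker=rec.smoker,
                exercise=rec.exercise, bmi=rec.bmi,
            )
            if not rec.waves:
                rows.append(dict(base, wave_date=None, pf_score=None,
                                 needs_help=None, state=None))
            for w in rec.waves:
                rows.append(dict(base, wave_date=w.date, pf_score=w.pf_score,
                                 needs_help=w.needs_help, state=w.state))
        return pd.DataFrame(rows)
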