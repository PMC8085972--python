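"""Nested case-control construction: eligibility, matching, quartiles.

Turns a benign-biopsy cohort into the analytic dataset: cases must be
diagnosed at least one year after cohort entry (a lag guarding against
cancer missed on the index biopsy); each case is matched to one control
by incidence-density sampling — a uniform draw, with replacement across
cases, from all cohort members still cancer-free at the case's
entry-to-diagnosis interval who agree on race and fall within +-2-year
calipers on age and calendar date of entry.  Marker expression is then
categorised by race-specific quartile cutpoints estimated from the
control arm only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_sim import CohortMember

__all__ = [
    "MatchCriteria",
    "MatchedPair",
    "UnmatchedCase",
    "QuartileCuts",
    "DegenerateCutsError",
    "eligible_cases",
    "incidence_density_match",
    "quartile_cuts",
    "assign_quartile",
]

_DAYS_PER_YEAR = 365.25


class DegenerateCutsError(ValueError):
    """All control values identical; quartile cutpoints undefined."""


@dataclass(frozen=True)
class MatchCriteria:
    """Matching calipers and the diagnosis lag rule.

    Defaults: +-2-year age and entry-date calipers, exact race match,
    and a 1-year minimum lag between entry and case diagnosis
    (diagnoses at exactly one year remain eligible).
    """

    age_caliper: float = 2.0
    entry_caliper: float = 2.0
    exact_race: bool = True
    min_lag: float = 1.0

    def __post_init__(self) -> None:
        if self.age_caliper < 0 or self.entry_caliper < 0 or self.min_lag < 0:
            raise ValueError("calipers and min_lag must be >= 0")


@dataclass(frozen=True)
class MatchedPair:
    """A case and its incidence-density-sampled control."""

    case: CohortMember
    control: CohortMember
    index_time: float  # case's entry-to-diagnosis interval, years

    @property
    def case_id(self) -> int:
        return self.case.id

    @property
    def control_id(self) -> int:
        return self.control.id


@dataclass(frozen=True)
class UnmatchedCase:
    case: CohortMember
    reason: str


def eligible_cases(
    cohort: list[CohortMember], criteria: MatchCriteria | None = None
) -> list[CohortMember]:
    """Cases diagnosed at least ``min_lag`` years after entry, no prior cancer."""
    criteria = criteria or MatchCriteria()
    return [
        m
        for m in cohort
        if m.is_case and not m.prior_cancer and m.event_time >= criteria.min_lag
    ]


def incidence_density_match(
    cases: list[CohortMember],
    cohort: list[CohortMember],
    criteria: MatchCriteria | None = None,
    seed: int = 0,
) -> tuple[list[MatchedPair], list[UnmatchedCase]]:
    """1:1 incidence-density sampling of controls, with replacement.

    For each case (processed in ascending diagnosis date, ties broken by
    id, so the output is invariant to cohort row order) the risk set
    contains every other member — later cases included — who is
    cancer-free at the case's index time (censored members need
    follow-up >= index time; case members must be diagnosed strictly
    after it), matches on race, and lies within the age and entry-date
    calipers.  One control is drawn uniformly; the same member may serve
    as control for several cases.  Cases with an empty risk set are
    returned unmatched.
    """
    criteria = criteria or MatchCriteria()
    rng = np.random.default_rng(seed)

    ids = np.array([m.id for m in cohort])
    age = np.array([m.age_at_entry for m in cohort])
    entry = np.array([m.entry_date.toordinal() for m in cohort], dtype=float)
    event_time = np.array([m.event_time for m in cohort])
    is_case = np.array([m.is_case for m in cohort])
    race = np.array([m.race for m in cohort])
    by_id = {m.id: m for m in cohort}

    def diagnosis_date(m: CohortMember) -> float:
        return m.entry_date.toordinal() + m.event_time * _DAYS_PER_YEAR

    pairs: list[MatchedPair] = []
    unmatched: list[UnmatchedCase] = []
    for case in sorted(cases, key=lambda m: (diagnosis_date(m), m.id)):
        t = case.event_time
        at_risk = np.where(is_case, event_time > t, event_time >= t)
        ok = (
            at_risk
            & (ids != case.id)
            & (np.abs(age - case.age_at_entry) <= criteria.age_caliper)
            & (
                np.abs(entry - case.entry_date.toordinal())
                <= criteria.entry_caliper * _DAYS_PER_YEAR
            )
        )
        if criteria.exact_race:
            ok &= race == case.race
        cand_ids = np.sort(ids[ok])  # id order, so the draw ignores row order
        if cand_ids.size == 0:
            unmatched.append(UnmatchedCase(case, "no_eligible_controls"))
            continue
        control = by_id[int(cand_ids[rng.integers(cand_ids.size)])]
        pairs.append(MatchedPair(case=case, control=control, index_time=t))
    return pairs, unmatched


@dataclass(frozen=True)
class QuartileCuts:
    """Race-specific quartile cutpoints estimated from controls."""

    race: str
    marker: str
    cut1: float
    cut2: float
    cut3: float

    def __post_init__(self) -> None:
        if not self.cut1 <= self.cut2 <= self.cut3:
            raise ValueError("quartile cuts must be nondecreasing")

    @property
    def cuts(self) -> np.ndarray:
        return np.array([self.cut1, self.cut2, self.cut3])


def quartile_cuts(values: np.ndarray, race: str, marker: str) -> QuartileCuts:
    """Empirical quartiles (linear interpolation between order statistics)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError(f"need >= 4 control values for {race}/{marker} quartiles")
    if np.ptp(values) == 0:
        raise DegenerateCutsError(f"all {race}/{marker} control values identical")
    c1, c2, c3 = np.quantile(values, [0.25, 0.50, 0.75], method="linear")
    return QuartileCuts(race, marker, float(c1), float(c2), float(c3))


def assign_quartile(value: float, cuts: QuartileCuts) -> int:
    """Quartile code 1-4 with right-closed boundaries.

    Intervals: (-inf, cut1], (cut1, cut2], (cut2, cut3], (cut3, inf).
    NaN (undefined expression) raises ValueError so callers can drop and
    log the subject.
    """
    if not np.isfinite(value):
        raise ValueError("cannot assign a quartile to an undefined expression")
    return int(np.searchsorted(cuts.cuts, value, side="left")) + 1
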