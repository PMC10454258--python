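"""Censored person-time and incidence rates per 100 person-years.

Follow-up runs from each cohort's index date to the earliest of
disenrollment, the administrative end of observation, and death; a death
after censoring contributes no event.  Person-years use days / 365.25
(configurable to 365.0).  Printed rates are rounded half-away-from-zero to
4 decimals; full precision is retained internally.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._util import DAYS_PER_YEAR, round_half_away
from .bundles import ClaimsBundle, claim_dates_matching
from .codesets import CodesetRegistry
from .linkage import LinkedDeath
from .phenotyping import CohortAssignment, StudyWindow, _sisa_match

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeAtRisk:
    patient_id: str
    cohort: str
    start: dt.date
    end: dt.date
    end_reason: str  # death | disenrollment | administrative
    days: int
    person_years: float


@dataclass(frozen=True)
class RateEstimate:
    cohort: str
    stratum_variable: str
    stratum_level: str
    events: int
    person_years: float
    rate_per_100: float  # nan when person-years are zero


def time_at_risk(assignment: CohortAssignment, bundle: ClaimsBundle,
                 linked_death: Optional[LinkedDeath], window: StudyWindow,
                 *, days_per_year: float = DAYS_PER_YEAR) -> list[TimeAtRisk]:
    """One record per cohort membership, each from that cohort's own index."""
    records = []
    for cohort, index in assignment.memberships():
        disenroll = bundle.disenrollment_after(index)
        if disenroll is None:
            log.warning("%s: index %s outside enrollment; zero days at risk",
                        bundle.patient_id, index)
            disenroll = index
        candidates = {
            "disenrollment": disenroll,
            "administrative": window.observation_end,
        }
        if linked_death is not None:
            candidates["death"] = linked_death.death_date
        end = min(candidates.values())
        # censoring applies only when it occurs strictly before death
        for reason in ("death", "disenrollment", "administrative"):
            if candidates.get(reason) == end:
                end_reason = reason
                break
        if end < index:
            end, end_reason = index, end_reason
        days = max((end - index).days, 0)
        records.append(TimeAtRisk(
            patient_id=bundle.patient_id, cohort=cohort, start=index, end=end,
            end_reason=end_reason, days=days, person_years=days / days_per_year,
        ))
    return records


def observation_anchor(bundle: ClaimsBundle, window: StudyWindow) -> dt.date:
    """Earliest of disenrollment, death, and the observation end — the end
    of this patient's observation, anchoring the last-year window."""
    candidates = [window.observation_end]
    if bundle.enrollment_end is not None:
        candidates.append(bundle.enrollment_end)
    if bundle.death is not None:
        candidates.append(bundle.death.death_date)
    return min(candidates)


def recent_sisa(bundle: ClaimsBundle, window_end: dt.date,
                registry: CodesetRegistry) -> bool:
    """True iff >=1 ideation/attempt claim (any position) falls in the
    inclusive 365-day window [window_end - 364 d, window_end]."""
    lo = window_end - dt.timedelta(days=364)
    return any(
        lo <= d <= window_end
        for d in claim_dates_matching(bundle, _sisa_match(registry))
    )


def incidence_rate(events: int, person_years: float) -> float:
    """events / person-years x 100; nan when person-years are zero."""
    if person_years <= 0:
        return math.nan
    return events / person_years * 100.0


def round_rate(rate: float, ndigits: int = 4) -> float:
    if math.isnan(rate):
        return rate
    return round_half_away(rate, ndigits)


def stratified_rates(tars: Sequence[TimeAtRisk],
                     linked_deaths: Mapping[str, LinkedDeath],
                     profiles: pd.DataFrame,
                     strata: Sequence[str] = ("age_group", "sex", "recent_sisa"),
                     *,
                     definition: str = "broad") -> pd.DataFrame:
    """Rate table: one row per cohort overall plus per stratum level.

    ``profiles`` needs columns patient_id, cohort, and one column per
    requested stratifier.  An event is a death ending follow-up that is
    classified as suicide under ``definition``.
    """
    allowed = {"age_group", "sex", "recent_sisa"}
    unknown = set(strata) - allowed
    if unknown:
        raise ValueError(f"unknown stratifiers: {sorted(unknown)}")

    rows = []
    for t in tars:
        death = linked_deaths.get(t.patient_id)
        event = int(
            t.end_reason == "death"
            and death is not None
            and death.suicide_by_definition.get(definition, False)
        )
        rows.append({"patient_id": t.patient_id, "cohort": t.cohort,
                     "person_years": t.person_years, "event": event})
    df = pd.DataFrame(rows, columns=["patient_id", "cohort", "person_years", "event"])
    if not df.empty and not profiles.empty:
        df = df.merge(profiles, on=["patient_id", "cohort"], how="left")
    else:
        for s in strata:
            df[s] = pd.Series(dtype=object)

    out = []
    for cohort, grp in df.groupby("cohort", sort=True):
        out.append(_rate_row(cohort, "overall", "overall", grp))
        for var in strata:
            if var not in grp.columns:
                continue
            for level, sub in grp.groupby(var, sort=True, dropna=False):
                out.append(_rate_row(cohort, var, str(level), sub))
    return pd.DataFrame(
        out, columns=["cohort", "stratum_variable", "stratum_level",
                      "events", "person_years", "rate_per_100"],
    )


def _rate_row(cohort, var, level, grp) -> dict:
    events = int(grp["event"].sum())
    py = float(grp["person_years"].sum())
    return {
        "cohort": cohort, "stratum_variable": var, "stratum_level": level,
        "events": events, "person_years": py,
        "rate_per_100": incidence_rate(events, py),
    }
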