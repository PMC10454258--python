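"""Cohort-identification algorithms.

Three cohorts are assigned from a patient's claims history:

* treatment-resistant (``trd``): after the date depression is established,
  fills of >=3 distinct antidepressant ingredients — or >=1 antidepressant
  plus >=1 atypical antipsychotic — within an inclusive 365-day window;
* ideation/attempt (``sisa``): a qualifying ideation or attempt claim after
  established depression, attributed to depression by a recent claim or a
  prior ER/inpatient encounter;
* depression alone (``mdd_alone``): in the diagnostic frame but qualifying
  for neither of the above.

The trd and sisa cohorts are not mutually exclusive; mdd_alone is disjoint
from both.  "6 months" is operationalized as 183 days throughout.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bundles import ClaimsBundle, claim_dates_matching, claims_matching
from .codesets import CodesetRegistry, code_matches
from .errors import ValidationError

log = logging.getLogger(__name__)

SIX_MONTHS_DAYS = 183


@dataclass(frozen=True)
class StudyWindow:
    """Calendar structure of a study run."""

    identification_start: dt.date
    identification_end: dt.date
    observation_end: dt.date
    baseline_days: int = SIX_MONTHS_DAYS
    lookback_window_days: int = 365
    baseline_gap_tolerance_days: int = 0
    trd_index_mode: str = "first"  # first | last completing fill
    trd_fills_after_established: bool = True
    bipolar_lookback_days: Optional[int] = None  # None = any observed time

    def __post_init__(self) -> None:
        if not self.identification_start < self.identification_end <= self.observation_end:
            raise ValidationError(
                "need identification_start < identification_end <= observation_end"
            )
        if self.baseline_days <= 0:
            raise ValidationError("baseline_days must be positive")
        if self.trd_index_mode not in ("first", "last"):
            raise ValidationError(f"unknown trd_index_mode {self.trd_index_mode!r}")


@dataclass
class CohortAssignment:
    patient_id: str
    in_trd: bool = False
    trd_index: Optional[dt.date] = None
    in_sisa: bool = False
    sisa_index: Optional[dt.date] = None
    in_mdd_alone: bool = False
    mdd_alone_index: Optional[dt.date] = None
    established_mdd_date: Optional[dt.date] = None
    exclusion_reasons: list[str] = field(default_factory=list)

    def memberships(self):
        """(cohort, index) pairs for every cohort this patient belongs to."""
        out = []
        if self.in_trd:
            out.append(("trd", self.trd_index))
        if self.in_sisa:
            out.append(("sisa", self.sisa_index))
        if self.in_mdd_alone:
            out.append(("mdd_alone", self.mdd_alone_index))
        return out


def _mdd_match(registry: CodesetRegistry):
    mdd = registry.diagnosis["mdd"]
    return lambda code: code_matches(code, mdd)


def _sisa_match(registry: CodesetRegistry):
    si = registry.diagnosis["si"]
    sa = registry.diagnosis["sa"]
    intent = registry.sa_intentional_only
    return lambda code: code_matches(code, si) or code_matches(
        code, sa, intentional_only=intent
    )


def established_mdd_date(bundle: ClaimsBundle, window: StudyWindow,
                         registry: CodesetRegistry) -> Optional[dt.date]:
    """Date depression is established: the earlier of (a) the second claim
    date of the earliest pair of distinct-date diagnosis claims <=365 days
    apart, and (b) the discharge date of the earliest qualifying inpatient
    stay.  None if neither pattern exists."""
    match = _mdd_match(registry)
    dates = claim_dates_matching(bundle, match)
    candidates: list[dt.date] = []
    for prev, cur in zip(dates, dates[1:]):
        if (cur - prev).days <= window.lookback_window_days:
            candidates.append(cur)
            break  # consecutive gaps are minimal, so the first hit is earliest
    discharges = [
        c.discharge_date or c.service_date
        for c in claims_matching(bundle, match)
        if c.setting == "inpatient"
    ]
    if discharges:
        candidates.append(min(discharges))
    return min(candidates) if candidates else None


def _classed_fills(bundle: ClaimsBundle, registry: CodesetRegistry):
    """(date, ingredient, class) for antidepressant / atypical fills;
    unknown ingredients are skipped with a warning."""
    out = []
    for f in bundle.pharmacy_fills:
        cls = registry.drug_class(f.ingredient)
        if cls is None:
            log.warning("%s: unknown ingredient %r ignored", bundle.patient_id, f.ingredient)
            continue
        if cls in ("antidepressant", "atypical_antipsychotic"):
            out.append((f.fill_date, f.ingredient.lower(), cls))
    return out


def _window_qualifies(fills_in_window) -> bool:
    ads = {ing for _, ing, cls in fills_in_window if cls == "antidepressant"}
    aaps = {ing for _, ing, cls in fills_in_window if cls == "atypical_antipsychotic"}
    return len(ads) >= 3 or (len(ads) >= 1 and len(aaps) >= 1)


def trd_index(bundle: ClaimsBundle, window: StudyWindow, registry: CodesetRegistry
              ) -> tuple[Optional[dt.date], list]:
    """Treatment-resistance index date plus the qualifying fills.

    Scans fills chronologically; at each fill inside the identification
    period, checks whether the trailing inclusive 365-day window contains a
    qualifying ingredient set.  ``trd_index_mode="first"`` (default) returns
    the fill completing the first qualifying set; ``"last"`` returns the
    last completing fill inside the identification period.
    """
    est = established_mdd_date(bundle, window, registry)
    if est is None:
        return None, []
    fills = _classed_fills(bundle, registry)
    if window.trd_fills_after_established:
        fills = [f for f in fills if f[0] >= est]
    fills.sort()
    hits = []
    for date, ing, cls in fills:
        if not (window.identification_start <= date <= window.identification_end):
            continue
        lo = date - dt.timedelta(days=window.lookback_window_days)
        in_win = [f for f in fills if lo <= f[0] <= date]
        if _window_qualifies(in_win):
            hits.append((date, in_win))
            if window.trd_index_mode == "first":
                break
    if not hits:
        return None, []
    date, in_win = hits[0] if window.trd_index_mode == "first" else hits[-1]
    return date, in_win


def sisa_index(bundle: ClaimsBundle, window: StudyWindow,
               registry: CodesetRegistry) -> Optional[dt.date]:
    """Earliest ideation/attempt claim date on/after established depression,
    inside the identification period, and attributed to depression (a
    diagnosis claim within the prior 365 days, or any prior ER encounter or
    inpatient stay for depression)."""
    est = established_mdd_date(bundle, window, registry)
    if est is None:
        return None
    mdd = _mdd_match(registry)
    mdd_dates = claim_dates_matching(bundle, mdd)
    mdd_acute = [
        c for c in claims_matching(bundle, mdd) if c.setting in ("ER", "inpatient")
    ]
    for day in claim_dates_matching(bundle, _sisa_match(registry)):
        if day < est:
            continue
        if not (window.identification_start <= day <= window.identification_end):
            continue
        recent_mdd = any(
            0 <= (day - d).days <= window.lookback_window_days for d in mdd_dates
        )
        acute_prior = any(c.service_date <= day for c in mdd_acute)
        if recent_mdd or acute_prior:
            return day
    return None


def apply_exclusions(bundle: ClaimsBundle, candidate_cohort: str,
                     index_date: dt.date, registry: CodesetRegistry,
                     window: StudyWindow) -> list[str]:
    """Exclusion reasons for a candidate at its index date.

    Bipolar/mania excludes from every cohort (any observed claim up to the
    index, unless a lookback is configured).  Dementia and psychosis in the
    183 days before the index (exclusive of the index) exclude trd and sisa
    candidates; autism in the same window excludes sisa candidates only.
    """
    reasons: list[str] = []
    bip = registry.diagnosis["bipolar_mania"]
    lo_bip: Optional[dt.date] = None
    if window.bipolar_lookback_days is not None:
        lo_bip = index_date - dt.timedelta(days=window.bipolar_lookback_days)
    for c in bundle.medical_claims:
        if c.service_date > index_date:
            continue
        if lo_bip is not None and c.service_date < lo_bip:
            continue
        if any(code_matches(code, bip) for code in c.codes):
            reasons.append("bipolar_mania")
            break

    if candidate_cohort in ("trd", "sisa"):
        lo = index_date - dt.timedelta(days=window.baseline_days)
        hi = index_date - dt.timedelta(days=1)
        sets = ["dementia", "psychosis"]
        if candidate_cohort == "sisa":
            sets.append("autism")
        for name in sets:
            cs = registry.diagnosis[name]
            hit = any(
                lo <= c.service_date <= hi and any(code_matches(code, cs) for code in c.codes)
                for c in bundle.medical_claims
            )
            if hit:
                reasons.append(f"{name}_6mo")
    return reasons


def baseline_eligible(bundle: ClaimsBundle, index_date: dt.date,
                      window: StudyWindow) -> bool:
    """True iff [index-183 d, index-1 d] is covered by enrollment, up to the
    configured gap tolerance (total uncovered days)."""
    lo = index_date - dt.timedelta(days=window.baseline_days)
    hi = index_date - dt.timedelta(days=1)
    uncovered = (hi - lo).days + 1
    for start, end in bundle.enrollment_spans:
        s, e = max(start, lo), min(end, hi)
        if s <= e:
            uncovered -= (e - s).days + 1
    return uncovered <= window.baseline_gap_tolerance_days


def _frame_entry(bundle: ClaimsBundle, window: StudyWindow,
                 registry: CodesetRegistry) -> Optional[dt.date]:
    """Second distinct diagnosis-claim date inside the identification
    period, or None if the patient never enters the frame."""
    dates = [
        d for d in claim_dates_matching(bundle, _mdd_match(registry))
        if window.identification_start <= d <= window.identification_end
    ]
    return dates[1] if len(dates) >= 2 else None


def assign_cohorts(population: Sequence[ClaimsBundle], window: StudyWindow,
                   registry: CodesetRegistry
                   ) -> tuple[list[CohortAssignment], list[dict]]:
    """Assign every patient to cohorts and log stepwise attrition.

    Returns (assignments, attrition rows).  Attrition rows have keys
    ``cohort, step, n_removed, n_remaining`` and satisfy, per cohort,
    entrants - sum(removals) = final count.
    """
    assignments: list[CohortAssignment] = []
    tally = {
        c: {"candidates": 0, "excluded": {}, "no_baseline": 0, "final": 0}
        for c in ("trd", "sisa", "mdd_alone")
    }
    n_frame = 0

    for bundle in population:
        a = CohortAssignment(patient_id=bundle.patient_id)
        frame_date = _frame_entry(bundle, window, registry)
        if frame_date is None:
            assignments.append(a)
            continue
        n_frame += 1
        a.established_mdd_date = established_mdd_date(bundle, window, registry)

        t_idx, _audit = trd_index(bundle, window, registry)
        if t_idx is not None:
            _evaluate(bundle, "trd", t_idx, window, registry, tally, a)
            if not a.in_trd:
                t_idx = None
            else:
                a.trd_index = t_idx

        s_idx = sisa_index(bundle, window, registry)
        if s_idx is not None:
            _evaluate(bundle, "sisa", s_idx, window, registry, tally, a)
            if not a.in_sisa:
                s_idx = None
            else:
                a.sisa_index = s_idx

        if not a.in_trd and not a.in_sisa:
            _evaluate(bundle, "mdd_alone", frame_date, window, registry, tally, a)
            if a.in_mdd_alone:
                a.mdd_alone_index = frame_date
        assignments.append(a)

    attrition = [
        {"cohort": "frame", "step": "population", "n_removed": 0,
         "n_remaining": len(population)},
        {"cohort": "frame", "step": "two_mdd_claims_in_identification_period",
         "n_removed": len(population) - n_frame, "n_remaining": n_frame},
    ]
    for cohort in ("trd", "sisa", "mdd_alone"):
        t = tally[cohort]
        remaining = t["candidates"]
        attrition.append({"cohort": cohort, "step": "candidates_with_index",
                          "n_removed": n_frame - remaining, "n_remaining": remaining})
        for reason in sorted(t["excluded"]):
            removed = t["excluded"][reason]
            remaining -= removed
            attrition.append({"cohort": cohort, "step": f"excluded_{reason}",
                              "n_removed": removed, "n_remaining": remaining})
        remaining -= t["no_baseline"]
        attrition.append({"cohort": cohort, "step": "insufficient_baseline_history",
                          "n_removed": t["no_baseline"], "n_remaining": remaining})
        assert remaining == t["final"]
        attrition.append({"cohort": cohort, "step": "final",
                          "n_removed": 0, "n_remaining": t["final"]})
    return assignments, attrition


def _evaluate(bundle, cohort, index_date, window, registry, tally, assignment):
    """Run the exclusion + baseline gate for one candidate and update both
    the attrition tally and the assignment flags."""
    t = tally[cohort]
    t["candidates"] += 1
    reasons = apply_exclusions(bundle, cohort, index_date, registry, window)
    if reasons:
        key = reasons[0]  # attrition counts each patient once, first reason
        t["excluded"][key] = t["excluded"].get(key, 0) + 1
        assignment.exclusion_reasons.extend(f"{cohort}:{r}" for r in reasons)
        return
    if not baseline_eligible(bundle, index_date, window):
        t["no_baseline"] += 1
        assignment.exclusion_reasons.append(f"{cohort}:insufficient_baseline")
        return
    t["final"] += 1
    if cohort == "trd":
        assignment.in_trd = True
    elif cohort == "sisa":
        assignment.in_sisa = True
    else:
        assignment.in_mdd_alone = True
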