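"""Per-patient claims containers shared by the generator and the analysis
stages: enrollment spans, medical claims, pharmacy fills, optional death."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import ValidationError


@dataclass(frozen=True)
class MedicalClaim:
    """One medical claim; ``codes`` are in claim-position order."""

    service_date: dt.date
    codes: tuple[str, ...]
    setting: str = "outpatient"  # inpatient | ER | outpatient
    discharge_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.setting not in ("inpatient", "ER", "outpatient"):
            raise ValidationError(f"unknown claim setting {self.setting!r}")
        if self.setting == "inpatient" and self.discharge_date is None:
            object.__setattr__(self, "discharge_date", self.service_date)


@dataclass(frozen=True)
class PharmacyFill:
    fill_date: dt.date
    ingredient: str


@dataclass(frozen=True)
class DeathRecord:
    death_date: dt.date
    cause_codes: tuple[str, ...]


@dataclass
class ClaimsBundle:
    """One patient's complete claims history — the unit of phenotyping.

    ``planted_truth`` carries generator labels for testing only and is never
    consulted by any analysis stage.
    """

    patient_id: str
    birth_year: int
    sex: str  # F | M
    enrollment_spans: list[tuple[dt.date, dt.date]] = field(default_factory=list)
    medical_claims: list[MedicalClaim] = field(default_factory=list)
    pharmacy_fills: list[PharmacyFill] = field(default_factory=list)
    death: Optional[DeathRecord] = None
    planted_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.enrollment_spans.sort()
        self.medical_claims.sort(key=lambda c: (c.service_date, c.codes))
        self.pharmacy_fills.sort(key=lambda f: (f.fill_date, f.ingredient))
        self.validate()

    def validate(self) -> None:
        if self.sex not in ("F", "M", "U"):
            raise ValidationError(f"{self.patient_id}: unknown sex {self.sex!r}")
        prev_end: Optional[dt.date] = None
        for start, end in self.enrollment_spans:
            if start > end:
                raise ValidationError(f"{self.patient_id}: span {start}..{end} reversed")
            if prev_end is not None and start <= prev_end:
                raise ValidationError(f"{self.patient_id}: overlapping enrollment spans")
            prev_end = end
        for claim in self.medical_claims:
            if not self.enrolled_on(claim.service_date):
                raise ValidationError(
                    f"{self.patient_id}: claim on {claim.service_date} outside enrollment"
                )
        for fill in self.pharmacy_fills:
            if not self.enrolled_on(fill.fill_date):
                raise ValidationError(
                    f"{self.patient_id}: fill on {fill.fill_date} outside enrollment"
                )

    def enrolled_on(self, day: dt.date) -> bool:
        return any(start <= day <= end for start, end in self.enrollment_spans)

    @property
    def enrollment_end(self) -> Optional[dt.date]:
        return self.enrollment_spans[-1][1] if self.enrollment_spans else None

    def disenrollment_after(self, day: dt.date) -> Optional[dt.date]:
        """End of the enrollment span containing ``day`` (follow-up stops at
        the first disenrollment)."""
        for start, end in self.enrollment_spans:
            if start <= day <= end:
                return end
        return None

    def without_truth(self) -> "ClaimsBundle":
        return replace(self, planted_truth=None)


def claim_dates_matching(bundle: ClaimsBundle, match) -> list[dt.date]:
    """Distinct, sorted service dates of claims with >=1 code accepted by
    ``match`` (a predicate on a code string), any claim position."""
    dates = {
        c.service_date
        for c in bundle.medical_claims
        if any(match(code) for code in c.codes)
    }
    return sorted(dates)


def claims_matching(bundle: ClaimsBundle, match) -> list[MedicalClaim]:
    return [c for c in bundle.medical_claims if any(match(code) for code in c.codes)]


def sorted_population(population: Sequence[ClaimsBundle]) -> list[ClaimsBundle]:
    return sorted(population, key=lambda b: b.patient_id)
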