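"""Table-1-style baseline / last-year indicator variables and summaries."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .bundles import ClaimsBundle
from .codesets import CodesetRegistry, DiagnosisCodeSet, code_matches
from .phenotyping import SIX_MONTHS_DAYS, _sisa_match

AGE_GROUPS = ("18-44", "45-64", "65+")


def age_group_of(age_years: int) -> str:
    if age_years <= 44:
        return "18-44"
    if age_years <= 64:
        return "45-64"
    return "65+"


@dataclass(frozen=True)
class CharacterizationWindow:
    """baseline = [index-183 d, index-1 d]; last_year = [anchor-364 d, anchor]."""

    kind: str  # baseline | last_year
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} after end {self.end}")

    @classmethod
    def baseline(cls, index_date: dt.date,
                 baseline_days: int = SIX_MONTHS_DAYS) -> "CharacterizationWindow":
        return cls("baseline", index_date - dt.timedelta(days=baseline_days),
                   index_date - dt.timedelta(days=1))

    @classmethod
    def last_year(cls, anchor: dt.date) -> "CharacterizationWindow":
        return cls("last_year", anchor - dt.timedelta(days=364), anchor)

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass
class PatientProfile:
    patient_id: str
    cohort: str
    age_years: int
    age_group: str
    sex: str
    condition_flags: dict = field(default_factory=dict)
    medication_flags: dict = field(default_factory=dict)
    si_flag: bool = False
    sa_flag: bool = False


def characterize(bundle: ClaimsBundle, cohort: str, index_date: dt.date,
                 windows: Sequence[CharacterizationWindow],
                 registry: CodesetRegistry,
                 category_map: Optional[Mapping[str, DiagnosisCodeSet]] = None,
                 ) -> dict[str, PatientProfile]:
    """One profile per window kind; flags are any-claim-position indicators."""
    if category_map is None:
        category_map = registry.condition_categories
    age = index_date.year - bundle.birth_year
    si_set = registry.diagnosis["si"]
    sa_set = registry.diagnosis["sa"]

    out: dict[str, PatientProfile] = {}
    for window in windows:
        profile = PatientProfile(
            patient_id=bundle.patient_id, cohort=cohort,
            age_years=age, age_group=age_group_of(age), sex=bundle.sex,
        )
        in_window = [c for c in bundle.medical_claims if window.contains(c.service_date)]
        for name, codeset in category_map.items():
            profile.condition_flags[name] = any(
                code_matches(code, codeset) for c in in_window for code in c.codes
            )
        fills = [f for f in bundle.pharmacy_fills if window.contains(f.fill_date)]
        classes = {registry.drug_class(f.ingredient) for f in fills}
        classes.discard(None)
        for cls in ("antidepressant", "atypical_antipsychotic", "antipsychotic_other",
                    "anxiolytic", "benzodiazepine"):
            profile.medication_flags[cls] = cls in classes
        profile.si_flag = any(
            code_matches(code, si_set) for c in in_window for code in c.codes
        )
        profile.sa_flag = any(
            code_matches(code, sa_set, intentional_only=registry.sa_intentional_only)
            for c in in_window for code in c.codes
        )
        out[window.kind] = profile
    return out


def summarize_cohort(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """Summary rows (variable, level, n, value) for one cohort x window.

    Percentages are over cohort n and printed to 2 decimals (half away from
    zero); age is summarized by mean/SD/median/IQR.
    """
    n = len(profiles)
    rows = [{"variable": "n", "level": "", "n": n, "value": n}]
    if n == 0:
        return pd.DataFrame(rows, columns=["variable", "level", "n", "value"])

    ages = np.array([p.age_years for p in profiles], dtype=float)
    q1, med, q3 = np.percentile(ages, [25, 50, 75])
    rows += [
        {"variable": "age_mean", "level": "", "n": n, "value": round_half_away(ages.mean(), 2)},
        {"variable": "age_sd", "level": "", "n": n,
         "value": round_half_away(float(ages.std(ddof=1)) if n > 1 else 0.0, 2)},
        {"variable": "age_median", "level": "", "n": n, "value": round_half_away(med, 2)},
        {"variable": "age_q1", "level": "", "n": n, "value": round_half_away(q1, 2)},
        {"variable": "age_q3", "level": "", "n": n, "value": round_half_away(q3, 2)},
    ]

    def pct(count: int) -> float:
        return round_half_away(100.0 * count / n, 2)

    for group in AGE_GROUPS:
        count = sum(p.age_group == group for p in profiles)
        rows.append({"variable": "age_group", "level": group, "n": count, "value": pct(count)})
    for sex in ("F", "M"):
        count = sum(p.sex == sex for p in profiles)
        rows.append({"variable": "sex", "level": sex, "n": count, "value": pct(count)})
    for name in profiles[0].condition_flags:
        count = sum(p.condition_flags.get(name, False) for p in profiles)
        rows.append({"variable": "condition", "level": name, "n": count, "value": pct(count)})
    for cls in profiles[0].medication_flags:
        count = sum(p.medication_flags.get(cls, False) for p in profiles)
        rows.append({"variable": "medication", "level": cls, "n": count, "value": pct(count)})
    for flag in ("si_flag", "sa_flag"):
        count = sum(getattr(p, flag) for p in profiles)
        rows.append({"variable": flag, "level": "", "n": count, "value": pct(count)})
    return pd.DataFrame(rows, columns=["variable", "level", "n", "value"])
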