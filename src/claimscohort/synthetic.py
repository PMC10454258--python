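"""Seeded synthetic administrative-claims generator.

Produces populations of :class:`~claimscohort.bundles.ClaimsBundle` with
planted cohort structure (treatment-resistant, ideation/attempt, depression
alone, or none) and per-cohort suicide hazards, so every downstream stage is
testable without access to proprietary claims or death-index data.

Event model: exponential time-to-suicide from the planted index date,
competing with exponential other-cause death and disenrollment; the earliest
event wins, with administrative censoring at the observation end.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from ._util import DAYS_PER_YEAR
from .bundles import ClaimsBundle, DeathRecord, MedicalClaim, PharmacyFill
from .errors import ConfigurationError

PLANTED_COHORTS = ("planted_TRD", "planted_SISA", "planted_MDD_alone", "planted_non_MDD")
AGE_BANDS = {"18-44": (18, 44), "45-64": (45, 64), "65+": (65, 89)}

_MDD_CODES = ("F32.9", "F33.0", "F33.1", "F33.2", "F32.1")
_SI_CODE = "R45.851"
_SA_CODES = ("T39.1X2A", "T42.4X2A", "T50.902A", "T71.9XXA")
_NOISE_CODES = ("I10", "E11.9", "J06.9", "M54.5", "K21.9")
_OTHER_DEATH_CODES = ("I21.9", "C34.90", "J44.1")
_AD_POOL = (
    "sertraline", "fluoxetine", "citalopram", "escitalopram", "paroxetine",
    "venlafaxine", "duloxetine", "bupropion", "mirtazapine", "trazodone",
)
_AAP_POOL = ("quetiapine", "aripiprazole", "olanzapine", "risperidone")

#: Default cause-of-death sampling weights by group: 70% intentional
#: self-harm, 15% accidental poisoning, 10% undetermined, 5% sequelae.
DEFAULT_CAUSE_WEIGHTS = {
    "intentional_self_harm": 0.55,
    "intentional_self_poisoning": 0.15,
    "accidental_poisoning": 0.15,
    "undetermined_poisoning": 0.05,
    "undetermined_accident": 0.05,
    "sequelae_self_harm": 0.02,
    "sequelae_undetermined": 0.02,
    "sequelae_unspecified": 0.01,
}

_GROUP_CODES = {
    "accidental_poisoning": ("X42", "X44"),
    "intentional_self_poisoning": ("X62", "X64"),
    "intentional_self_harm": ("X70", "X74", "X80"),
    "undetermined_poisoning": ("Y12", "Y14"),
    "undetermined_accident": ("Y21", "Y30"),
    "sequelae_self_harm": ("Y87.0",),
    "sequelae_undetermined": ("Y87.2",),
    "sequelae_unspecified": ("Y89.9",),
}

_EXCLUSION_CODES = {
    "bipolar_mania": "F31.9",
    "dementia": "F03.90",
    "psychosis": "F29",
    "autism": "F84.0",
}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic population draw."""

    n_patients: int = 1000
    identification_start: dt.date = dt.date(2016, 1, 1)
    identification_end: dt.date = dt.date(2019, 6, 30)
    observation_end: dt.date = dt.date(2019, 9, 30)
    cohort_mix: dict = field(
        default_factory=lambda: {
            "planted_TRD": 0.25,
            "planted_SISA": 0.15,
            "planted_MDD_alone": 0.45,
            "planted_non_MDD": 0.15,
        }
    )
    age_mix: dict = field(
        default_factory=lambda: {"18-44": 0.25, "45-64": 0.35, "65+": 0.40}
    )
    female_fraction: float = 0.67
    suicide_hazard_per_100py: dict = field(
        default_factory=lambda: {
            "planted_TRD": 0.14,
            "planted_SISA": 0.27,
            "planted_MDD_alone": 0.04,
            "planted_non_MDD": 0.0,
        }
    )
    other_death_hazard_per_100py: float = 1.0
    disenrollment_hazard_per_100py: float = 15.0
    enrollment_gap_prob: float = 0.0
    exclusion_prob: float = 0.0
    sa_before_death_prob: float = 0.6
    noise_claims_mean: float = 1.0
    cause_weights: dict = field(default_factory=lambda: dict(DEFAULT_CAUSE_WEIGHTS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not self.identification_start < self.identification_end <= self.observation_end:
            raise ConfigurationError(
                "need identification_start < identification_end <= observation_end"
            )
        for name, mix in (("cohort_mix", self.cohort_mix), ("age_mix", self.age_mix)):
            vals = list(mix.values())
            if any(v < 0 or v > 1 for v in vals):
                raise ConfigurationError(f"{name} proportions must lie in [0, 1]")
            total = sum(vals)
            if total <= 0:
                raise ConfigurationError(f"{name} sums to zero — impossible mix")
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {total})")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigurationError("female_fraction must lie in [0, 1]")
        for c, h in self.suicide_hazard_per_100py.items():
            if h < 0:
                raise ConfigurationError(f"suicide hazard for {c} is negative")
        if self.other_death_hazard_per_100py < 0 or self.disenrollment_hazard_per_100py < 0:
            raise ConfigurationError("hazards must be >= 0")


def _exp_days(rng: np.random.Generator, hazard_per_100py: float) -> float:
    """Exponential waiting time in days for a hazard per 100 person-years."""
    if hazard_per_100py <= 0:
        return math.inf
    rate_per_day = hazard_per_100py / 100.0 / DAYS_PER_YEAR
    return rng.exponential(1.0 / rate_per_day)


def _uniform_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    return lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def generate_population(spec: SimulationSpec) -> list[ClaimsBundle]:
    """Draw a population of claims bundles; deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cohort_names = list(spec.cohort_mix)
    cohort_p = np.asarray([spec.cohort_mix[c] for c in cohort_names], dtype=float)
    cohort_p = cohort_p / cohort_p.sum()
    band_names = list(spec.age_mix)
    band_p = np.asarray([spec.age_mix[b] for b in band_names], dtype=float)
    band_p = band_p / band_p.sum()
    group_names = list(spec.cause_weights)
    group_p = np.asarray([spec.cause_weights[g] for g in group_names], dtype=float)
    group_p = group_p / group_p.sum()

    width = max(6, len(str(max(spec.n_patients, 1))))
    population = []
    for i in range(spec.n_patients):
        pid = f"P{i:0{width}d}"
        cohort = cohort_names[int(rng.choice(len(cohort_names), p=cohort_p))]
        band = band_names[int(rng.choice(len(band_names), p=band_p))]
        population.append(_generate_patient(pid, cohort, band, spec, rng,
                                            group_names, group_p))
    return population


def _generate_patient(pid, cohort, band, spec, rng, group_names, group_p) -> ClaimsBundle:
    sex = "F" if rng.random() < spec.female_fraction else "M"
    lo, hi = AGE_BANDS[band]
    age = int(rng.integers(lo, hi + 1))

    # index anchor leaves room inside the identification period for the
    # prior MDD claims that establish the diagnosis
    lead = dt.timedelta(days=150)
    index = _uniform_date(rng, spec.identification_start + lead, spec.identification_end)
    birth_year = index.year - age
    enroll_start = index - dt.timedelta(days=int(rng.integers(400, 900)))

    claims: list[MedicalClaim] = []
    fills: list[PharmacyFill] = []

    def mdd_claim(day, setting="outpatient"):
        code = _MDD_CODES[int(rng.integers(0, len(_MDD_CODES)))]
        claims.append(MedicalClaim(service_date=day, codes=(code,), setting=setting))

    if cohort == "planted_TRD":
        mdd_claim(index - dt.timedelta(days=120))
        mdd_claim(index - dt.timedelta(days=90))
        if rng.random() < 0.7:
            ads = rng.choice(len(_AD_POOL), size=3, replace=False)
            offsets = (60, 30, 0)
            for k, off in zip(ads, offsets):
                fills.append(PharmacyFill(index - dt.timedelta(days=off), _AD_POOL[int(k)]))
        else:
            fills.append(PharmacyFill(index - dt.timedelta(days=45),
                                      _AD_POOL[int(rng.integers(0, len(_AD_POOL)))]))
            fills.append(PharmacyFill(index,
                                      _AAP_POOL[int(rng.integers(0, len(_AAP_POOL)))]))
    elif cohort == "planted_SISA":
        mdd_claim(index - dt.timedelta(days=120))
        mdd_claim(index - dt.timedelta(days=90))
        code = _SI_CODE if rng.random() < 0.5 else _SA_CODES[int(rng.integers(0, len(_SA_CODES)))]
        setting = "ER" if rng.random() < 0.4 else "outpatient"
        claims.append(MedicalClaim(service_date=index, codes=(code,), setting=setting))
    elif cohort == "planted_MDD_alone":
        gap = int(rng.integers(30, 200))
        first = max(index - dt.timedelta(days=gap), spec.identification_start)
        mdd_claim(first)
        mdd_claim(index)
        if rng.random() < 0.5:  # some treatment, never enough to qualify
            fills.append(PharmacyFill(index - dt.timedelta(days=10),
                                      _AD_POOL[int(rng.integers(0, len(_AD_POOL)))]))
    else:  # planted_non_MDD
        if rng.random() < 0.3:
            mdd_claim(index)  # a single claim never enters the frame

    if cohort != "planted_non_MDD" and rng.random() < spec.exclusion_prob:
        reason = ("bipolar_mania", "dementia", "psychosis", "autism")[
            int(rng.choice(4, p=[0.4, 0.3, 0.2, 0.1]))
        ]
        if reason == "bipolar_mania":
            day = index - dt.timedelta(days=300)
        else:
            day = index - dt.timedelta(days=int(rng.integers(30, 181)))
        claims.append(MedicalClaim(service_date=day, codes=(_EXCLUSION_CODES[reason],)))

    for _ in range(int(rng.poisson(spec.noise_claims_mean))):
        day = index - dt.timedelta(days=int(rng.integers(0, 181)))
        code = _NOISE_CODES[int(rng.integers(0, len(_NOISE_CODES)))]
        claims.append(MedicalClaim(service_date=day, codes=(code,)))

    # competing exponential event times, in days from index
    t_suicide = _exp_days(rng, spec.suicide_hazard_per_100py.get(cohort, 0.0))
    t_other = _exp_days(rng, spec.other_death_hazard_per_100py)
    t_disenroll = _exp_days(rng, spec.disenrollment_hazard_per_100py)
    t_admin = (spec.observation_end - index).days

    death = None
    event = "censored"
    if min(t_suicide, t_other, t_disenroll) > t_admin:
        # administratively censored; usually remains enrolled past the end of
        # observation, emulating the death-index search restriction
        if rng.random() < 0.7:
            span_end = spec.observation_end + dt.timedelta(days=int(rng.integers(30, 400)))
        else:
            span_end = spec.observation_end
    elif t_disenroll <= min(t_suicide, t_other):
        event = "disenrolled"
        span_end = index + dt.timedelta(days=int(math.ceil(t_disenroll)))
        if t_suicide <= t_admin:
            # death after disenrollment: linked, but contributes no event
            day = index + dt.timedelta(days=int(math.ceil(t_suicide)))
            death = DeathRecord(day, _suicide_causes(rng, group_names, group_p))
            event = "disenrolled_then_suicide"
    elif t_suicide <= t_other:
        event = "suicide"
        day = index + dt.timedelta(days=int(math.ceil(t_suicide)))
        span_end = day
        death = DeathRecord(day, _suicide_causes(rng, group_names, group_p))
        if cohort == "planted_SISA" and rng.random() < spec.sa_before_death_prob:
            sa_day = day - dt.timedelta(days=int(rng.integers(30, 200)))
            sa_day = max(sa_day, index)
            code = _SA_CODES[int(rng.integers(0, len(_SA_CODES)))]
            claims.append(MedicalClaim(service_date=sa_day, codes=(code,), setting="ER"))
    else:
        event = "other_death"
        day = index + dt.timedelta(days=int(math.ceil(t_other)))
        span_end = day
        death = DeathRecord(
            day, (_OTHER_DEATH_CODES[int(rng.integers(0, len(_OTHER_DEATH_CODES)))],)
        )

    spans = [(enroll_start, span_end)]
    if rng.random() < spec.enrollment_gap_prob:
        gap_region_end = index - dt.timedelta(days=430)
        if enroll_start + dt.timedelta(days=10) < gap_region_end:
            g0 = _uniform_date(rng, enroll_start + dt.timedelta(days=10), gap_region_end)
            g1 = g0 + dt.timedelta(days=int(rng.integers(10, 61)))
            spans = [(enroll_start, g0 - dt.timedelta(days=1)),
                     (g1 + dt.timedelta(days=1), span_end)]

    return ClaimsBundle(
        patient_id=pid,
        birth_year=birth_year,
        sex=sex,
        enrollment_spans=spans,
        medical_claims=claims,
        pharmacy_fills=fills,
        death=death,
        planted_truth={
            "planted_cohort": cohort,
            "planted_event": event,
            "planted_index": index.isoformat(),
        },
    )


def _suicide_causes(rng, group_names, group_p) -> tuple[str, ...]:
    group = group_names[int(rng.choice(len(group_names), p=group_p))]
    codes = _GROUP_CODES[group]
    cause = codes[int(rng.integers(0, len(codes)))]
    if rng.random() < 0.3:  # exercise multiple-cause matching
        return ("J96.0", cause)
    return (cause,)


def write_tables(population, directory) -> dict:
    """Write the population as delimited tables; see :mod:`claimscohort.io`."""
    from .io import write_tables as _write

    return _write(population, directory)
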