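import datetime as dt

import pytest

from claimscohort.bundles import ClaimsBundle, DeathRecord, MedicalClaim, PharmacyFill
from claimscohort.codesets import load_codesets
from claimscohort.phenotyping import StudyWindow

D = dt.date


@pytest.fixture(scope="session")
def registry():
    return load_codesets()


@pytest.fixture(scope="session")
def window():
    return StudyWindow(
        identification_start=D(2016, 1, 1),
        identification_end=D(2019, 6, 30),
        observation_end=D(2019, 9, 30),
    )


def make_bundle(
    patient_id="P1",
    birth_year=1970,
    sex="F",
    spans=((D(2014, 1, 1), D(2020, 12, 31)),),
    claims=(),
    fills=(),
    death=None,
    truth=None,
):
    """Hand-built bundle; claims are (date, code[, setting[, discharge]])
    tuples, fills are (date, ingredient)."""
    medical = []
    for item in claims:
        date, code, *rest = item
        setting = rest[0] if rest else "outpatient"
        discharge = rest[1] if len(rest) > 1 else None
        codes = tuple(code) if isinstance(code, (list, tuple)) else (code,)
        medical.append(MedicalClaim(service_date=date, codes=codes,
                                    setting=setting, discharge_date=discharge))
    pharmacy = [PharmacyFill(fill_date=d, ingredient=i) for d, i in fills]
    if death is not None and not isinstance(death, DeathRecord):
        date, codes = death
        codes = tuple(codes) if isinstance(codes, (list, tuple)) else (codes,)
        death = DeathRecord(death_date=date, cause_codes=codes)
    return ClaimsBundle(
        patient_id=patient_id, birth_year=birth_year, sex=sex,
        enrollment_spans=[tuple(s) for s in spans],
        medical_claims=medical, pharmacy_fills=pharmacy,
        death=death, planted_truth=truth,
    )
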