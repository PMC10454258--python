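"""Delimited-table schema for claims data, plus reader/writer.

Files (comma-delimited, ISO-8601 dates):

* ``patients.csv``        — patient_id, birth_year, sex
* ``enrollment.csv``      — patient_id, span_start, span_end
* ``medical_claims.csv``  — patient_id, service_date, setting, discharge_date,
  diagnosis_codes (semicolon-joined, claim-position order); a wide dialect
  with dx1..dxK columns is also read
* ``pharmacy_claims.csv`` — patient_id, fill_date, ingredient
* ``deaths.csv``          — patient_id, death_date, cause_codes (optional file)
* ``truth.csv``           — generator labels; written separately, never read
  by any analysis stage

Rows violating bundle invariants (claims outside enrollment, unknown
patients) are rejected and counted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from ._util import parse_date
from .bundles import ClaimsBundle, DeathRecord, MedicalClaim, PharmacyFill
from .errors import SchemaError

log = logging.getLogger(__name__)

_REQUIRED = {
    "patients.csv": ["patient_id", "birth_year", "sex"],
    "enrollment.csv": ["patient_id", "span_start", "span_end"],
    "medical_claims.csv": ["patient_id", "service_date", "setting", "discharge_date"],
    "pharmacy_claims.csv": ["patient_id", "fill_date", "ingredient"],
}


def write_tables(population, directory) -> dict:
    """Write a population; returns row counts per file.  The deaths file is
    omitted when no deaths exist; truth labels go to a separate file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    patients, enrollment, claims, fills, deaths, truth = [], [], [], [], [], []
    for b in sorted(population, key=lambda b: b.patient_id):
        patients.append({"patient_id": b.patient_id, "birth_year": b.birth_year,
                         "sex": b.sex})
        for start, end in b.enrollment_spans:
            enrollment.append({"patient_id": b.patient_id,
                               "span_start": start.isoformat(),
                               "span_end": end.isoformat()})
        for c in b.medical_claims:
            claims.append({
                "patient_id": b.patient_id,
                "service_date": c.service_date.isoformat(),
                "setting": c.setting,
                "discharge_date": c.discharge_date.isoformat() if c.discharge_date else "",
                "diagnosis_codes": ";".join(c.codes),
            })
        for f in b.pharmacy_fills:
            fills.append({"patient_id": b.patient_id,
                          "fill_date": f.fill_date.isoformat(),
                          "ingredient": f.ingredient})
        if b.death is not None:
            deaths.append({"patient_id": b.patient_id,
                           "death_date": b.death.death_date.isoformat(),
                           "cause_codes": ";".join(b.death.cause_codes)})
        if b.planted_truth is not None:
            truth.append({"patient_id": b.patient_id, **b.planted_truth})

    counts = {}
    tables = {
        "patients.csv": (patients, ["patient_id", "birth_year", "sex"]),
        "enrollment.csv": (enrollment, ["patient_id", "span_start", "span_end"]),
        "medical_claims.csv": (claims, ["patient_id", "service_date", "setting",
                                        "discharge_date", "diagnosis_codes"]),
        "pharmacy_claims.csv": (fills, ["patient_id", "fill_date", "ingredient"]),
    }
    try:
        for name, (rows, columns) in tables.items():
            pd.DataFrame(rows, columns=columns).to_csv(directory / name, index=False)
            counts[name] = len(rows)
        if deaths:
            pd.DataFrame(deaths).to_csv(directory / "deaths.csv", index=False)
            counts["deaths.csv"] = len(deaths)
        if truth:
            pd.DataFrame(truth).to_csv(directory / "truth.csv", index=False)
            counts["truth.csv"] = len(truth)
    except OSError as exc:
        raise OSError(f"failed writing tables under {directory}: {exc}") from exc
    return counts


def _read_csv(directory: Path, name: str, required: list[str],
              optional: bool = False) -> pd.DataFrame | None:
    path = directory / name
    if not path.exists():
        if optional:
            return None
        raise SchemaError(f"missing required table: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")
    return df


def _claim_codes(row: pd.Series, dx_cols: list[str]) -> tuple[str, ...]:
    joined = row.get("diagnosis_codes", "")
    if joined:
        return tuple(c for c in str(joined).split(";") if c)
    return tuple(str(row[c]) for c in dx_cols if str(row.get(c, "")).strip())


def read_tables(directory) -> tuple[list[ClaimsBundle], dict]:
    """Read and validate a population; returns (bundles, rejection counts)."""
    directory = Path(directory)
    patients = _read_csv(directory, "patients.csv", _REQUIRED["patients.csv"])
    enrollment = _read_csv(directory, "enrollment.csv", _REQUIRED["enrollment.csv"])
    claims = _read_csv(directory, "medical_claims.csv", _REQUIRED["medical_claims.csv"])
    fills = _read_csv(directory, "pharmacy_claims.csv", _REQUIRED["pharmacy_claims.csv"])
    deaths = _read_csv(directory, "deaths.csv",
                       ["patient_id", "death_date", "cause_codes"], optional=True)

    spans_by_pid: dict[str, list] = {}
    for _, row in enrollment.iterrows():
        spans_by_pid.setdefault(row["patient_id"], []).append(
            (parse_date(row["span_start"]), parse_date(row["span_end"]))
        )

    dx_cols = sorted(c for c in claims.columns if c.startswith("dx"))
    rejected = {"medical_claims": 0, "pharmacy_claims": 0, "deaths": 0}

    claims_by_pid: dict[str, list[MedicalClaim]] = {}
    for _, row in claims.iterrows():
        pid = row["patient_id"]
        day = parse_date(row["service_date"])
        spans = spans_by_pid.get(pid, [])
        if not any(s <= day <= e for s, e in spans):
            rejected["medical_claims"] += 1
            continue
        discharge = row.get("discharge_date", "")
        claims_by_pid.setdefault(pid, []).append(MedicalClaim(
            service_date=day,
            codes=_claim_codes(row, dx_cols),
            setting=row.get("setting", "outpatient") or "outpatient",
            discharge_date=parse_date(discharge) if discharge else None,
        ))

    fills_by_pid: dict[str, list[PharmacyFill]] = {}
    for _, row in fills.iterrows():
        pid = row["patient_id"]
        day = parse_date(row["fill_date"])
        if not any(s <= day <= e for s, e in spans_by_pid.get(pid, [])):
            rejected["pharmacy_claims"] += 1
            continue
        fills_by_pid.setdefault(pid, []).append(
            PharmacyFill(fill_date=day, ingredient=row["ingredient"])
        )

    deaths_by_pid: dict[str, DeathRecord] = {}
    if deaths is not None:
        known = set(patients["patient_id"])
        for _, row in deaths.iterrows():
            pid = row["patient_id"]
            if pid not in known:
                rejected["deaths"] += 1
                log.warning("deaths.csv: unknown patient %r dropped", pid)
                continue
            deaths_by_pid[pid] = DeathRecord(
                death_date=parse_date(row["death_date"]),
                cause_codes=tuple(c for c in str(row["cause_codes"]).split(";") if c),
            )

    bundles = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        bundles.append(ClaimsBundle(
            patient_id=pid,
            birth_year=int(row["birth_year"]),
            sex=row["sex"],
            enrollment_spans=sorted(spans_by_pid.get(pid, [])),
            medical_claims=claims_by_pid.get(pid, []),
            pharmacy_fills=fills_by_pid.get(pid, []),
            death=deaths_by_pid.get(pid),
        ))
    if any(rejected.values()):
        log.info("rejected rows: %s", rejected)
    return bundles, rejected
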