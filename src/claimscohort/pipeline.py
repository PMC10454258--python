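"""End-to-end orchestration: load/simulate -> phenotype -> characterize ->
link deaths -> person-time rates per definition -> misclassification
adjustment -> report files + machine-readable manifest."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .adjustment import adjust_from_rates, adjustment_report
from .bundles import ClaimsBundle
from .characterization import CharacterizationWindow, characterize, summarize_cohort
from .codesets import load_codesets
from .errors import ConfigurationError
from .io import read_tables, write_tables
from .linkage import DEFAULT_NDI_CUTOFF, link_deaths
from .phenotyping import StudyWindow, assign_cohorts
from .rates import observation_anchor, recent_sisa, round_rate, stratified_rates, time_at_risk
from .synthetic import SimulationSpec, generate_population

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one of ``input_dir`` /
    ``simulation`` must be provided."""

    output_dir: Path
    input_dir: Optional[Path] = None
    simulation: Optional[SimulationSpec] = None
    codeset_config: Optional[Path] = None
    identification_start: dt.date = dt.date(2016, 1, 1)
    identification_end: dt.date = dt.date(2019, 6, 30)
    observation_end: dt.date = dt.date(2019, 9, 30)
    ndi_cutoff: dt.date = DEFAULT_NDI_CUTOFF
    definitions: tuple[str, ...] = ("broad", "probable", "strict")
    strata: tuple[str, ...] = ("age_group", "sex", "recent_sisa")
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigurationError(
                "provide exactly one of input tables or a simulation spec"
            )

    def study_window(self) -> StudyWindow:
        return StudyWindow(
            identification_start=self.identification_start,
            identification_end=self.identification_end,
            observation_end=self.observation_end,
        )

    def fingerprint(self) -> str:
        def default(o):
            if isinstance(o, (dt.date, Path)):
                return str(o)
            if hasattr(o, "__dict__"):
                return o.__dict__
            return repr(o)

        fields = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        blob = json.dumps(fields, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write report tables; returns the manifest."""
    config.validate()
    registry = load_codesets(config.codeset_config)
    window = config.study_window()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        population = generate_population(config.simulation)
        write_tables(population, outdir / "input_tables")
        rejected: dict = {}
    else:
        population, rejected = read_tables(config.input_dir)
    population = [b.without_truth() for b in population]
    by_id = {b.patient_id: b for b in population}

    assignments, attrition = assign_cohorts(population, window, registry)
    linked, assumed_alive = link_deaths(
        population, registry=registry, ndi_cutoff=config.ndi_cutoff
    )

    profile_rows, char_profiles, tars = [], [], []
    for a in assignments:
        bundle = by_id[a.patient_id]
        anchor = observation_anchor(bundle, window)
        recent = recent_sisa(bundle, anchor, registry)
        for cohort, index in a.memberships():
            profile_rows.append({
                "patient_id": a.patient_id, "cohort": cohort,
                "age_group": _age_group(bundle, index), "sex": bundle.sex,
                "recent_sisa": recent,
            })
            windows = [CharacterizationWindow.baseline(index),
                       CharacterizationWindow.last_year(anchor)]
            char_profiles.extend(
                (kind, p) for kind, p in
                characterize(bundle, cohort, index, windows, registry).items()
            )
        tars.extend(time_at_risk(a, bundle, linked.get(a.patient_id), window))
    profiles = pd.DataFrame(
        profile_rows, columns=["patient_id", "cohort", "age_group", "sex", "recent_sisa"]
    )

    # report tables
    pd.DataFrame(attrition).to_csv(outdir / "attrition.csv", index=False)
    cohort_table = pd.DataFrame([{
        "patient_id": a.patient_id,
        "in_trd": a.in_trd, "trd_index": a.trd_index or "",
        "in_sisa": a.in_sisa, "sisa_index": a.sisa_index or "",
        "in_mdd_alone": a.in_mdd_alone, "mdd_alone_index": a.mdd_alone_index or "",
        "established_mdd_date": a.established_mdd_date or "",
        "exclusion_reasons": ";".join(a.exclusion_reasons),
    } for a in assignments])
    cohort_table.to_csv(outdir / "cohorts.csv", index=False)

    char_frames = []
    for kind in ("baseline", "last_year"):
        for cohort in ("trd", "sisa", "mdd_alone"):
            subset = [p for k, p in char_profiles if k == kind and p.cohort == cohort]
            summary = summarize_cohort(subset)
            summary.insert(0, "window", kind)
            summary.insert(1, "cohort", cohort)
            char_frames.append(summary)
    pd.concat(char_frames, ignore_index=True).to_csv(
        outdir / "characterization.csv", index=False
    )

    rate_tables = {}
    for definition in config.definitions:
        tab = stratified_rates(tars, linked, profiles, config.strata,
                               definition=definition)
        tab["rate_per_100"] = tab["rate_per_100"].map(round_rate)
        tab.to_csv(outdir / f"rates_{definition}.csv", index=False,
                   float_format="%.4f")
        rate_tables[definition] = tab

    if {"broad", "probable", "strict"} <= set(config.definitions):
        results = adjust_from_rates(rate_tables)
        adjustment_report(results).to_csv(outdir / "adjustment.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config_hash": config.fingerprint(),
        "seed": config.seed if config.simulation is None else config.simulation.seed,
        "n_patients": len(population),
        "n_frame": next(r["n_remaining"] for r in attrition
                        if r["step"] == "two_mdd_claims_in_identification_period"),
        "cohort_sizes": {
            "trd": int(cohort_table["in_trd"].sum()),
            "sisa": int(cohort_table["in_sisa"].sum()),
            "mdd_alone": int(cohort_table["in_mdd_alone"].sum()),
        },
        "n_linked_deaths": len(linked),
        "n_assumed_alive": len(assumed_alive),
        "rejected_rows": rejected,
        "rate_table_rows": {d: len(t) for d, t in rate_tables.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _age_group(bundle: ClaimsBundle, index: dt.date) -> str:
    from .characterization import age_group_of

    return age_group_of(index.year - bundle.birth_year)
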