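"""Deterministic death-record linkage and cause-of-death classification.

Only patients whose enrollment does not extend beyond the configured
death-index search cutoff are linked; patients still enrolled past the
cutoff are assumed alive regardless of any record on file.  Each linked
death is classified under every configured suicide definition, matching
both underlying and contributory (multiple-cause) codes.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .bundles import ClaimsBundle, DeathRecord
from .codesets import CodesetRegistry, normalize_code

log = logging.getLogger(__name__)

DEFAULT_NDI_CUTOFF = dt.date(2019, 12, 31)


@dataclass(frozen=True)
class LinkedDeath:
    patient_id: str
    death_date: dt.date
    cause_codes: tuple[str, ...]
    suicide_by_definition: Mapping[str, bool]


def classify_suicide(cause_codes: Sequence[str], definition: str,
                     registry: CodesetRegistry) -> bool:
    """True iff any cause code (any position) matches any group prefix of
    the named definition."""
    prefixes = registry.definition_prefixes(definition)
    for code in cause_codes:
        norm = normalize_code(code)
        if any(norm.startswith(p) for p in prefixes):
            return True
    return False


def link_deaths(population: Sequence[ClaimsBundle],
                death_records: Optional[Mapping[str, DeathRecord]] = None,
                *,
                registry: CodesetRegistry,
                ndi_cutoff: dt.date = DEFAULT_NDI_CUTOFF,
                ) -> tuple[dict[str, LinkedDeath], set[str]]:
    """Link death records to patients; returns (linked, assumed_alive ids).

    ``death_records`` defaults to the records carried on the bundles.
    Records for unknown patients are logged and dropped.
    """
    by_id = {b.patient_id: b for b in population}
    if death_records is None:
        death_records = {
            b.patient_id: b.death for b in population if b.death is not None
        }
    linked: dict[str, LinkedDeath] = {}
    assumed_alive: set[str] = set()
    for pid, record in death_records.items():
        bundle = by_id.get(pid)
        if bundle is None:
            log.warning("death record for unknown patient %r dropped", pid)
            continue
        end = bundle.enrollment_end
        if end is not None and end > ndi_cutoff:
            assumed_alive.add(pid)
            continue
        flags = {
            name: classify_suicide(record.cause_codes, name, registry)
            for name in registry.suicide_definitions
        }
        linked[pid] = LinkedDeath(
            patient_id=pid,
            death_date=record.death_date,
            cause_codes=tuple(record.cause_codes),
            suicide_by_definition=flags,
        )
    return linked, assumed_alive


def suicide_counts(linked: Iterable[LinkedDeath]) -> dict[str, int]:
    """Death counts per definition; always monotone under nesting."""
    counts: dict[str, int] = {}
    for d in linked:
        for name, flag in d.suicide_by_definition.items():
            counts.setdefault(name, 0)
            if flag:
                counts[name] += 1
    return counts
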