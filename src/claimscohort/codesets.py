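"""Code lists, drug classification, and nested cause-of-death definitions.

All diagnosis and cause-of-death matching in the package goes through this
module: codes are compared as undotted, uppercased ICD-10(-CM) strings
against explicit prefix lists.  Ranges written as ``"X40-X44"`` in config
are expanded to explicit prefixes at load time so matching is pure prefix
comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

_PREFIX_RE = re.compile(r"^[A-Z0-9]+$")
_RANGE_RE = re.compile(r"^([A-Z]+)(\d+)\s*[-‐-―]\s*([A-Z]+)?(\d+)$")

#: Diagnosis code sets every loaded registry must provide.
MANDATORY_CODESETS = frozenset(
    {
        "mdd",
        "si",
        "sa",
        "bipolar_mania",
        "dementia",
        "psychosis",
        "autism",
        "schizophrenia_psychotic",
    }
)

#: Cause-of-death definitions every loaded registry must provide, in
#: superset order (each must contain the next as a code set).
NESTED_DEFINITIONS = ("broad", "probable", "strict")

DRUG_CLASSES = (
    "antidepressant",
    "atypical_antipsychotic",
    "antipsychotic_other",
    "anxiolytic",
    "benzodiazepine",
    "other",
)


def normalize_code(code: str) -> str:
    """Canonical undotted uppercase form of an ICD-10 code string."""
    return str(code).replace(".", "").replace(" ", "").upper()


def expand_code_range(token: str) -> list[str]:
    """Expand a range token like ``"T36-T65"`` into explicit prefixes.

    Single codes pass through unchanged.  Both endpoints are inclusive and
    must share the alphabetic part and numeric width.
    """
    token = normalize_code(token)
    m = _RANGE_RE.match(token)
    if m is None:
        return [token]
    alpha, lo, alpha2, hi = m.groups()
    if alpha2 is not None and alpha2 != alpha:
        raise ConfigurationError(
            f"code range {token!r} spans different letters; list codes explicitly"
        )
    if len(lo) != len(hi):
        raise ConfigurationError(f"code range {token!r} endpoints differ in width")
    if int(lo) > int(hi):
        raise ConfigurationError(f"code range {token!r} is reversed")
    width = len(lo)
    return [f"{alpha}{i:0{width}d}" for i in range(int(lo), int(hi) + 1)]


def _expand_prefixes(tokens: Iterable[str]) -> tuple[str, ...]:
    out: list[str] = []
    for tok in tokens:
        out.extend(expand_code_range(tok))
    return tuple(out)


@dataclass(frozen=True)
class DiagnosisCodeSet:
    """A named list of ICD-10-CM prefixes with prefix-match semantics."""

    name: str
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ValidationError(f"code set {self.name!r} has no prefixes")
        bad = [p for p in self.prefixes if not _PREFIX_RE.match(p)]
        if bad:
            raise ValidationError(
                f"code set {self.name!r} has non-alphanumeric prefixes: {bad}"
            )
        if len(set(self.prefixes)) != len(self.prefixes):
            dupes = sorted({p for p in self.prefixes if self.prefixes.count(p) > 1})
            raise ValidationError(f"code set {self.name!r} has duplicate prefixes: {dupes}")


@dataclass(frozen=True)
class CauseOfDeathGroup:
    """One named group of cause-of-death code prefixes."""

    name: str
    prefixes: tuple[str, ...]


@dataclass(frozen=True)
class SuicideDefinition:
    """A named set of cause-of-death groups (broad / probable / strict)."""

    name: str
    groups: frozenset[str]

    def prefixes(self, registry: "CodesetRegistry") -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out.update(registry.cod_groups[g].prefixes)
        return frozenset(out)


@dataclass(frozen=True)
class CodesetRegistry:
    """Everything the algorithms look codes up in.

    ``diagnosis`` and ``cod_groups`` map names to prefix sets;
    ``drug_classes`` maps each ingredient to exactly one class;
    ``condition_categories`` is the miniature comorbidity grouper.
    """

    diagnosis: Mapping[str, DiagnosisCodeSet]
    cod_groups: Mapping[str, CauseOfDeathGroup]
    suicide_definitions: Mapping[str, SuicideDefinition]
    drug_classes: Mapping[str, str]
    condition_categories: Mapping[str, DiagnosisCodeSet] = field(default_factory=dict)
    sa_intentional_only: bool = False

    def drug_class(self, ingredient: str) -> str | None:
        return self.drug_classes.get(str(ingredient).strip().lower())

    def definition_prefixes(self, definition: str) -> frozenset[str]:
        return self.suicide_definitions[definition].prefixes(self)


def code_matches(code: str, codeset: DiagnosisCodeSet | CauseOfDeathGroup,
                 *, intentional_only: bool = False) -> bool:
    """True iff the undotted, uppercased code starts with any set prefix.

    Matching is dot-insensitive.  Malformed codes never match (logged at
    debug level, not raised).  With ``intentional_only``, codes matching a
    T36..T65 prefix additionally need the ICD-10-CM intent character
    (6th character) to be ``"2"`` (intentional self-harm).
    """
    norm = normalize_code(code)
    if not norm or not _PREFIX_RE.match(norm):
        log.debug("malformed code %r ignored", code)
        return False
    for prefix in codeset.prefixes:
        if norm.startswith(prefix):
            if (
                intentional_only
                and prefix[0] == "T"
                and prefix != "T71"
                and "T36" <= prefix <= "T65"
            ):
                if len(norm) < 6 or norm[5] != "2":
                    continue
            return True
    return False


def _default_config() -> dict:
    text = resources.files("claimscohort.data").joinpath("default_codesets.yaml").read_text()
    return yaml.safe_load(text)


def load_codesets(config_source: str | Path | Mapping | None = None) -> CodesetRegistry:
    """Build a :class:`CodesetRegistry` from a YAML path, a dict, or the
    packaged default config.

    Raises :class:`ConfigurationError` for missing mandatory sections and
    :class:`ValidationError` when the broad/probable/strict nesting or the
    cause-group disjointness invariant fails.
    """
    if config_source is None:
        raw = _default_config()
    elif isinstance(config_source, Mapping):
        raw = dict(config_source)
    else:
        with open(config_source) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError("codeset config did not parse to a mapping")

    dx_raw = raw.get("diagnosis_codesets") or {}
    diagnosis = {
        name: DiagnosisCodeSet(name=name, prefixes=_expand_prefixes(tokens))
        for name, tokens in dx_raw.items()
    }
    missing = MANDATORY_CODESETS - diagnosis.keys()
    if missing:
        raise ConfigurationError(f"missing mandatory diagnosis code sets: {sorted(missing)}")

    groups_raw = raw.get("cause_of_death_groups") or {}
    cod_groups = {
        name: CauseOfDeathGroup(name=name, prefixes=_expand_prefixes(tokens))
        for name, tokens in groups_raw.items()
    }
    _check_disjoint(cod_groups)

    defs_raw = raw.get("suicide_definitions") or {}
    missing_defs = set(NESTED_DEFINITIONS) - defs_raw.keys()
    if missing_defs:
        raise ConfigurationError(f"missing suicide definitions: {sorted(missing_defs)}")
    definitions: dict[str, SuicideDefinition] = {}
    for name, group_names in defs_raw.items():
        unknown = set(group_names) - cod_groups.keys()
        if unknown:
            raise ConfigurationError(
                f"suicide definition {name!r} references undeclared groups: {sorted(unknown)}"
            )
        definitions[name] = SuicideDefinition(name=name, groups=frozenset(group_names))

    classes_raw = raw.get("drug_classes") or {}
    drug_classes: dict[str, str] = {}
    for cls, ingredients in classes_raw.items():
        for ing in ingredients:
            key = str(ing).strip().lower()
            if key in drug_classes:
                raise ConfigurationError(
                    f"ingredient {key!r} mapped to both {drug_classes[key]!r} and {cls!r}"
                )
            drug_classes[key] = cls

    categories = {
        name: DiagnosisCodeSet(name=name, prefixes=_expand_prefixes(tokens))
        for name, tokens in (raw.get("condition_categories") or {}).items()
    }

    options = raw.get("options") or {}
    registry = CodesetRegistry(
        diagnosis=diagnosis,
        cod_groups=cod_groups,
        suicide_definitions=definitions,
        drug_classes=drug_classes,
        condition_categories=categories,
        sa_intentional_only=bool(options.get("sa_intentional_only", False)),
    )
    _check_nesting(registry)
    return registry


def _check_disjoint(groups: Mapping[str, CauseOfDeathGroup]) -> None:
    seen: dict[str, str] = {}
    for g in groups.values():
        for p in g.prefixes:
            if p in seen:
                raise ValidationError(
                    f"cause-of-death prefix {p!r} in both {seen[p]!r} and {g.name!r}"
                )
            seen[p] = g.name


def _check_nesting(registry: CodesetRegistry) -> None:
    for outer, inner in zip(NESTED_DEFINITIONS, NESTED_DEFINITIONS[1:]):
        outer_p = registry.definition_prefixes(outer)
        inner_p = registry.definition_prefixes(inner)
        extra = inner_p - outer_p
        if extra:
            raise ValidationError(
                f"definition {inner!r} is not nested in {outer!r}; "
                f"offending prefixes: {sorted(extra)}"
            )
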