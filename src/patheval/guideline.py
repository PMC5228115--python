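"""Guideline configuration: domain model, loading, validation, serialization.

A *guideline* is a self-contained formal rule system for germline variant
classification: a set of evidence codes (e.g. ``PVS1``, ``BS2``), an evidence
grid that places each code in one (evidence type x strength) cell, a set of
combining rules expressed as thresholds over counts of applied tags at each
strength level, and a metarule policy that resolves multiple or conflicting
satisfied rules. The ACMG/AMP 2015 guideline ships as packaged configuration;
custom guidelines (gene- or disease-specific variants, novel evidence types
such as metabolite levels) are loaded from user-supplied documents.

A guideline is completely defined by three structured documents:

1. rules and metarules (plus identity and the ordered conclusion list),
2. evidence codes and their grid-cell assignments,
3. the rows (evidence types) and columns (strength levels) of the grid.

Both a single bundle file and a directory of three co-located files
(``rules``, ``codes``, ``grid``) are accepted, in JSON or YAML; JSON is
written. Structural problems are reported by pydantic with every offending
field listed; semantic problems (dangling references, duplicates,
unsatisfiable rules) are collected exhaustively by :func:`validate_guideline`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

Direction = Literal["pathogenic", "benign"]

#: Section names of the three-document split (directory form of a bundle).
DOCUMENT_SECTIONS = {
    "rules": ("meta", "conclusions", "rules", "metarules"),
    "codes": ("codes",),
    "grid": ("strength_levels", "evidence_types"),
}


class ConfigurationError(Exception):
    """A guideline document set is missing or structurally unreadable."""


class GuidelineValidationError(Exception):
    """A parsed guideline violates its invariants.

    Carries the complete list of violations, never just the first.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "\n".join(f"  - [{v.kind}] {v.location}: {v.message}" for v in violations)
        super().__init__(f"guideline failed validation with {len(violations)} violation(s):\n{lines}")


# ---------------------------------------------------------------------------
# Domain model
# ---------------------------------------------------------------------------

class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GuidelineMeta(_Model):
    id: str
    version: str = "1.0"
    name: str = ""
    description: str = ""


class StrengthLevel(_Model):
    """One column of the evidence grid: a weight in one direction.

    ``rank`` orders levels within a direction, higher = stronger; level lists
    are written strongest first with strictly decreasing ranks.
    """

    direction: Direction
    level_id: str
    label: str = ""
    rank: int


class EvidenceType(_Model):
    """One row of the evidence grid (e.g. Population Data, Functional Data)."""

    type_id: str
    label: str


class EvidenceCode(_Model):
    """One criterion, occupying exactly one grid cell at its default strength."""

    code_id: str
    direction: Direction
    default_strength: str
    evidence_type: str
    description: str = ""


class ThresholdTerm(_Model):
    """Requires ``min_count <= observed <= max_count`` tags at one strength.

    ``max_count`` of ``None`` means unbounded; bounded maxima express rules
    such as "1-2 Moderate".
    """

    direction: Direction
    strength: str
    min_count: int = Field(ge=0)
    max_count: Optional[int] = Field(default=None, ge=0)


class CombiningRule(_Model):
    """A rule supporting one conclusion.

    ``kind`` is ``threshold`` for ordinary count rules. The two special kinds
    mirror the published combining table's uncertain-significance rows and
    carry no terms: ``no_rule_fallback`` fires when no threshold rule is
    satisfied, ``directional_conflict`` when satisfied rules exist in both
    directions. Both are applied by the metarule policy, never by term
    evaluation.
    """

    rule_id: str
    conclusion: str
    kind: Literal["threshold", "no_rule_fallback", "directional_conflict"] = "threshold"
    terms: tuple[ThresholdTerm, ...] = ()
    description: str = ""

    @property
    def direction(self) -> Optional[Direction]:
        """Direction of a threshold rule's terms; None for special kinds."""
        return self.terms[0].direction if self.terms else None


class MetarulePolicy(_Model):
    """Resolution policy applied after rule evaluation.

    ``precedence`` picks among several satisfied same-direction conclusions
    (strongest first); ``conflict_scope`` selects whether a conflict means
    satisfied rules in both directions (``rule``, the default) or merely
    applied tags in both directions (``tag``).
    """

    precedence: tuple[str, ...]
    conflict_conclusion: str
    insufficient_conclusion: str
    conflict_scope: Literal["rule", "tag"] = "rule"
    conflict_rule: Optional[str] = None
    insufficient_rule: Optional[str] = None


class Guideline(_Model):
    meta: GuidelineMeta
    conclusions: tuple[str, ...]
    strength_levels: tuple[StrengthLevel, ...]
    evidence_types: tuple[EvidenceType, ...]
    codes: tuple[EvidenceCode, ...]
    rules: tuple[CombiningRule, ...]
    metarules: MetarulePolicy

    @property
    def guideline_id(self) -> str:
        return self.meta.id

    def level(self, direction: str, level_id: str) -> Optional[StrengthLevel]:
        for lv in self.strength_levels:
            if lv.direction == direction and lv.level_id == level_id:
                return lv
        return None

    def levels_for(self, direction: str) -> list[StrengthLevel]:
        return [lv for lv in self.strength_levels if lv.direction == direction]

    def code(self, code_id: str) -> Optional[EvidenceCode]:
        wanted = code_id.upper()
        for c in self.codes:
            if c.code_id.upper() == wanted:
                return c
        return None

    def evidence_type(self, type_id: str) -> Optional[EvidenceType]:
        for t in self.evidence_types:
            if t.type_id == type_id:
                return t
        return None

    def codes_in_cell(self, type_id: str, direction: str, level_id: str) -> list[EvidenceCode]:
        """Codes whose default grid cell is (type row, strength column)."""
        return [
            c for c in self.codes
            if c.evidence_type == type_id and c.direction == direction
            and c.default_strength == level_id
        ]

    def threshold_rules(self) -> list[CombiningRule]:
        return [r for r in self.rules if r.kind == "threshold"]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One invariant violation or lint; data, not an exception."""

    kind: str
    location: str
    message: str


def validate_guideline(g: Guideline) -> list[Violation]:
    """Return every invariant violation and lint found in ``g``.

    Checks cross-reference integrity (codes -> strengths/types, rules ->
    strengths, metarules -> conclusions), uniqueness (case-insensitive code
    ids, level and type ids, rule ids), rank ordering within each direction,
    direction consistency of codes and of rule terms, unsatisfiable terms
    (min > max), and conclusions never produced by any rule or metarule.
    """
    out: list[Violation] = []

    def bad(kind: str, location: str, message: str) -> None:
        out.append(Violation(kind, location, message))

    level_keys = set()
    for lv in g.strength_levels:
        key = (lv.direction, lv.level_id)
        if key in level_keys:
            bad("duplicate_level", f"strength_levels[{lv.level_id}]",
                f"level ({lv.direction}, {lv.level_id}) declared more than once")
        level_keys.add(key)
    for direction in ("pathogenic", "benign"):
        ranks = [lv.rank for lv in g.strength_levels if lv.direction == direction]
        if any(a <= b for a, b in zip(ranks, ranks[1:])):
            bad("rank_order", f"strength_levels[{direction}]",
                "ranks must be strictly decreasing from strongest to weakest")

    type_ids = set()
    for t in g.evidence_types:
        if t.type_id in type_ids:
            bad("duplicate_type", f"evidence_types[{t.type_id}]",
                f"evidence type {t.type_id!r} declared more than once")
        type_ids.add(t.type_id)

    seen_codes = set()
    for c in g.codes:
        cid = c.code_id.upper()
        if cid in seen_codes:
            bad("duplicate_code", f"codes[{c.code_id}]",
                f"code id {c.code_id!r} duplicates another code (ids compare case-insensitively)")
        seen_codes.add(cid)
        if (c.direction, c.default_strength) not in level_keys:
            bad("dangling_strength", f"codes[{c.code_id}]",
                f"default strength ({c.direction}, {c.default_strength}) is not a declared level")
        if c.evidence_type not in type_ids:
            bad("dangling_type", f"codes[{c.code_id}]",
                f"evidence type {c.evidence_type!r} is not a declared grid row")

    conclusions = set(g.conclusions)
    rule_ids = set()
    for r in g.rules:
        if r.rule_id in rule_ids:
            bad("duplicate_rule", f"rules[{r.rule_id}]", f"rule id {r.rule_id!r} declared more than once")
        rule_ids.add(r.rule_id)
        if r.conclusion not in conclusions:
            bad("unknown_conclusion", f"rules[{r.rule_id}]",
                f"conclusion {r.conclusion!r} is not in the guideline's conclusion list")
        if r.kind == "threshold":
            if not r.terms:
                bad("empty_rule", f"rules[{r.rule_id}]", "threshold rule has no terms")
            directions = {t.direction for t in r.terms}
            if len(directions) > 1:
                bad("mixed_direction_rule", f"rules[{r.rule_id}]",
                    "all terms of one rule must count tags of the same direction")
        elif r.terms:
            bad("terms_on_special_rule", f"rules[{r.rule_id}]",
                f"rule of kind {r.kind!r} must not carry threshold terms")
        for i, t in enumerate(r.terms):
            if (t.direction, t.strength) not in level_keys:
                bad("dangling_strength", f"rules[{r.rule_id}].terms[{i}]",
                    f"strength ({t.direction}, {t.strength}) is not a declared level")
            if t.max_count is not None and t.min_count > t.max_count:
                bad("unsatisfiable_term", f"rules[{r.rule_id}].terms[{i}]",
                    f"min_count {t.min_count} exceeds max_count {t.max_count}")

    m = g.metarules
    for field, token in (
        ("conflict_conclusion", m.conflict_conclusion),
        ("insufficient_conclusion", m.insufficient_conclusion),
        *(("precedence", p) for p in m.precedence),
    ):
        if token not in conclusions:
            bad("unknown_conclusion", f"metarules.{field}",
                f"conclusion {token!r} is not in the guideline's conclusion list")
    for field, rid in (("conflict_rule", m.conflict_rule), ("insufficient_rule", m.insufficient_rule)):
        if rid is not None and rid not in rule_ids:
            bad("dangling_rule", f"metarules.{field}", f"rule {rid!r} is not declared")

    producible = {r.conclusion for r in g.rules} | {m.conflict_conclusion, m.insufficient_conclusion}
    for token in g.conclusions:
        if token not in producible:
            bad("unreachable_conclusion", f"conclusions[{token}]",
                f"conclusion {token!r} is never produced by any rule or metarule")

    return out


# ---------------------------------------------------------------------------
# Loading and writing
# ---------------------------------------------------------------------------

def _read_structured(path: Path) -> dict:
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigurationError(f"cannot read guideline document {path}: {exc}") from exc
    try:
        if path.suffix.lower() in {".yaml", ".yml"}:
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"guideline document {path} is not parseable: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"guideline document {path} must contain a mapping at top level")
    return data


def _find_document(directory: Path, stem: str) -> Path:
    for suffix in (".json", ".yaml", ".yml"):
        candidate = directory / f"{stem}{suffix}"
        if candidate.exists():
            return candidate
    raise ConfigurationError(
        f"guideline directory {directory} is missing the {stem!r} document "
        f"({stem}.json or {stem}.yaml)"
    )


def _parse_bundle(data: dict, source: str) -> Guideline:
    try:
        g = Guideline.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(f"guideline from {source} is structurally invalid:\n{exc}") from exc
    violations = validate_guideline(g)
    if violations:
        raise GuidelineValidationError(violations)
    return g


def load_guideline(source: str | Path) -> Guideline:
    """Load and fully validate a guideline from a bundle file or directory.

    ``source`` may be a single bundle file (all sections in one document) or
    a directory holding the three documents ``rules``, ``codes`` and ``grid``.
    Raises :class:`ConfigurationError` for missing/unreadable documents and
    :class:`GuidelineValidationError` (listing every violation) for semantic
    problems; never returns a partially valid guideline.
    """
    path = Path(source)
    if path.is_dir():
        paths = {stem: _find_document(path, stem) for stem in DOCUMENT_SECTIONS}
        data: dict = {}
        for stem, sections in DOCUMENT_SECTIONS.items():
            doc = _read_structured(paths[stem])
            for section in sections:
                if section not in doc:
                    raise ConfigurationError(
                        f"document {stem!r} in {path} is missing section {section!r}")
                data[section] = doc[section]
        return _parse_bundle(data, str(path))
    if not path.exists():
        raise ConfigurationError(f"guideline source {path} does not exist")
    return _parse_bundle(_read_structured(path), str(path))


def write_guideline(g: Guideline, target: str | Path, split: bool = False) -> None:
    """Serialize ``g`` as JSON: one bundle file, or three documents if ``split``.

    ``load_guideline(write_guideline(g))`` reproduces ``g`` field for field.
    """
    data = g.model_dump(mode="json")
    target = Path(target)
    if split:
        target.mkdir(parents=True, exist_ok=True)
        for stem, sections in DOCUMENT_SECTIONS.items():
            doc = {section: data[section] for section in sections}
            (target / f"{stem}.json").write_text(json.dumps(doc, indent=2) + "\n")
    else:
        target.write_text(json.dumps(data, indent=2) + "\n")


_DEFAULT_RESOURCE = "acmg_amp_2015.json"
_default_cache: Optional[Guideline] = None


def default_acmg_guideline() -> Guideline:
    """The packaged ACMG/AMP 2015 guideline.

    28 evidence codes (PVS1; PS1-PS4; PM1-PM6; PP1-PP5; BA1; BS1-BS4;
    BP1-BP7), pathogenic strength levels very_strong/strong/moderate/
    supporting, benign levels stand_alone/strong/supporting, the 20 combining
    rules of the 2015 publication (18 threshold rows plus the two
    uncertain-significance rows), and five ordered conclusions. Deterministic
    and identical across calls.
    """
    global _default_cache
    if _default_cache is None:
        data = json.loads(
            resources.files("patheval").joinpath("guidelines", _DEFAULT_RESOURCE).read_text()
        )
        _default_cache = _parse_bundle(data, f"packaged:{_DEFAULT_RESOURCE}")
    return _default_cache


def packaged_guideline_path() -> Path:
    """Filesystem path of the shipped default configuration."""
    return Path(str(resources.files("patheval").joinpath("guidelines", _DEFAULT_RESOURCE)))
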