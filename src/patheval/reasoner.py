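"""The reasoning engine: evidence tags -> conclusion with full provenance.

An evidence *tag* is one evidence code asserted for a variant, applied either
at the code's default strength or at a re-weighted strength within the same
direction (the framework's professional-judgment flexibility: ``PVS1`` applied
at Strong is written ``PVS1_Strong``). Combining rules see only *counts* of
tags per (direction, strength) cell, so re-weighted tags participate in the
ordinary rules with no rule duplication.

Classification proceeds in two stages:

1. every threshold rule is evaluated against the strength profile, recording
   a term-by-term account (required vs observed counts, contributing tags);
2. the metarule policy resolves the satisfied rules: satisfied rules in both
   directions yield the conflict conclusion (uncertain significance from
   *conflicting* evidence); several satisfied same-direction conclusions are
   resolved by precedence (Pathogenic over Likely Pathogenic, Benign over
   Likely Benign); no satisfied rule yields the insufficiency conclusion
   (uncertain significance from *insufficient* evidence).

``classify`` is a deterministic pure function of (tags, guideline) and is
invariant under tag reordering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .guideline import CombiningRule, EvidenceCode, Guideline, StrengthLevel

VusFlavor = Literal["not_applicable", "insufficient_evidence", "conflicting_evidence"]


class TagValidationError(Exception):
    """One or more tags are invalid under the guideline; lists every problem."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid evidence tags:\n" + "\n".join(f"  - {p}" for p in problems))


class Link(BaseModel):
    model_config = ConfigDict(extra="allow", frozen=True)
    url: str
    comment: Optional[str] = None


class EvidenceTag(BaseModel):
    """One applied evidence code, optionally re-weighted, with support links."""

    model_config = ConfigDict(extra="allow", frozen=True)

    code: str
    strength: Optional[str] = None  # level_id within the code's direction; None = default
    summary: Optional[str] = None
    links: tuple[Link, ...] = ()


@dataclass(frozen=True)
class ResolvedTag:
    tag: EvidenceTag
    code: EvidenceCode
    applied_strength: StrengthLevel

    @property
    def display_name(self) -> str:
        if self.applied_strength.level_id == self.code.default_strength:
            return self.code.code_id
        suffix = re.sub(r"[^A-Za-z0-9]+", "_", self.applied_strength.label or self.applied_strength.level_id)
        return f"{self.code.code_id}_{suffix}"

    @property
    def cell(self) -> tuple[str, str]:
        return (self.code.direction, self.applied_strength.level_id)


def _normalize_level_token(token: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", token.lower()).strip("_")


def _match_level(g: Guideline, direction: str, token: str) -> Optional[StrengthLevel]:
    wanted = _normalize_level_token(token)
    for lv in g.levels_for(direction):
        if wanted in {_normalize_level_token(lv.level_id), _normalize_level_token(lv.label)}:
            return lv
    return None


def parse_tag_token(token: str, g: Guideline) -> EvidenceTag:
    """Parse ``CODE`` or ``CODE_LEVEL`` (case-insensitive, ``-`` accepted).

    Examples under the default guideline: ``PS1``, ``pvs1_strong``,
    ``PP1_Very-Strong``. Raises :class:`TagValidationError` naming the token
    when the code or level is unknown.
    """
    token = token.strip()
    if not token:
        raise TagValidationError(["empty tag token"])
    if g.code(token) is not None:
        return EvidenceTag(code=g.code(token).code_id)
    m = re.match(r"^([A-Za-z0-9]+)[_-](.+)$", token)
    if m and g.code(m.group(1)) is not None:
        code = g.code(m.group(1))
        level = _match_level(g, code.direction, m.group(2))
        if level is None:
            raise TagValidationError([
                f"tag {token!r}: {m.group(2)!r} is not a {code.direction}-direction "
                f"strength level of guideline {g.guideline_id!r}"])
        return EvidenceTag(code=code.code_id, strength=level.level_id)
    raise TagValidationError([f"unknown evidence code in tag token {token!r} "
                              f"under guideline {g.guideline_id!r}"])


def parse_tag_list(spec: str, g: Guideline) -> list[EvidenceTag]:
    """Parse a comma-separated tag list such as ``PS1,PS2,PM1_Supporting``."""
    tokens = [t for t in (s.strip() for s in spec.split(",")) if t]
    tags, problems = [], []
    for token in tokens:
        try:
            tags.append(parse_tag_token(token, g))
        except TagValidationError as exc:
            problems.extend(exc.problems)
    if problems:
        raise TagValidationError(problems)
    return tags


def resolve_tags(tags: Sequence[EvidenceTag], g: Guideline) -> list[ResolvedTag]:
    """Validate tags against the guideline, collecting every problem.

    Enforces: known code; known applied strength of the code's own direction
    (a code may change strength, never direction); one tag per base code.
    """
    problems: list[str] = []
    resolved: list[ResolvedTag] = []
    seen: set[str] = set()
    for t in tags:
        code = g.code(t.code)
        if code is None:
            problems.append(f"unknown evidence code {t.code!r} under guideline {g.guideline_id!r}")
            continue
        if code.code_id.upper() in seen:
            problems.append(f"evidence code {code.code_id} applied more than once; "
                            "one code may be applied once, at one strength")
            continue
        seen.add(code.code_id.upper())
        level_id = t.strength or code.default_strength
        level = g.level(code.direction, level_id)
        if level is None:
            problems.append(
                f"tag {code.code_id}: applied strength {level_id!r} is not a "
                f"{code.direction}-direction level (strength may shift, direction may not)")
            continue
        resolved.append(ResolvedTag(tag=t, code=code, applied_strength=level))
    if problems:
        raise TagValidationError(problems)
    return resolved


# ---------------------------------------------------------------------------
# Strength profiles and rule evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrengthProfile:
    """Counts of applied tags per (direction, level_id) grid column."""

    counts: dict[tuple[str, str], int]

    def count(self, direction: str, level_id: str) -> int:
        return self.counts.get((direction, level_id), 0)

    def direction_total(self, direction: str) -> int:
        return sum(n for (d, _), n in self.counts.items() if d == direction)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def strength_profile(tags: Sequence[EvidenceTag], g: Guideline) -> StrengthProfile:
    """Tally applied strengths per direction; rejects duplicate base codes."""
    counts: dict[tuple[str, str], int] = {}
    for rt in resolve_tags(tags, g):
        counts[rt.cell] = counts.get(rt.cell, 0) + 1
    return StrengthProfile(counts)


@dataclass(frozen=True)
class TermAccount:
    direction: str
    strength: str
    required_min: int
    required_max: Optional[int]
    observed: int
    holds: bool
    tags: tuple[str, ...] = ()  # display names of contributing tags

    def to_dict(self) -> dict:
        return {
            "direction": self.direction, "strength": self.strength,
            "required_min": self.required_min, "required_max": self.required_max,
            "observed": self.observed, "holds": self.holds, "tags": list(self.tags),
        }


@dataclass(frozen=True)
class RuleAccount:
    rule_id: str
    conclusion: str
    satisfied: bool
    terms: tuple[TermAccount, ...]
    direction: Optional[str]

    def to_dict(self) -> dict:
        return {"rule_id": self.rule_id, "conclusion": self.conclusion,
                "satisfied": self.satisfied, "direction": self.direction,
                "terms": [t.to_dict() for t in self.terms]}


def evaluate_rule(rule: CombiningRule, profile: StrengthProfile,
                  bindings: Optional[dict[tuple[str, str], tuple[str, ...]]] = None) -> RuleAccount:
    """Evaluate one threshold rule, recording required vs observed per term."""
    accounts = []
    satisfied = rule.kind == "threshold" and bool(rule.terms)
    for term in rule.terms:
        observed = profile.count(term.direction, term.strength)
        holds = observed >= term.min_count and (term.max_count is None or observed <= term.max_count)
        satisfied = satisfied and holds
        accounts.append(TermAccount(
            direction=term.direction, strength=term.strength,
            required_min=term.min_count, required_max=term.max_count,
            observed=observed, holds=holds,
            tags=(bindings or {}).get((term.direction, term.strength), ()),
        ))
    return RuleAccount(rule_id=rule.rule_id, conclusion=rule.conclusion,
                       satisfied=satisfied, terms=tuple(accounts), direction=rule.direction)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Classification:
    """The reasoner's output: conclusion plus complete provenance.

    ``satisfied_rules`` holds the satisfied threshold rules with per-term tag
    bindings; recomputing the conclusion from these and the metarule policy
    alone reproduces ``conclusion``. ``metarule`` names the resolution that
    fired (``precedence``, ``conflict`` or ``insufficient``) and
    ``fired_rule_id`` the guideline rule recorded for the two
    uncertain-significance causes, when the guideline declares them.
    """

    conclusion: str
    vus_flavor: VusFlavor
    satisfied_rules: tuple[RuleAccount, ...]
    candidate_conclusions: tuple[str, ...]
    profile: StrengthProfile
    rule_accounts: tuple[RuleAccount, ...]
    metarule: str
    fired_rule_id: Optional[str] = None
    tags: tuple[ResolvedTag, ...] = ()

    def to_dict(self) -> dict:
        return {
            "conclusion": self.conclusion,
            "vus_flavor": self.vus_flavor,
            "candidate_conclusions": list(self.candidate_conclusions),
            "metarule": self.metarule,
            "fired_rule_id": self.fired_rule_id,
            "satisfied_rules": [r.to_dict() for r in self.satisfied_rules],
            "profile": {f"{d}:{s}": n for (d, s), n in sorted(self.profile.counts.items())},
            "tags": [rt.display_name for rt in self.tags],
        }


def _precedence_pick(conclusions: set[str], g: Guideline) -> str:
    for token in g.metarules.precedence:
        if token in conclusions:
            return token
    for token in g.conclusions:  # fallback for conclusions outside the precedence list
        if token in conclusions:
            return token
    return sorted(conclusions)[0]


def _special_rule_id(g: Guideline, kind: str, policy_field: Optional[str]) -> Optional[str]:
    if policy_field is not None:
        return policy_field
    for r in g.rules:
        if r.kind == kind:
            return r.rule_id
    return None


def classify_profile(profile: StrengthProfile, g: Guideline,
                     bindings: Optional[dict[tuple[str, str], tuple[str, ...]]] = None,
                     tags: tuple[ResolvedTag, ...] = ()) -> Classification:
    """Classify a strength profile (the counting substrate of ``classify``)."""
    accounts = tuple(evaluate_rule(r, profile, bindings) for r in g.threshold_rules())
    satisfied = tuple(a for a in accounts if a.satisfied)
    sat_by_dir = {d: [a for a in satisfied if a.direction == d] for d in ("pathogenic", "benign")}

    order = {c: i for i, c in enumerate(g.metarules.precedence)}
    candidates = tuple(sorted({a.conclusion for a in satisfied},
                              key=lambda c: (order.get(c, len(order)), c)))

    policy = g.metarules
    if policy.conflict_scope == "rule":
        conflicted = bool(sat_by_dir["pathogenic"]) and bool(sat_by_dir["benign"])
    else:  # tag scope: applied evidence in both directions is itself a conflict
        conflicted = profile.direction_total("pathogenic") > 0 and profile.direction_total("benign") > 0

    if conflicted:
        conclusion, flavor, metarule = policy.conflict_conclusion, "conflicting_evidence", "conflict"
        fired = _special_rule_id(g, "directional_conflict", policy.conflict_rule)
    elif satisfied:
        conclusion = _precedence_pick({a.conclusion for a in satisfied}, g)
        flavor, metarule, fired = "not_applicable", "precedence", None
    else:
        conclusion, flavor, metarule = policy.insufficient_conclusion, "insufficient_evidence", "insufficient"
        fired = _special_rule_id(g, "no_rule_fallback", policy.insufficient_rule)

    return Classification(
        conclusion=conclusion, vus_flavor=flavor, satisfied_rules=satisfied,
        candidate_conclusions=candidates, profile=profile, rule_accounts=accounts,
        metarule=metarule, fired_rule_id=fired, tags=tags)


def classify(tags: Sequence[EvidenceTag], g: Guideline) -> Classification:
    """Classify a set of evidence tags under a guideline.

    Deterministic pure function of (tags, guideline); invariant under tag
    reordering. Raises :class:`TagValidationError` for invalid tags.
    """
    resolved = tuple(sorted(resolve_tags(tags, g), key=lambda rt: rt.display_name))
    counts: dict[tuple[str, str], int] = {}
    bindings: dict[tuple[str, str], list[str]] = {}
    for rt in resolved:
        counts[rt.cell] = counts.get(rt.cell, 0) + 1
        bindings.setdefault(rt.cell, []).append(rt.display_name)
    frozen = {cell: tuple(names) for cell, names in bindings.items()}
    return classify_profile(StrengthProfile(counts), g, bindings=frozen, tags=resolved)
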