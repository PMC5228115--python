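"""Near-miss conclusion search: what minimal extra evidence changes the call.

For each conclusion other than the current one, find the smallest multiset of
*additional* hypothetical tags — represented as (direction, strength) grid
cells, since the combining rules only see counts — whose addition to the
current tag set reaches that conclusion, and enumerate all distinct minimal
witnesses. Only additions are searched (evidence "turned on"), never removal
or re-weighting of existing tags.

A witness is only offered when it is actionable: each required cell must have
enough *unapplied* codes whose default grid column is that cell. Witnesses
that would trip the conflict metarule (yielding uncertain significance
instead of the target) are naturally excluded because candidates are checked
with the full classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Optional, Sequence

from .guideline import Guideline
from .reasoner import (EvidenceTag, StrengthProfile, classify_profile,
                       resolve_tags)

Cell = tuple[str, str]  # (direction, level_id)


@dataclass(frozen=True)
class Suggestion:
    """One reachable (or blocked) alternate conclusion.

    ``witness_cells`` lists every distinct minimal multiset of additional
    (direction, level_id) cells reaching the target; all have length
    ``distance``. ``blocked`` marks targets unreachable within the search
    bound, in which case ``distance`` is None and no witnesses are given.
    """

    target_conclusion: str
    distance: Optional[int]
    witness_cells: tuple[tuple[Cell, ...], ...]
    blocked: bool
    applied_codes: tuple[str, ...] = ()  # base codes of the originating tag set

    def to_dict(self) -> dict:
        return {
            "target_conclusion": self.target_conclusion,
            "distance": self.distance,
            "blocked": self.blocked,
            "witnesses": [[f"{d}:{s}" for d, s in w] for w in self.witness_cells],
        }


def unapplied_cell_availability(applied_codes: Sequence[str], g: Guideline) -> dict[Cell, int]:
    """Unapplied codes per default grid column (direction, level)."""
    applied = {c.upper() for c in applied_codes}
    avail: dict[Cell, int] = {}
    for code in g.codes:
        if code.code_id.upper() not in applied:
            cell = (code.direction, code.default_strength)
            avail[cell] = avail.get(cell, 0) + 1
    return avail


def _augment(profile: StrengthProfile, witness: Sequence[Cell]) -> StrengthProfile:
    counts = dict(profile.counts)
    for cell in witness:
        counts[cell] = counts.get(cell, 0) + 1
    return StrengthProfile(counts)


def near_conclusions(tags: Sequence[EvidenceTag], g: Guideline,
                     max_distance: int = 4) -> list[Suggestion]:
    """One Suggestion per non-current conclusion, sorted by distance.

    The search enumerates cell multisets of size 1..``max_distance`` in
    increasing size; for each target the first size with a witness is its
    distance and *all* witnesses of that size are returned. Ties are ordered
    by the guideline's conclusion list.
    """
    resolved = resolve_tags(tags, g)
    profile = StrengthProfile({})
    counts: dict[Cell, int] = {}
    for rt in resolved:
        counts[rt.cell] = counts.get(rt.cell, 0) + 1
    profile = StrengthProfile(counts)

    applied = tuple(sorted(rt.code.code_id for rt in resolved))
    avail = unapplied_cell_availability(applied, g)
    current = classify_profile(profile, g).conclusion

    cells = sorted(avail)  # only cells with at least one unapplied code
    found: dict[str, tuple[int, list[tuple[Cell, ...]]]] = {}
    targets = [c for c in g.conclusions if c != current]

    for size in range(1, max_distance + 1):
        if all(t in found for t in targets):
            break
        for witness in combinations_with_replacement(cells, size):
            ok = True
            for cell in set(witness):
                if witness.count(cell) > avail[cell]:
                    ok = False
                    break
            if not ok:
                continue
            outcome = classify_profile(_augment(profile, witness), g).conclusion
            if outcome == current:
                continue
            if outcome in found and found[outcome][0] < size:
                continue
            found.setdefault(outcome, (size, []))[1].append(witness)

    order = {c: i for i, c in enumerate(g.conclusions)}
    suggestions = []
    for target in targets:
        if target in found:
            distance, witnesses = found[target]
            suggestions.append(Suggestion(
                target_conclusion=target, distance=distance,
                witness_cells=tuple(sorted(set(witnesses))), blocked=False,
                applied_codes=applied))
        else:
            suggestions.append(Suggestion(
                target_conclusion=target, distance=None, witness_cells=(),
                blocked=True, applied_codes=applied))
    suggestions.sort(key=lambda s: (s.distance if s.distance is not None else float("inf"),
                                    order.get(s.target_conclusion, len(order))))
    return suggestions


@dataclass(frozen=True)
class GapCell:
    """One witness cell mapped back onto the evidence grid."""

    direction: str
    level_id: str
    level_label: str
    needed: int  # maximum multiplicity of this cell over the witnesses
    codes: tuple[tuple[str, str], ...]  # (code_id, evidence-type row label), unapplied

    def to_dict(self) -> dict:
        return {"direction": self.direction, "strength": self.level_id,
                "label": self.level_label, "needed": self.needed,
                "codes": [{"code": c, "evidence_type": t} for c, t in self.codes]}


@dataclass(frozen=True)
class GapReport:
    target_conclusion: str
    blocked: bool
    cells: tuple[GapCell, ...]

    def to_dict(self) -> dict:
        return {"target_conclusion": self.target_conclusion, "blocked": self.blocked,
                "cells": [c.to_dict() for c in self.cells]}


def explain_gap(s: Suggestion, g: Guideline) -> GapReport:
    """Map a suggestion's witness cells to grid columns and unapplied codes.

    For each cell appearing in any minimal witness, lists the concrete
    unapplied codes whose default grid column is that cell, with their
    evidence-type rows — i.e. what evidence could be sought. Blocked
    suggestions yield an empty cell mapping.
    """
    if s.blocked:
        return GapReport(target_conclusion=s.target_conclusion, blocked=True, cells=())
    applied = {c.upper() for c in s.applied_codes}
    needed: dict[Cell, int] = {}
    for witness in s.witness_cells:
        for cell in set(witness):
            needed[cell] = max(needed.get(cell, 0), witness.count(cell))
    cells = []
    for (direction, level_id), n in sorted(needed.items()):
        level = g.level(direction, level_id)
        codes = tuple(
            (c.code_id, (g.evidence_type(c.evidence_type).label if g.evidence_type(c.evidence_type) else c.evidence_type))
            for c in sorted(g.codes, key=lambda c: c.code_id)
            if c.direction == direction and c.default_strength == level_id
            and c.code_id.upper() not in applied)
        cells.append(GapCell(direction=direction, level_id=level_id,
                             level_label=level.label if level else level_id,
                             needed=n, codes=codes))
    return GapReport(target_conclusion=s.target_conclusion, blocked=False, cells=tuple(cells))


def materialize_witness(witness: Sequence[Cell], applied_codes: Sequence[str],
                        g: Guideline) -> list[EvidenceTag]:
    """Turn a witness cell multiset into concrete hypothetical tags.

    Draws unapplied codes whose default column matches each cell (smallest
    code id first); raises ValueError if the witness is infeasible.
    """
    applied = {c.upper() for c in applied_codes}
    tags: list[EvidenceTag] = []
    for cell in witness:
        direction, level_id = cell
        pool = [c for c in sorted(g.codes, key=lambda c: c.code_id)
                if c.direction == direction and c.default_strength == level_id
                and c.code_id.upper() not in applied]
        if not pool:
            raise ValueError(f"no unapplied code available for cell {cell}")
        code = pool[0]
        applied.add(code.code_id.upper())
        tags.append(EvidenceTag(code=code.code_id))
    return tags
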