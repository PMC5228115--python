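"""Fixture generation and independent oracles.

Everything here exists so the engine's behaviour can be checked without any
external data: seeded random tag sets, an exhaustive strength-profile
enumerator, deliberately discordant multi-laboratory document sets, batch
tables with planted stated-conclusion mismatches, and a naive oracle
classifier.

The oracle is interpretive: it works from the guideline's plain document
form (``model_dump``) by direct term arithmetic and a literal reading of the
metarule policy, sharing no compiled rule structures or evaluation code with
the main reasoner. Independence is the point — agreement between the two
over the exhaustive profile sweep is the package's central correctness test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import product
from typing import Iterator, Sequence, Union

from .assessment import BatchRow, EvidenceDocument
from .guideline import Guideline
from .reasoner import EvidenceTag, StrengthProfile, classify


# ---------------------------------------------------------------------------
# Random tag sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagSetSpec:
    """Recipe for a reproducible random tag set.

    ``n_tags`` is a fixed count or an inclusive (low, high) range;
    ``direction_mix`` is the probability that a tag is drawn from the benign
    side; ``strength_modification_rate`` the probability that a tag's
    strength is re-weighted to a random level of its code's direction.
    """

    seed: int
    n_tags: Union[int, tuple[int, int]] = (0, 6)
    direction_mix: float = 0.3
    strength_modification_rate: float = 0.15


def random_tagset(spec: TagSetSpec, g: Guideline) -> list[EvidenceTag]:
    """Sample a valid tag set: codes without replacement, strengths in-direction.

    Reproducible for a fixed spec; raises ValueError if more tags are
    requested than the guideline has codes.
    """
    rng = random.Random(spec.seed)
    n = spec.n_tags if isinstance(spec.n_tags, int) else rng.randint(*spec.n_tags)
    if n > len(g.codes):
        raise ValueError(f"requested {n} tags but guideline defines only {len(g.codes)} codes")
    pools = {
        "pathogenic": sorted(c.code_id for c in g.codes if c.direction == "pathogenic"),
        "benign": sorted(c.code_id for c in g.codes if c.direction == "benign"),
    }
    tags: list[EvidenceTag] = []
    for _ in range(n):
        direction = "benign" if rng.random() < spec.direction_mix else "pathogenic"
        if not pools[direction]:
            direction = "pathogenic" if direction == "benign" else "benign"
        code_id = pools[direction].pop(rng.randrange(len(pools[direction])))
        strength = None
        if rng.random() < spec.strength_modification_rate:
            strength = rng.choice([lv.level_id for lv in g.levels_for(direction)])
        tags.append(EvidenceTag(code=code_id, strength=strength))
    return tags


# ---------------------------------------------------------------------------
# Exhaustive profile enumeration
# ---------------------------------------------------------------------------

def enumerate_profiles(g: Guideline, max_count: int) -> Iterator[StrengthProfile]:
    """Yield every profile with each per-level count in 0..max_count, once."""
    cells = [(lv.direction, lv.level_id) for lv in g.strength_levels]
    for combo in product(range(max_count + 1), repeat=len(cells)):
        yield StrengthProfile({cell: n for cell, n in zip(cells, combo) if n})


# ---------------------------------------------------------------------------
# The naive oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleClassification:
    conclusion: str
    vus_flavor: str
    satisfied_rule_ids: tuple[str, ...]


_doc_cache: dict[int, dict] = {}


def _guideline_doc(g: Guideline) -> dict:
    """Plain document form of the guideline (cached per instance)."""
    key = id(g)
    if key not in _doc_cache:
        _doc_cache.clear()  # keep at most one entry; guidelines are few and reused
        _doc_cache[key] = g.model_dump(mode="json")
    return _doc_cache[key]


def oracle_classify_counts(counts: dict[tuple[str, str], int], g: Guideline) -> OracleClassification:
    """Literal re-evaluation of the guideline documents on a counts mapping."""
    doc = _guideline_doc(g)

    satisfied = []
    directions = set()
    for rule in doc["rules"]:
        if rule["kind"] != "threshold":
            continue
        ok = True
        for term in rule["terms"]:
            n = counts.get((term["direction"], term["strength"]), 0)
            if n < term["min_count"]:
                ok = False
            if term["max_count"] is not None and n > term["max_count"]:
                ok = False
        if ok:
            satisfied.append(rule)
            directions.add(rule["terms"][0]["direction"])

    meta = doc["metarules"]
    if meta["conflict_scope"] == "tag":
        has = {d for (d, _), n in counts.items() if n > 0}
        conflict = {"pathogenic", "benign"} <= has
    else:
        conflict = {"pathogenic", "benign"} <= directions

    if conflict:
        return OracleClassification(meta["conflict_conclusion"], "conflicting_evidence",
                                    tuple(r["rule_id"] for r in satisfied))
    if satisfied:
        reached = {r["conclusion"] for r in satisfied}
        for token in list(meta["precedence"]) + list(doc["conclusions"]):
            if token in reached:
                return OracleClassification(token, "not_applicable",
                                            tuple(r["rule_id"] for r in satisfied))
    return OracleClassification(meta["insufficient_conclusion"], "insufficient_evidence", ())


def oracle_classify(tags: Sequence[EvidenceTag], g: Guideline) -> OracleClassification:
    """Naive classification of a tag set, independent of the main reasoner.

    Counts tags per (direction, applied strength) straight from the code
    documents, then delegates to :func:`oracle_classify_counts`.
    """
    doc = _guideline_doc(g)
    codes = {c["code_id"].upper(): c for c in doc["codes"]}
    counts: dict[tuple[str, str], int] = {}
    seen = set()
    for tag in tags:
        code = codes[tag.code.upper()]
        if code["code_id"] in seen:
            raise ValueError(f"duplicate code {code['code_id']}")
        seen.add(code["code_id"])
        cell = (code["direction"], tag.strength or code["default_strength"])
        counts[cell] = counts.get(cell, 0) + 1
    return oracle_classify_counts(counts, g)


# ---------------------------------------------------------------------------
# Document and batch fixtures
# ---------------------------------------------------------------------------

def _allele_id(i: int) -> str:
    return f"CA{900000 + i:06d}"


def verification_batch(g: Guideline, seed: int, n_rows: int = 353,
                       n_mismatches: int = 16) -> list[BatchRow]:
    """A batch of (allele, tags, stated) rows with planted mismatches.

    Each row's stated conclusion is the computed one, except ``n_mismatches``
    rows whose stated conclusion is deliberately shifted to a different
    guideline conclusion — emulating submissions whose listed evidence codes
    do not support the conclusion provided.
    """
    rng = random.Random(seed)
    mismatch_rows = set(rng.sample(range(n_rows), n_mismatches))
    rows = []
    for i in range(n_rows):
        tags = random_tagset(TagSetSpec(seed=rng.randrange(2**31), n_tags=(0, 7)), g)
        computed = classify(tags, g).conclusion
        stated = computed
        if i in mismatch_rows:
            stated = rng.choice([c for c in g.conclusions if c != computed])
        spec = ",".join(sorted(t.code if t.strength is None else f"{t.code}_{t.strength}"
                               for t in tags))
        rows.append(BatchRow(allele_id=_allele_id(i), tags_spec=spec, stated_conclusion=stated))
    return rows


def write_batch(rows: Sequence[BatchRow], path) -> None:
    """Write batch rows as TSV (the bulk-upload table format)."""
    lines = ["allele_id\ttags\tstated_conclusion"]
    for r in rows:
        lines.append(f"{r.allele_id}\t{r.tags_spec}\t{r.stated_conclusion or ''}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def discordant_document_set(g: Guideline, seed: int, n_alleles: int = 4,
                            n_labs: int = 2) -> list[EvidenceDocument]:
    """Multi-laboratory assessments of shared alleles, some discordant.

    For each allele, the first laboratory's tag set is random; each further
    laboratory perturbs it (dropping or adding a code), so some allele groups
    end up with divergent computed conclusions — exercising concordance
    comparison the way a proficiency challenge would.
    """
    rng = random.Random(seed)
    docs = []
    for i in range(n_alleles):
        allele = _allele_id(i)
        base = random_tagset(TagSetSpec(seed=rng.randrange(2**31), n_tags=(1, 6)), g)
        for lab in range(n_labs):
            tags = list(base)
            if lab > 0 and rng.random() < 0.75:
                if tags and rng.random() < 0.5:
                    tags.pop(rng.randrange(len(tags)))
                else:
                    used = {t.code.upper() for t in tags}
                    pool = sorted(c.code_id for c in g.codes if c.code_id.upper() not in used)
                    if pool:
                        tags.append(EvidenceTag(code=rng.choice(pool)))
            stated = classify(tags, g).conclusion
            docs.append(EvidenceDocument(
                allele=allele, condition="synthetic condition",
                mode_of_inheritance="autosomal dominant",
                guideline=g.guideline_id, tags=tuple(tags),
                stated_conclusion=stated, curator=f"lab-{chr(ord('A') + lab)}"))
    return docs
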