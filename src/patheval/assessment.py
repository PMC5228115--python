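"""Evidence documents: serialization, verification, comparison, reports.

An *evidence document* is the complete assessment record for one variant
under one guideline: the allele identifier (a registry key such as
``CA021883`` and/or an HGVS expression, treated as an opaque string), the
condition and mode of inheritance, the applied evidence tags with free-text
summaries and supporting links, and optionally the conclusion stated by the
submitting laboratory. Documents deliberately carry no patient-identifying
fields.

Three operations sit on top of the document model:

* ``verify_assessment`` recomputes the conclusion from the tags and flags
  documents whose stated conclusion the listed evidence codes do not support
  — discordance is reported, the stated value is never overwritten (a
  deliberate professional-judgment override looks the same as an error and
  is for a human to adjudicate);
* ``compare_assessments`` groups documents by allele and reports discordant
  groups with pairwise tag differences, as in proficiency-challenge and
  multi-laboratory concordance evaluations;
* ``generate_report`` renders one comprehensive, deterministic report (plain
  text or markdown) with the conclusion, rule-level provenance, the populated
  evidence grid, per-tag support, and near-miss suggestions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .guideline import Guideline, default_acmg_guideline, load_guideline
from .reasoner import (Classification, EvidenceTag, classify, resolve_tags)
from .suggest import near_conclusions


class DocumentError(Exception):
    """An assessment document fails schema or reference checks."""


class Timestamps(BaseModel):
    model_config = ConfigDict(extra="allow", frozen=True)
    created: Optional[str] = None
    modified: Optional[str] = None


class EvidenceDocument(BaseModel):
    """One complete assessment record for one variant under one guideline."""

    model_config = ConfigDict(extra="allow", frozen=True, populate_by_name=True)

    allele_id: str = Field(alias="allele")
    condition: str = ""
    mode_of_inheritance: str = ""
    guideline_id: str = Field(alias="guideline", default="acmg_amp_2015")
    tags: tuple[EvidenceTag, ...] = ()
    stated_conclusion: Optional[str] = None
    curator: Optional[str] = None
    timestamps: Optional[Timestamps] = None


def read_document(path: str | Path) -> EvidenceDocument:
    """Read a JSON (or YAML) assessment document.

    Schema violations raise :class:`DocumentError` listing every offending
    field; tag/guideline resolution happens at operation time.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise DocumentError(f"cannot read assessment document {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text) if path.suffix.lower() in {".yaml", ".yml"} else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise DocumentError(f"assessment document {path} is not parseable: {exc}") from exc
    try:
        return EvidenceDocument.model_validate(data)
    except ValidationError as exc:
        raise DocumentError(f"assessment document {path} violates the schema:\n{exc}") from exc


def write_document(doc: EvidenceDocument, path: str | Path) -> None:
    """Write a document as JSON; read∘write is identity, unknown fields kept."""
    data = doc.model_dump(mode="json", by_alias=True, exclude_none=True)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def document_guideline(doc: EvidenceDocument) -> Guideline:
    """Resolve the document's guideline reference: packaged id or a path."""
    gid = doc.guideline_id
    default = default_acmg_guideline()
    if gid in {default.guideline_id, "default", ""}:
        return default
    if Path(gid).exists():
        return load_guideline(gid)
    raise DocumentError(
        f"document for allele {doc.allele_id!r} cites guideline {gid!r}, "
        "which is neither the packaged guideline nor a readable path")


def validate_document(doc: EvidenceDocument, g: Guideline) -> list[str]:
    """Semantic checks of a document against its guideline; problems as data."""
    problems: list[str] = []
    try:
        resolve_tags(doc.tags, g)
    except Exception as exc:  # TagValidationError carries per-tag problems
        problems.extend(getattr(exc, "problems", [str(exc)]))
    if doc.stated_conclusion is not None and doc.stated_conclusion not in g.conclusions:
        problems.append(f"stated conclusion {doc.stated_conclusion!r} is not one of "
                        f"the guideline's conclusions {list(g.conclusions)}")
    return problems


# ---------------------------------------------------------------------------
# Verification: stated vs computed
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerificationResult:
    status: Literal["concordant", "discordant"]
    computed: Classification
    stated: str
    note: Literal["rule_supported", "not_supported"]

    def to_dict(self) -> dict:
        return {"status": self.status, "stated": self.stated,
                "computed": self.computed.conclusion, "note": self.note,
                "vus_flavor": self.computed.vus_flavor}


def verify_assessment(doc: EvidenceDocument, g: Guideline) -> VerificationResult:
    """Check whether the listed evidence codes support the stated conclusion."""
    if doc.stated_conclusion is None:
        raise DocumentError(
            f"document for allele {doc.allele_id!r} carries no stated conclusion to verify")
    computed = classify(doc.tags, g)
    concordant = computed.conclusion == doc.stated_conclusion
    return VerificationResult(
        status="concordant" if concordant else "discordant",
        computed=computed, stated=doc.stated_conclusion,
        note="rule_supported" if concordant else "not_supported")


# ---------------------------------------------------------------------------
# Multi-assessment comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagDiff:
    first: str   # curator label (or positional label) of the first document
    second: str
    only_in_first: tuple[str, ...]
    only_in_second: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"first": self.first, "second": self.second,
                "only_in_first": list(self.only_in_first),
                "only_in_second": list(self.only_in_second)}


@dataclass(frozen=True)
class AlleleGroup:
    allele_id: str
    documents: tuple[EvidenceDocument, ...]
    classifications: tuple[Classification, ...]
    discordant: bool
    tag_diffs: tuple[TagDiff, ...]

    def to_dict(self) -> dict:
        return {"allele_id": self.allele_id,
                "n_documents": len(self.documents),
                "conclusions": [c.conclusion for c in self.classifications],
                "discordant": self.discordant,
                "tag_diffs": [d.to_dict() for d in self.tag_diffs]}


@dataclass(frozen=True)
class ConcordanceReport:
    groups: tuple[AlleleGroup, ...]
    concordance_fraction: Optional[float]  # None when no allele has >=2 documents

    @property
    def discordant_groups(self) -> tuple[AlleleGroup, ...]:
        return tuple(gr for gr in self.groups if gr.discordant)

    def to_dict(self) -> dict:
        return {"concordance_fraction": self.concordance_fraction,
                "groups": [gr.to_dict() for gr in self.groups]}


def _doc_label(doc: EvidenceDocument, index: int) -> str:
    return doc.curator or f"document-{index + 1}"


def compare_assessments(docs: Sequence[EvidenceDocument], g: Guideline) -> ConcordanceReport:
    """Group documents by exact allele id, flag discordant groups, diff tags.

    A group is discordant when its computed conclusions are not all
    identical. The overall concordance fraction is taken over groups with at
    least two documents; invariant under document reordering.
    """
    if not docs:
        raise DocumentError("compare_assessments requires at least one document")
    by_allele: dict[str, list[EvidenceDocument]] = {}
    for doc in docs:
        by_allele.setdefault(doc.allele_id, []).append(doc)

    groups = []
    multi = concordant_multi = 0
    for allele_id in sorted(by_allele):
        group_docs = sorted(by_allele[allele_id],
                            key=lambda d: (_doc_label(d, 0) if d.curator else "",
                                           tuple(sorted(t.code for t in d.tags))))
        classifications = tuple(classify(d.tags, g) for d in group_docs)
        conclusions = {c.conclusion for c in classifications}
        discordant = len(conclusions) > 1
        diffs = []
        if discordant:
            names = [{rt.display_name for rt in resolve_tags(d.tags, g)} for d in group_docs]
            for i in range(len(group_docs)):
                for j in range(i + 1, len(group_docs)):
                    diffs.append(TagDiff(
                        first=_doc_label(group_docs[i], i),
                        second=_doc_label(group_docs[j], j),
                        only_in_first=tuple(sorted(names[i] - names[j])),
                        only_in_second=tuple(sorted(names[j] - names[i]))))
        groups.append(AlleleGroup(allele_id=allele_id, documents=tuple(group_docs),
                                  classifications=classifications,
                                  discordant=discordant, tag_diffs=tuple(diffs)))
        if len(group_docs) >= 2:
            multi += 1
            concordant_multi += 0 if discordant else 1

    fraction = concordant_multi / multi if multi else None
    return ConcordanceReport(groups=tuple(groups), concordance_fraction=fraction)


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

def _grid_columns(g: Guideline) -> list[tuple[str, str, str]]:
    """(direction, level_id, header) columns: pathogenic then benign, strongest first."""
    cols = []
    for direction in ("pathogenic", "benign"):
        for lv in g.levels_for(direction):
            side = "P" if direction == "pathogenic" else "B"
            cols.append((direction, lv.level_id, f"{side}:{lv.label or lv.level_id}"))
    return cols


def _report_sections(doc: EvidenceDocument, g: Guideline, max_distance: int = 4):
    """Shared content assembly for both renderings (deterministic)."""
    computed = classify(doc.tags, g)
    suggestions = near_conclusions(doc.tags, g, max_distance=max_distance)
    resolved = computed.tags
    columns = _grid_columns(g)
    grid: dict[tuple[str, str, str], list[str]] = {}
    for rt in resolved:
        key = (rt.code.evidence_type, *rt.cell)
        grid.setdefault(key, []).append(rt.display_name)
    return computed, suggestions, resolved, columns, grid


def generate_report(doc: EvidenceDocument, g: Guideline,
                    fmt: Literal["text", "markdown"] = "text",
                    max_distance: int = 4) -> str:
    """Render one comprehensive assessment report.

    Sections, in order: allele identification; computed conclusion (with the
    uncertain-significance cause when applicable); satisfied rules with
    term-by-term accounts; the evidence grid with applied tags in their
    cells; per-tag summaries and links; near-miss suggestions; guideline
    identity. Output is byte-identical across runs for identical input; any
    timestamps shown are the document's own.
    """
    computed, suggestions, resolved, columns, grid = _report_sections(doc, g, max_distance)
    md = fmt == "markdown"
    lines: list[str] = []

    def heading(text: str) -> None:
        if md:
            lines.append(f"## {text}")
        else:
            lines.append(text)
            lines.append("-" * len(text))
        lines.append("")

    title = f"Variant pathogenicity assessment: {doc.allele_id}"
    lines.append(f"# {title}" if md else title.upper())
    lines.append("")

    heading("Allele")
    for label, value in (("Allele", doc.allele_id), ("Condition", doc.condition or "(not given)"),
                         ("Mode of inheritance", doc.mode_of_inheritance or "(not given)"),
                         ("Curator", doc.curator or "(not given)")):
        lines.append(f"- {label}: {value}" if md else f"  {label}: {value}")
    ts = doc.timestamps
    if ts and (ts.created or ts.modified):
        stamp = f"created {ts.created or '?'} / modified {ts.modified or '?'}"
        lines.append(f"- Timestamps: {stamp}" if md else f"  Timestamps: {stamp}")
    lines.append("")

    heading("Conclusion")
    conclusion = computed.conclusion
    if computed.vus_flavor == "insufficient_evidence":
        conclusion += " (insufficient evidence)"
    elif computed.vus_flavor == "conflicting_evidence":
        conclusion += " (conflicting evidence)"
    lines.append(f"**{conclusion}**" if md else f"  {conclusion}")
    if doc.stated_conclusion is not None:
        lines.append(f"- Stated by submitter: {doc.stated_conclusion}" if md
                     else f"  Stated by submitter: {doc.stated_conclusion}")
    lines.append("")

    heading("Satisfied rules")
    if not computed.satisfied_rules:
        lines.append("  (no combining rule satisfied)" if not md else "(no combining rule satisfied)")
    for rule in computed.satisfied_rules:
        lines.append(f"- **{rule.rule_id}** -> {rule.conclusion}" if md
                     else f"  {rule.rule_id} -> {rule.conclusion}")
        for term in rule.terms:
            bound = f">={term.required_min}" if term.required_max is None \
                else f"{term.required_min}-{term.required_max}"
            tag_list = f" [{', '.join(term.tags)}]" if term.tags else ""
            text = (f"{term.direction} {term.strength}: required {bound}, "
                    f"observed {term.observed}{tag_list}")
            lines.append(f"  - {text}" if md else f"      {text}")
    lines.append("")

    heading("Evidence grid")
    types = list(g.evidence_types)
    header = ["Evidence type"] + [c[2] for c in columns]
    rows = []
    for et in types:
        row = [et.label]
        for direction, level_id, _ in columns:
            names = grid.get((et.type_id, direction, level_id), [])
            row.append(", ".join(sorted(names)) if names else ("" if md else "."))
        rows.append(row)
    if md:
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join(["---"] * len(header)) + "|")
        for row in rows:
            lines.append("| " + " | ".join(row) + " |")
    else:
        widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
        lines.append("  " + "  ".join(h.ljust(w) for h, w in zip(header, widths)))
        for row in rows:
            lines.append("  " + "  ".join(c.ljust(w) for c, w in zip(row, widths)))
    lines.append("")

    heading("Evidence tags")
    if not resolved:
        lines.append("(none applied)" if md else "  (none applied)")
    for rt in resolved:
        lines.append(f"- **{rt.display_name}** ({rt.code.direction} {rt.applied_strength.label})"
                     if md else f"  {rt.display_name} ({rt.code.direction} {rt.applied_strength.label})")
        if rt.tag.summary:
            lines.append(f"  - Summary: {rt.tag.summary}" if md else f"      Summary: {rt.tag.summary}")
        for link in rt.tag.links:
            note = f" ({link.comment})" if link.comment else ""
            lines.append(f"  - Link: {link.url}{note}" if md else f"      Link: {link.url}{note}")
    lines.append("")

    heading("Conclusions within reach")
    reachable = [s for s in suggestions if not s.blocked]
    if not reachable:
        lines.append("(none within the search bound)" if md else "  (none within the search bound)")
    for s in reachable:
        witnesses = "; ".join(
            " + ".join(f"{d}:{lv}" for d, lv in w) for w in s.witness_cells)
        text = f"{s.target_conclusion}: {s.distance} additional tag(s) — {witnesses}"
        lines.append(f"- {text}" if md else f"  {text}")
    lines.append("")

    heading("Guideline")
    gl = f"{g.meta.id} version {g.meta.version} — {g.meta.name}".rstrip(" —")
    lines.append(f"- {gl}" if md else f"  {gl}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Batch tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatchRow:
    allele_id: str
    tags_spec: str
    stated_conclusion: Optional[str]


@dataclass(frozen=True)
class BatchRowResult:
    allele_id: str
    tags_spec: str
    status: str  # concordant | discordant | error
    stated: Optional[str]
    computed: Optional[str]
    detail: str = ""

    def to_dict(self) -> dict:
        return {"allele_id": self.allele_id, "tags": self.tags_spec,
                "status": self.status, "stated": self.stated,
                "computed": self.computed, "detail": self.detail}


def read_batch(path: str | Path) -> list[BatchRow]:
    """Read a TSV/CSV batch of (allele_id, tags, stated_conclusion) rows."""
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = {"allele_id", "tags"}
    missing = required - set(df.columns)
    if missing:
        raise DocumentError(f"batch table {path} is missing column(s): {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        stated = rec.get("stated_conclusion", "") or None
        rows.append(BatchRow(allele_id=str(rec["allele_id"]),
                             tags_spec=str(rec["tags"]), stated_conclusion=stated))
    return rows


def verify_batch(rows: Sequence[BatchRow], g: Guideline) -> tuple[list[BatchRowResult], dict]:
    """Verify every batch row; rows with unparseable tags are counted as errors
    and the run continues. Returns (per-row results, summary counts)."""
    from .reasoner import TagValidationError, parse_tag_list

    results = []
    for row in rows:
        try:
            tags = parse_tag_list(row.tags_spec, g)
            if row.stated_conclusion is None:
                raise DocumentError(f"row for allele {row.allele_id!r} has no stated conclusion")
            if row.stated_conclusion not in g.conclusions:
                raise DocumentError(
                    f"stated conclusion {row.stated_conclusion!r} is not a guideline conclusion")
            computed = classify(tags, g)
            status = "concordant" if computed.conclusion == row.stated_conclusion else "discordant"
            results.append(BatchRowResult(
                allele_id=row.allele_id, tags_spec=row.tags_spec, status=status,
                stated=row.stated_conclusion, computed=computed.conclusion))
        except (TagValidationError, DocumentError) as exc:
            results.append(BatchRowResult(
                allele_id=row.allele_id, tags_spec=row.tags_spec, status="error",
                stated=row.stated_conclusion, computed=None, detail=str(exc)))
    n = len(results)
    concordant = sum(r.status == "concordant" for r in results)
    discordant = sum(r.status == "discordant" for r in results)
    errors = sum(r.status == "error" for r in results)
    checked = concordant + discordant
    summary = {"n": n, "concordant": concordant, "discordant": discordant,
               "errors": errors,
               "discordance_fraction": (discordant / checked) if checked else None}
    return results, summary
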