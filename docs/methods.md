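# Methods

## The classification procedure

`patheval` treats a semi-quantitative variant-interpretation guideline as a
formal object with four parts: an ordered conclusion list; a set of strength
levels per direction (pathogenic, benign), each with a rank; a set of
evidence codes, each assigned to exactly one evidence-grid cell (evidence
type × default strength); and a set of combining rules plus a metarule
policy. Classification of a tag set proceeds deterministically:

1. **Resolution.** Each tag is resolved against the guideline: the code must
   exist (ids compare case-insensitively and are stored uppercase), the
   applied strength must be a level of the code's own direction (strength
   may be re-weighted up or down, direction never changes), and each base
   code may be applied at most once. All violations are collected and
   reported together; duplicates are rejected loudly rather than
   deduplicated, since a code applied twice is almost certainly a
   data-entry error.
2. **Profiling.** Tags are tallied into a strength profile
   *n*(direction, level). Rules never see code identities — this is what
   lets a re-weighted tag such as `PVS1_Strong` participate in the ordinary
   "≥2 Strong" rule with no rule duplication.
3. **Rule evaluation.** Every threshold rule is evaluated as a conjunction
   of interval terms `min ≤ n(direction, level) ≤ max` (max unbounded
   unless the source table prints a range, e.g. "1–2 Moderate"). Each
   evaluation records a term-by-term account of required versus observed
   counts and the contributing tags, whether or not the rule is satisfied.
4. **Metarule resolution.** If satisfied rules exist in both directions,
   the conflict conclusion is emitted with the `conflicting_evidence`
   flavor. Otherwise, among satisfied conclusions the precedence list picks
   the strongest (Pathogenic over Likely Pathogenic; Benign over Likely
   Benign). If nothing is satisfied, the insufficiency conclusion is
   emitted with the `insufficient_evidence` flavor. The two uncertainty
   causes are an attribute of the result, not extra conclusion tokens: the
   conclusion list stays at the published five.

### Design choices where the design was open

- **The 20-rule count.** The published combining table has 18 threshold
  rows plus two Uncertain Significance rows ("criteria not met";
  "pathogenic and benign contradictory"). Those two are genuine rules of
  the system but are not expressible as count thresholds, so they are
  shipped as `CombiningRule` records of kind `no_rule_fallback` and
  `directional_conflict` with empty term lists; the metarule policy
  references them by id so that uncertainty outcomes carry rule-level
  provenance like every other conclusion.
- **Conflict is rule-level, not tag-level.** A lone benign-supporting tag
  beside a satisfied Pathogenic rule does not force uncertainty; conflict
  means conflicting *derivable conclusions*. The stricter tag-level reading
  (any evidence in both directions conflicts) is available as the metarule
  option `conflict_scope: tag`.
- **Opposing evidence with no satisfied rule** (e.g. one PP plus one BP) is
  reported as insufficient, not conflicting: no conclusions conflict when
  none is derivable. The bidirectional tags remain visible in the profile
  and rule accounts.
- **BA1 stand-alone** is an ordinary one-term benign rule (≥1 Stand-Alone),
  keeping the rule schema uniform rather than special-casing it.
- **Re-weighting is unrestricted within a direction**, including upgrades
  (e.g. PP1 applied at Strong for extended segregation data), mirroring the
  framework's provision that criteria may be moved between weights by
  professional judgment.

## Near-miss search

Because rules see only counts, the search for conclusions "a few tags away"
runs over multisets of (direction, level) cells rather than concrete codes.
For each conclusion other than the current one, multisets of additional
cells are enumerated in increasing size (default bound 4, the deepest
supporting-count any shipped rule requires); the first size that reaches
the target under the full classifier — metarules included, so witnesses
that would trip the conflict metarule are excluded automatically — is the
distance, and *all* witnesses of that size are returned. A witness is only
offered if each of its cells has enough unapplied codes whose default grid
column is that cell (a suggestion requiring seven Moderate tags when only
six PM codes exist, one already applied, is unactionable). `explain_gap`
maps witness cells back to the grid and lists the concrete unapplied codes,
i.e. what evidence could be sought. Only additions are searched; removing
or re-weighting existing evidence is a curatorial act, not a gap.

Targets unreachable within the bound are reported as blocked with no
distance. Reaching Uncertain Significance *by adding opposing evidence* is
a legitimate suggestion (it tells a curator how fragile the current call
is) and falls out of the same search.

## Verification and comparison

`verify_assessment` recomputes the conclusion from a document's tags and
compares it with the conclusion stated by the submitter. Discordance is
reported, never repaired: a mismatch may be an error or a deliberate
professional-judgment override, and distinguishing the two is a human
decision, so the stated value is preserved alongside the computed one.
`compare_assessments` groups documents by exact allele-id string (allele
canonicalization across nomenclatures is a registry's job, out of scope
here), flags groups with more than one distinct computed conclusion, and
reports pairwise symmetric differences of applied tag names. The overall
concordance fraction is taken over groups with at least two documents and
is undefined (reported as n/a) when there are none.

Reports are rendered from document content only — any timestamps shown are
caller-supplied fields, never the wall clock — so regenerating a report
yields identical bytes.

## Synthetic data and the oracle

The test fixtures are tag-level only; nothing simulates real variants,
population frequencies or assay read-outs. `random_tagset` draws codes
without replacement (default 0–6 tags per set, 30 % benign direction, 15 %
re-weighted — a mix chosen to exercise every rule family and both metarule
branches, including conflicts, at realistic assessment sizes), so passing
tests demonstrate the correctness of the reasoning, not the realism of any
evidence-generating process. `verification_batch` plants stated-conclusion
mismatches by shifting the stated value of chosen rows to a different
conclusion, emulating submissions whose listed codes do not support the
stated call; `discordant_document_set` perturbs a shared tag set across
synthetic laboratories to produce genuinely discordant allele groups.

The oracle classifier is deliberately naive and structurally independent:
it works from the guideline's plain document form by direct term
arithmetic and a literal reading of the metarule policy, sharing no parsed
rule objects or evaluation code with the engine. The central correctness
test sweeps every strength profile with per-level counts 0–4 — 5⁷ = 78 125
profiles, chosen because no shipped rule term requires more than 4 of any
level, so higher counts cannot change which side of any threshold a profile
sits on — and requires exact agreement of conclusion and uncertainty
flavor. The suggestion audit checks 1000 seeded tag sets: every witness,
materialized as concrete unapplied codes, must reach its target under the
engine, and brute-force enumeration of all smaller feasible multisets via
the oracle must find none that does.

## Numerical and degenerate-input conventions

There is no floating-point numerics; all evaluation is integer counting.
Ties among satisfied same-direction rules are resolved purely by the
precedence list, never by rule order. Empty tag sets are valid input
(insufficient evidence). Guideline validation returns *every* violation as
data (dangling references, duplicate ids, unsatisfiable `min > max` terms,
conclusions no rule or metarule can produce) rather than failing at the
first; loading refuses to return a partially valid guideline.

## Known limitations

- Down-weighting monotonicity (lowering one tag's strength never
  strengthens the conclusion) holds on profiles with at most one
  very-strong tag. With two or more — constructible only by upgrading a
  second code to Very Strong — the published table fires no rule until one
  of them is down-weighted to Strong, because it has no "≥2 Very Strong"
  row. The engine reproduces the table faithfully rather than inventing
  such a row; curators upgrading a second code to Very Strong should expect
  an insufficient-evidence result unless other rules apply.
- Allele grouping is exact string match; two documents describing the same
  allele under different HGVS expressions are separate groups unless a
  shared registry id is used.
- The rule schema expresses conjunctions of count intervals. Quantitative
  (e.g. Bayesian) guideline variants are out of scope beyond what that
  schema can encode.
- Evidence tags are asserted by the user; the package performs no evidence
  gathering or annotation lookup.
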