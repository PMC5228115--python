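# patheval

A configurable rule engine for classifying the pathogenicity of Mendelian
germline sequence variants from asserted evidence, in the style of the
ACMG/AMP 2015 framework. It is aimed at variant curators, clinical
laboratories and curation-tool developers who want the combining logic of a
classification guideline to be explicit, checkable and scriptable rather
than applied by hand.

## The model

A guideline is a formal rule system over *evidence tags*:

- **Evidence codes** (28 in the shipped ACMG/AMP 2015 configuration: PVS1,
  PS1–PS4, PM1–PM6, PP1–PP5, BA1, BS1–BS4, BP1–BP7) each occupy one cell of
  an **evidence grid** — rows are evidence types (Population Data,
  Functional Data, …), columns are strength levels for or against
  pathogenicity (Very Strong / Strong / Moderate / Supporting on the
  pathogenic side; Stand-Alone / Strong / Supporting on the benign side).
- A **tag** applies one code at an effective strength. Professional
  judgment may re-weight a tag within its direction: `PVS1_Strong` is the
  same evidence as PVS1 counted at Strong. Rules see only the resulting
  counts *n*(direction, strength), so re-weighted tags need no extra rules.
- **Combining rules** are conjunctions of threshold terms, e.g. Pathogenic
  if *n*(P, Strong) ≥ 2, or Likely Pathogenic if *n*(P, Strong) ≥ 1 and
  1 ≤ *n*(P, Moderate) ≤ 2. The shipped configuration carries the 20 rows
  of the published combining table (8 Pathogenic, 6 Likely Pathogenic,
  2 Benign, 2 Likely Benign, plus the two Uncertain Significance rows).
- **Metarules** resolve the satisfied rules: satisfied rules in both
  directions give Uncertain Significance from *conflicting* evidence;
  several same-direction conclusions resolve by precedence (Pathogenic over
  Likely Pathogenic, Benign over Likely Benign); no satisfied rule gives
  Uncertain Significance from *insufficient* evidence.

On top of classification the package verifies stated conclusions against
the evidence ("do the listed codes support the call?"), compares multiple
assessments of the same allele for discordance, searches for conclusions a
few tags away (with the minimal additional evidence needed and where it
lives in the grid), and renders deterministic assessment reports. All of it
is configurable: a guideline is three structured documents (rules and
metarules; codes; grid), so gene- or disease-specific variants — down to
novel evidence types such as metabolite levels — are data, not code.

## Worked example

```text
$ patheval classify --tags PS1,PS2,PM1,PM2,PM3
Pathogenic
Satisfied rules:
  pathogenic_2strong -> Pathogenic
  pathogenic_strong_3moderate -> Pathogenic
  likely_pathogenic_3moderate -> Likely Pathogenic
Within reach: Uncertain Significance distance=1 (benign:stand_alone)
```

Two strong plus three moderate pathogenic tags satisfy both a Pathogenic
rule (≥2 Strong) and a Likely Pathogenic rule (≥3 Moderate); the precedence
metarule scores the variant Pathogenic, and the full derivation is printed.
The last line notes that a single stand-alone benign observation (BA1, high
population frequency) would create a rule-level conflict and drop the call
to Uncertain Significance.

```text
$ patheval suggest --tags PVS1
conclusion               distance  witnesses
Pathogenic               1         pathogenic:strong
Likely Pathogenic        1         pathogenic:moderate
Benign                   1         benign:stand_alone
Likely Benign            2         benign:strong + benign:supporting; benign:supporting + benign:supporting
```

A lone very-strong tag satisfies no rule (Uncertain Significance,
insufficient evidence); the search shows every minimal multiset of
additional evidence that reaches each other conclusion — one moderate tag
(any of PM1–PM6) would make it Likely Pathogenic.

The same operations are importable (`patheval.classify`,
`patheval.near_conclusions`, `patheval.verify_assessment`, …), and
`patheval verify --batch table.tsv` checks whole submission tables at once.

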