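# Methods

This note documents the models, conventions and numerical choices behind
`trialsql`: what each component computes, the parameters that matter, what
the synthetic data does and does not emulate, and the known limitations.

## Scope and data model

The toolkit targets a fixed subset of OMOP CDM v5.3, shipped as a JSON
catalog (`src/trialsql/assets/cdm_catalog.json`): the `person` table, seven
domain event tables (`condition_occurrence`, `drug_exposure`,
`procedure_occurrence`, `measurement`, `observation`, `device_exposure`,
`visit_occurrence`), and the vocabulary tables `concept` and
`concept_ancestor`. The catalog is static and versioned — no live DDL
introspection — so schema validation is reproducible. It can be overridden
with `--cdm-catalog`. Era, cost and payer tables are out of scope.

Each clinical domain maps to exactly one (event table, concept column, date
column, optional value column) rule. Demographic criteria are the exception:
OMOP has no demographic event table, so they map to `person`
(`year_of_birth`, `gender_concept_id`), and age criteria render as an
age-at-index-date comparison `(index_year − year_of_birth) ⋈ N`. The index
date defaults to 2023-12-31 and is configurable; using a fixed reference
date rather than "today" keeps query text and test results stable.

## Preprocessing pipeline

**Tokenizer.** All stage statistics use one token measure: punctuation is
isolated into separate tokens, then the text is split on whitespace
(`re.findall(r"\w+|[^\w\s]")`). This is a documented proxy — absolute token
counts depend on the tokenizer, so only *relative* quantities (the percent
reduction `100 × (1 − final/initial)`) are meaningful across tokenizers.

**Segmentation** emits one criterion per bulleted/numbered/lettered item.
A line ending in a colon becomes a parent context; lettered sub-items
(`a)`, `b)`, inline or on their own lines) inherit it as a prefix.
Numbered or dash bullets reset the context. Boolean connectors (AND/OR)
are never split — they stay verbatim inside the criterion so downstream
logic can see them. A block with no structure passes through unchanged.

**Filtration** flags criteria with no CDM footprint using an explicit,
user-extensible rule list keyed by reason code: `consent`, `willingness`
(compliance), `investigator_judgment`, `contraception`, `co_enrollment`.
These are trial-administrative criteria a database cannot answer. The list
is deliberately a small, documented superset of the canonical consent
example; extend it by passing a `{reason: regex}` mapping.

**Simplification** applies an ordered rewrite table: parentheticals
removed; number words → digits; temporal phrases ("within the past six
months") → comparator form ("≤ 6 months"); comparator phrases ("greater
than or equal to") → symbols; age phrasing ("18 years or older") →
"≥ 18 years"; content-free lead-ins ("patients must have …") dropped. A
guard rejects any rewrite that would *increase* the token count, so token
monotonicity across stages holds by construction, and the rules are
idempotent: already-normalized text is a fixed point.

**Element extraction** fills a seven-slot record: clinical terms,
terminology system (SNOMED CT / ICD-10 / RxNorm / LOINC, detected by
mention), codes, value constraint (comparator, number, unit), attributes
(severity/chronicity adjectives), temporal constraint (quantity, unit,
anchor), and negation. Disambiguation convention: a comparator+number+
time-unit phrase is a *temporal* constraint unless "age" precedes it, in
which case it is a *value* (so "age ≥ 18 years" is a value on age, while
"stroke ≤ 6 months" is a recency window). Negation uses a fixed cue list
("no history of", "without", "excluding", "absence of", "no evidence of").

**Backends.** Every stage calls a `BackendContract` — `(name,
transform(task, json) → json, deterministic)` — so an LLM adapter can be
substituted per stage. The shipped default is the deterministic rule
backend above; a scripted mock (exact input → scripted output, erroring on
unscripted input) supports testing adapter plumbing. All backend outputs
pass a pydantic schema gate before use; malformed output raises rather than
propagating. Production LLM adapters are intentionally not included: the
package's claims are about the pipeline, audit and metrics, which must be
reproducible offline.

## Concept mapping baseline

The baseline mapper emulates the OHDSI USAGI approach: normalize (lowercase,
strip punctuation, collapse whitespace), score candidates by normalized
Levenshtein similarity `1 − d(a, b)/max(|a|, |b|)` (edit distance computed
with edlib; a pure-Python dynamic-programming oracle cross-checks it in
tests), sort descending, break ties toward the lower concept ID. It is a
documented approximation used as an internal comparator — no claim of
bit-compatibility with USAGI, whose exact normalization and cutoffs are not
public in citable form.

## SQL assembly

Per-criterion subqueries select exactly one column (`person_id`). Concept
sets expand through the precomputed ancestor closure; expansion defaults on
for Condition and Drug (where missing descendants are the classic cause of
silently incomplete cohorts) and off for other domains, overridable per
criterion. Temporal windows render as precomputed ISO date cutoffs —
month = 30 days, year = 365 days, documented rather than calendar-exact —
so the emitted SQL contains no engine-specific date arithmetic and runs on
the embedded sqlite engine used in tests. Inclusions merge with
`INTERSECT`; exclusions chain as `EXCEPT` terms or rewrite to
`person_id NOT IN (union of exclusions)`. Both modes are set-identical by
relational algebra, and tests verify this on every fixture. Negated
inclusions route to the exclusion arm (absence-of-X ≡ exclude has-X);
negated *exclusions* are ambiguous in intent and are flagged for manual
review instead of being double-negated silently.

## Hallucination audit

A lightweight SQL lexer (not a full grammar) locates literals compared
against concept-ID columns (`=`, `IN (...)`, `BETWEEN`) and table/column
identifiers. A full parser is deliberately avoided: broken generator output
contains placeholder tokens (`?`, `:name`, `<ANGLE>`, `{curly}`) and
truncations that real SQL parsers reject outright, and the auditor must
*classify* such text, not refuse it. The structural `parse_check`
(lexability, SELECT/WITH head, balanced parentheses, FROM targets) decides
"generated SQL" vs "generation failure"; only the former is audited.

Classification precedence is **D → C → A → B**: placeholder, then
non-integer literal, then nonexistent ID, then wrong domain. The order is
forced — a placeholder is also non-numeric, and a non-numeric literal has
no ID to look up — and makes classification a total function assigning at
most one category per site. Schema validation supplies category E
(unknown table/column, non-key joins), with matching case-insensitive and
quote-stripping. When a referenced table is unknown, column resolution is
suppressed in that statement so one misspelled table yields one violation,
not a cascade.

Three hallucination policies are reportable, because "hallucinated" is used
inconsistently across published evaluations: `default` counts categories
A–D (schema errors tracked separately), `strict` counts only A (the
literal "invalid concept IDs" definition), `broad` counts A–E. Category
distributions are tallied per *instance* (site), not per query, matching
the convention of model-comparison tables. The effective-SQL rate is
`generation rate × (1 − hallucination rate)`; published model-level tables
computed with live LLMs are internally inconsistent with that formula (e.g.
88.4 × (1 − 0.211) = 69.8, not 75.8), so the toolkit implements the stated
definition and desk-scale reproduction targets only the arithmetic that is
self-consistent.

## Evaluation statistics

- **Proportions**: Wald 95% interval `p ± 1.96·√(p(1−p)/n)` clipped to
  [0, 1], as the default (it reproduces the published 29.4–36.1% interval
  for 249/760); Wilson available behind a flag as the better-behaved
  option at extreme p.
- **McNemar**: uncorrected `χ² = (|b−c|)²/(b+c)` on the discordant cells
  with df = 1 by default; continuity-corrected and exact-binomial variants
  selectable (the published comparison is significant under all three).
  Cross-checked against `statsmodels` in tests.
- **Paired mapping table**: from published marginals 173/357, 114/357 and
  61 rescues, the 2×2 table is uniquely (112, 61, 2, 182). Rescue rate =
  `sys1_only/(sys1_only + both_wrong)`. Per-domain strata are treated as
  independent counts (whether they partition the full term set is not
  documented).
- **Concordance**: Jaccard `|A∩B|/|A∪B|` and overlap
  `|A∩B|/min(|A|,|B|)`; when either cohort is empty both metrics are 0 by
  convention (with a warning), matching the reporting convention for a
  failed retrieval. Jaccard ≤ overlap for all nonempty pairs.
- **Rater agreement**: item score = mean of the two raters on the 1–4
  scale; Cohen's κ unweighted over the 4 levels (weighting is a choice the
  source evaluations do not specify). The degenerate all-identical-constant
  case is defined as κ = 1.

## Synthetic data: what it emulates, and what it does not

The vocabulary generator reproduces the *limited-coverage* situation that
makes hallucinations detectable: a loadable inventory sampled from a larger
universe (defaults: 10,000-concept universe, 10% loaded — the same ~1.3%
coverage regime as a claims dataset exposing ~27k of >2M concepts, at desk
scale). Concept hierarchies are per-domain rooted trees (depth 3, branching
≤ 3); the loaded inventory's ancestor relation is the universe closure
restricted to loaded endpoints, which preserves transitivity. Domain
weights follow the empirical mix of concepts extracted from real trial
criteria (≈49.5% Condition, 15.4% Drug, …).

Error injection produces labeled positives: per site, category A swaps in a
universe∖loaded ID (a *real-looking* but unloadable concept — the actual
mechanism behind coverage-induced hallucinations), B a loaded ID of the
wrong domain, C the concept's own name as a quoted string, D a placeholder
token, E a corrupted table name (query-level, at most once). One injection
per site keeps the manifest↔audit comparison exact. The central correctness
property — audit recovers 100% of injected labels with zero false positives
across seeds — is *by construction* the detector's correctness surface: it
shows the detector implements its specification exactly, not that it would
catch every failure mode of a live LLM.

The mini-CDM (default 500 persons; tests use 200–300) draws events per
concept as independent Bernoulli trials and logs the draws, so cohort
execution has a ground-truth oracle independent of SQL. It makes no claim
of clinical realism: no comorbidity structure, visit patterns, missingness,
coding variation or temporal consistency. Passing tests therefore
demonstrate *mechanical* correctness of assembly, execution and auditing —
not retrieval quality on real EHR data, which published validations show is
limited by concept-hierarchy coverage and unit handling, not by query
mechanics.

## Problem sizes

Test fixtures use a 1,000-concept universe (100 loaded) and a 200-person
CDM; the acceptance script uses a 2,000-concept universe, a 300-person CDM,
10 × 100 injected queries and 1,000 random set pairs. These sizes were
chosen so the whole suite runs in seconds while keeping every combinatorial
regime exercised (multi-site queries, all five categories, both assembly
modes, empty and full event rates).

## Known limitations

- The SQL lexer handles the SELECT-based cohort dialect the toolkit emits
  and the mutilations generators produce; it is not a general SQL
  validator (no CTE scope tracking, no expression grammar).
- Bare-word column checking is heuristic in multi-table statements;
  qualified references are exact.
- Month/year temporal arithmetic is 30/365-day approximate by design.
- The rule backend's extraction quality is bounded by its pattern tables;
  it is a deterministic floor, not a ceiling — the backend contract exists
  precisely so stronger extractors can be plugged in and audited with the
  same machinery.
- The baseline mapper is lexical; semantically correct but lexically
  distant mappings (the known failure class of edit-distance mappers) are
  out of reach by design, which is exactly the gap the audit quantifies
  for any stronger candidate system.
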