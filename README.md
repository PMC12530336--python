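# trialsql

Clinical-trial feasibility assessment starts with a tedious manual step:
translating the free-text inclusion/exclusion criteria of a trial protocol
into database queries over real-world data. `trialsql` is an offline toolkit
for that path targeting the OMOP Common Data Model (CDM v5.3): it
preprocesses eligibility criteria, extracts their structured elements, maps
clinical terms to standardized vocabulary concepts, assembles executable
cohort SQL — and, critically, **audits any candidate SQL for concept-ID
hallucinations**, the failure mode that makes LLM-generated queries unsafe
to trust.

It is aimed at clinical research informaticians who want to (1) generate
OMOP cohort queries from criteria text with a deterministic, inspectable
rule pipeline (or plug in their own text-model backend), and (2) measure how
often a generator — human or model — emits invalid concept references.

## What it does

**Preprocessing pipeline.** Criteria blocks go through segmentation (one
criterion per bullet/clause, nested items inheriting parent context),
filtration (dropping non-queryable administrative criteria: consent,
willingness/compliance, investigator judgment, contraception agreements,
co-enrollment), and simplification (normalizing temporal and comparator
phrasing, e.g. *"history of MI within the past six months"* → *"history of
MI ≤ 6 months"*). Token counts fall monotonically across stages. Seven
structured elements are then extracted per criterion: clinical terms,
terminology system, codes, value constraint, attributes, temporal
constraint, and negation.

**Concept mapping.** A USAGI-style baseline mapper ranks inventory concepts
by normalized Levenshtein similarity, `1 − d(a,b)/max(|a|,|b|)` after
lowercasing, punctuation stripping and whitespace collapsing, with
deterministic low-concept-id tie-breaking.

**SQL assembly.** Each criterion renders as
`SELECT person_id FROM <event table> WHERE <concept column> IN (...)` with
descendant expansion through `concept_ancestor` (default on for Condition
and Drug), value predicates on `value_as_number`, and date cutoffs relative
to a configurable index date. Inclusions merge with `INTERSECT`; exclusions
apply via `EXCEPT` or an equivalent `NOT IN` rewrite. Negated inclusions
("no history of X") are routed to the exclusion arm.

**Hallucination audit.** Every literal compared against a `*_concept_id`
column is classified by fixed precedence into: **A** (Critical) nonexistent
concept ID, **B** (Major) valid concept in the wrong domain's column, **C**
(Major) natural language in a concept field, **D** (Moderate) placeholder
token, **E** (Minor) schema/syntax errors. Headline statistics follow:
hallucination rate with a Wald 95% CI, and the *effective SQL rate* =
generation rate × (1 − hallucination rate).

**Evaluation metrics.** Paired-system mapping accuracy and McNemar's test
on the discordant cells (χ² = (|b−c|)²/(b+c), exact-binomial option), cohort
concordance (Jaccard = |A∩B|/|A∪B|, overlap = |A∩B|/min(|A|,|B|)), and
dual-rater 4-point score aggregation with Cohen's κ.

**Synthetic data.** Generators for a limited-coverage vocabulary (a loadable
inventory inside a larger concept universe — the situation that makes
hallucinations observable and labelable), a mini patient-level CDM
executable through sqlite, seeded hallucination injection with a
ground-truth manifest, and cohort pairs hitting a target Jaccard index.

## Worked example

Build a cohort query for a toy trial against a 4-concept inventory
(`concept.csv` / `ancestor.csv` in OMOP CONCEPT/CONCEPT_ANCESTOR layout,
where concept 1002 is a descendant of 1001):

```bash
trialsql build --in trial.json --concepts concept.csv --ancestors ancestor.csv
```

with `trial.json`:

```json
{"trial_id": "NCT-DEMO",
 "inclusion": "1. Type 2 diabetes mellitus\n2. Provided written informed consent",
 "exclusion": "1. Pregnancy"}
```

prints:

```sql
SELECT person_id FROM condition_occurrence WHERE condition_concept_id IN (1001, 1002)
EXCEPT
SELECT person_id FROM condition_occurrence WHERE condition_concept_id IN (2001)
```

The consent criterion was filtered out as non-queryable; "Type 2 diabetes
mellitus" mapped to concept 1001 and expanded to its descendant 1002; the
exclusion became an `EXCEPT` arm. Auditing a query with a placeholder
(`... WHERE condition_concept_id = ?`) flags one category-D instance;
summary statistics come from `trialsql report`:

```bash
trialsql report --rate 249 760 --mcnemar 112 61 2 182
```

```json
{
  "rate": {"percent": 32.8, "ci95_percent": [29.4, 36.1]},
  "mcnemar": {"statistic": 55.25, "p_value": 1.0592025360668376e-13},
  "accuracy": {"sys1_percent": 48.5, "sys2_percent": 31.9}
}
```

i.e. 249 hallucinated queries out of 760 attempts is a 32.8% rate (95% CI
29.4–36.1%), and a mapping comparison with 61 vs 2 discordant successes is
decisively one-sided (χ² = 55.25, p < .001).

## Layout

```
src/trialsql/
  cdm_schema.py        # embedded CDM v5.3 subset catalog + SQL schema validation
  vocabulary.py        # concept inventory, ancestor closure, baseline mapper
  criteria_pipeline.py # segmentation/filtration/simplification + extraction
  sql_builder.py       # criterion subqueries and cohort assembly
  audit.py             # hallucination detection and A-E classification
  metrics.py           # rates, CIs, McNemar, concordance, rater agreement
  synth.py             # synthetic vocabulary/CDM/injection/cohort generators
  cli.py               # `trialsql` command group
docs/methods.md        # models, parameters, conventions, limitations
```
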