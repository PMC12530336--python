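"""Automated concept-hallucination detection and five-category classification.

Candidate SQL is scanned for literals compared against concept-ID columns;
each site is classified by a fixed precedence into one of five categories:

* **A (Critical)** — nonexistent concept ID (absent from the inventory),
* **B (Major)** — valid concept assigned to the wrong domain's column,
* **C (Major)** — natural language where an identifier belongs,
* **D (Moderate)** — placeholder token requiring manual substitution,
* **E (Minor)** — syntax/schema errors (unknown tables or columns).

Precedence is D → C → A → B: a placeholder is also non-numeric and a
non-numeric literal cannot be looked up, so the specific check must fire
before the general one; every site receives at most one category.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import _sql
from .cdm_schema import CdmCatalog, DomainRule, default_catalog, validate_identifiers
from .errors import SqlParseError
from .vocabulary import ConceptInventory

SEVERITY = {"A": "Critical", "B": "Major", "C": "Major", "D": "Moderate", "E": "Minor"}

#: which categories make a query count as hallucinated, by policy name
POLICIES = {
    "default": frozenset("ABCD"),  # concept-level errors; schema errors tracked separately
    "strict": frozenset("A"),      # only invalid concept IDs
    "broad": frozenset("ABCDE"),
}

#: placeholder token shapes; user-extensible via classify_site(patterns=...)
PLACEHOLDER_PATTERNS: tuple[re.Pattern, ...] = (
    re.compile(r"^\?$"),
    re.compile(r"^:\w+$"),
    re.compile(r"^<[^>]*>$"),
    re.compile(r"^\{[^}]*\}$"),
    re.compile(r"^[A-Z][A-Z0-9_]*_ID_HERE$"),
    re.compile(r"^[A-Z0-9_]*PLACEHOLDER[A-Z0-9_]*$"),
)

_INTEGER = re.compile(r"^\d+$")


@dataclass(frozen=True)
class ConceptRefSite:
    """One literal compared against a concept-ID column."""

    table: str | None
    column: str
    literal: str  # verbatim token, including quoting/placeholder markers
    position: int


@dataclass(frozen=True)
class HallucinationInstance:
    site: ConceptRefSite
    category: str  # A–E
    severity: str
    explanation: str


@dataclass
class QueryAudit:
    sql: str
    parse_ok: bool
    instances: list[HallucinationInstance] = field(default_factory=list)
    schema_violations: list = field(default_factory=list)
    hallucinated: bool = False
    effective: bool = False
    policy: str = "default"
    group: str | None = None

    @property
    def categories(self) -> list[str]:
        return sorted(i.category for i in self.instances)


def extract_concept_refs(sql: str, catalog: CdmCatalog | None = None) -> list[ConceptRefSite]:
    """Locate every literal compared against a ``*_concept_id`` column.

    Handles ``= literal``, ``IN (list)`` and ``BETWEEN a AND b`` forms.
    Raises :class:`SqlParseError` if the text fails the structural check
    (a generation failure, handled upstream by :func:`audit_query`).
    """
    catalog = catalog or default_catalog()
    ok, reason = _sql.parse_check(sql)
    if not ok:
        raise SqlParseError(reason)
    tokens = _sql.tokenize(sql)
    table_tokens, aliases = _sql.table_references(tokens)
    scope_tables = [t.value.lower() for t in table_tokens]
    concept_cols = catalog.concept_columns

    sites: list[ConceptRefSite] = []
    n = len(tokens)
    literal_kinds = (_sql.NUMBER, _sql.STRING, _sql.PLACEHOLDER, _sql.IDENT, _sql.QIDENT)

    def resolve_table(idx: int) -> str | None:
        prv = tokens[idx - 1] if idx > 0 else None
        if prv is not None and prv.text == "." and idx >= 2:
            qual = tokens[idx - 2].value.lower()
            return aliases.get(qual, qual)
        owners = [t for t in scope_tables
                  if tokens[idx].value.lower() in
                  {c.lower() for c in catalog.columns_by_table.get(t, [])}]
        if len(owners) == 1:
            return owners[0]
        # fall back to the nearest preceding FROM/JOIN table
        best = None
        for t in table_tokens:
            if t.pos < tokens[idx].pos:
                best = t.value.lower()
        return best

    def is_literal(tok: _sql.Token) -> bool:
        return tok.kind in literal_kinds and not (
            tok.kind == _sql.IDENT and tok.value in _sql.KEYWORDS
        )

    for idx, tok in enumerate(tokens):
        if tok.kind != _sql.IDENT or tok.value.lower() not in concept_cols:
            continue
        column = tok.value.lower()
        table = resolve_table(idx)
        j = idx + 1
        if j >= n:
            continue
        op = tokens[j]
        if op.text in ("=", "!=", "<>"):
            if j + 1 < n and is_literal(tokens[j + 1]):
                lit = tokens[j + 1]
                sites.append(ConceptRefSite(table, column, lit.text, lit.pos))
        elif op.kind == _sql.IDENT and op.value == "in":
            k = j + 1
            if k < n and tokens[k].text == "(":
                k += 1
                if k < n and tokens[k].kind == _sql.IDENT and tokens[k].value == "select":
                    continue  # subquery, not a literal list
                depth = 1
                while k < n and depth > 0:
                    t = tokens[k]
                    if t.text == "(":
                        depth += 1
                    elif t.text == ")":
                        depth -= 1
                    elif depth == 1 and is_literal(t):
                        sites.append(ConceptRefSite(table, column, t.text, t.pos))
                    k += 1
        elif op.kind == _sql.IDENT and op.value == "between":
            bounds = []
            if j + 1 < n and is_literal(tokens[j + 1]):
                bounds.append(tokens[j + 1])
            if (j + 2 < n and tokens[j + 2].kind == _sql.IDENT
                    and tokens[j + 2].value == "and" and j + 3 < n
                    and is_literal(tokens[j + 3])):
                bounds.append(tokens[j + 3])
            for lit in bounds:
                sites.append(ConceptRefSite(table, column, lit.text, lit.pos))
    sites.sort(key=lambda s: s.position)
    return sites


def classify_site(
    site: ConceptRefSite,
    inventory: ConceptInventory,
    rule_of: "DomainRule | None | object" = None,
    catalog: CdmCatalog | None = None,
    patterns: Sequence[re.Pattern] = PLACEHOLDER_PATTERNS,
) -> HallucinationInstance | None:
    """Classify one concept-reference site, or return None if it is valid.

    ``rule_of`` may be a :class:`DomainRule` for the site's column or a
    callable ``column -> DomainRule``; if omitted it is resolved from the
    catalog. Precedence: placeholder (D) → non-integer (C) → nonexistent
    (A) → wrong domain (B).
    """
    lit = site.literal
    for pat in patterns:
        if pat.match(lit):
            return HallucinationInstance(
                site, "D", SEVERITY["D"], f"placeholder token {lit!r} in {site.column}"
            )
    if not _INTEGER.match(lit):
        return HallucinationInstance(
            site, "C", SEVERITY["C"],
            f"natural-language or non-numeric literal {lit!r} in {site.column}",
        )
    cid = int(lit)
    if cid not in inventory:
        return HallucinationInstance(
            site, "A", SEVERITY["A"], f"concept {cid} does not exist in the inventory"
        )
    if rule_of is None:
        rule = (catalog or default_catalog()).rule_for_column(site.column)
    elif callable(rule_of):
        rule = rule_of(site.column)
    else:
        rule = rule_of
    if rule is not None:
        actual = inventory.domain_of(cid)
        if actual != rule.domain_id:
            return HallucinationInstance(
                site, "B", SEVERITY["B"],
                f"concept {cid} has domain {actual!r} but {site.column} expects {rule.domain_id!r}",
            )
    return None


def audit_query(
    sql: str,
    inventory: ConceptInventory,
    catalog: CdmCatalog | None = None,
    policy: str = "default",
    group: str | None = None,
) -> QueryAudit:
    """Full audit of one candidate query.

    Combines the parse check, concept-reference classification (categories
    A–D) and schema validation (category E). Unparseable text is a
    generation failure: ``parse_ok=False``, no instances, not effective.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {sorted(POLICIES)}")
    catalog = catalog or default_catalog()
    ok, _reason = _sql.parse_check(sql)
    audit = QueryAudit(sql=sql, parse_ok=ok, policy=policy, group=group)
    if not ok:
        return audit
    for site in extract_concept_refs(sql, catalog):
        instance = classify_site(site, inventory, catalog=catalog)
        if instance is not None:
            audit.instances.append(instance)
    violations = validate_identifiers(sql, catalog)
    audit.schema_violations = violations
    for v in violations:
        site = ConceptRefSite(v.table, v.column or "", v.table or v.column or "", v.position)
        audit.instances.append(HallucinationInstance(site, "E", SEVERITY["E"], v.message))
    flagged = POLICIES[policy]
    audit.hallucinated = any(i.category in flagged for i in audit.instances)
    audit.effective = audit.parse_ok and not any(
        i.category in POLICIES["default"] for i in audit.instances
    )
    if policy == "broad":
        audit.effective = audit.parse_ok and not audit.instances
    return audit


def category_tally(audits: Iterable[QueryAudit]) -> dict[str, dict]:
    """Per-group category counts and percentages over instances.

    Mirrors the per-site counting convention of model-comparison tables:
    the denominator is the total number of instances in the group.
    """
    groups: dict[str, Counter] = {}
    for a in audits:
        key = a.group or "all"
        counter = groups.setdefault(key, Counter())
        for inst in a.instances:
            counter[inst.category] += 1
    out: dict[str, dict] = {}
    for key, counter in groups.items():
        total = sum(counter.values())
        counts = {c: counter.get(c, 0) for c in "ABCDE"}
        pct = {c: (100.0 * counts[c] / total if total else 0.0) for c in "ABCDE"}
        out[key] = {"total": total, "counts": counts, "percent": pct}
    return out


def audit_batch(
    queries: Sequence[str | tuple[str, str]],
    inventory: ConceptInventory,
    catalog: CdmCatalog | None = None,
    policy: str = "default",
) -> tuple[list[QueryAudit], dict[str, dict]]:
    """Audit a batch of queries (optionally ``(sql, group_label)`` pairs)."""
    audits = []
    for q in queries:
        sql, group = q if isinstance(q, tuple) else (q, None)
        audits.append(audit_query(sql, inventory, catalog, policy=policy, group=group))
    return audits, category_tally(audits)
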