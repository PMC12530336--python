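"""Embedded OMOP CDM v5.3 subset registry and SQL schema validation.

The catalog is a static JSON asset shipped with the package: the event tables
one per clinical domain (condition_occurrence, drug_exposure, ...), their
column lists, the person-ID join keys, and the domain→(table, concept column)
rules that decide where a criterion of a given domain must be queried.
Demographic criteria map onto the ``person`` table (year_of_birth /
gender_concept_id) per OMOP convention rather than an event table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import _sql
from .errors import SqlParseError, UnknownDomainError


@dataclass(frozen=True)
class DomainRule:
    """Where events of one clinical domain live in the CDM."""

    domain_id: str
    event_table: str
    concept_column: str
    date_column: str
    value_column: str | None = None


@dataclass(frozen=True)
class SchemaViolation:
    """One schema-conformance failure found in candidate SQL."""

    kind: str  # "unknown_table" | "unknown_column" | "nonkey_join"
    table: str | None
    column: str | None
    position: int
    message: str


@dataclass
class CdmCatalog:
    """Table/column catalog plus domain rules for a CDM subset."""

    tables: set[str]
    columns_by_table: dict[str, list[str]]
    join_keys: dict[str, str]
    domain_rules: dict[str, DomainRule]
    cdm_version: str = "5.3-subset"
    _concept_column_domains: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for table, key in self.join_keys.items():
            if key not in self.columns_by_table.get(table, []):
                raise ValueError(f"join key {key!r} is not a column of {table!r}")
        if not self._concept_column_domains:
            self._concept_column_domains = {
                rule.concept_column: rule.domain_id for rule in self.domain_rules.values()
            }

    @property
    def concept_columns(self) -> set[str]:
        """Columns whose literals are concept IDs subject to auditing."""
        return set(self._concept_column_domains)

    def domain_for_column(self, column: str) -> str | None:
        return self._concept_column_domains.get(column.lower())

    def rule_for_column(self, column: str) -> DomainRule | None:
        domain = self.domain_for_column(column)
        return self.domain_rules.get(domain) if domain else None


def load_catalog(path: str | Path | None = None) -> CdmCatalog:
    """Load the embedded CDM catalog, or an override JSON file.

    The JSON layout is ``{tables: {name: [cols]}, join_keys: {...},
    domain_rules: {domain: {event_table, concept_column, date_column,
    value_column}}}``.
    """
    if path is None:
        raw = resources.files("trialsql.assets").joinpath("cdm_catalog.json").read_text()
    else:
        raw = Path(path).read_text()
    data = json.loads(raw)
    rules = {
        dom: DomainRule(domain_id=dom, **spec) for dom, spec in data["domain_rules"].items()
    }
    return CdmCatalog(
        tables=set(data["tables"]),
        columns_by_table={t: list(cols) for t, cols in data["tables"].items()},
        join_keys=dict(data["join_keys"]),
        domain_rules=rules,
        cdm_version=data.get("cdm_version", "5.3-subset"),
    )


_DEFAULT_CATALOG: CdmCatalog | None = None


def default_catalog() -> CdmCatalog:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_catalog()
    return _DEFAULT_CATALOG


def domain_to_rule(domain_id: str, catalog: CdmCatalog | None = None) -> DomainRule:
    """Resolve a clinical domain to its event table / concept column rule."""
    catalog = catalog or default_catalog()
    try:
        return catalog.domain_rules[domain_id]
    except KeyError:
        raise UnknownDomainError(
            f"unknown domain {domain_id!r}; known: {sorted(catalog.domain_rules)}"
        ) from None


def validate_identifiers(sql: str, catalog: CdmCatalog | None = None) -> list[SchemaViolation]:
    """Check every table/column identifier in *sql* against the catalog.

    Returns one violation per unknown table, unknown column, or join whose ON
    equality uses no join-key column on either side; an empty list means the
    statement is fully schema-conformant. Matching is case-insensitive and
    quoted identifiers are unquoted before lookup. When a referenced table is
    unknown, column resolution is suppressed (columns cannot be attributed),
    so a single misspelled table yields a single violation.

    Raises :class:`SqlParseError` for text that fails the structural parse
    check — a generation failure, distinct from schema violations.
    """
    catalog = catalog or default_catalog()
    ok, reason = _sql.parse_check(sql)
    if not ok:
        raise SqlParseError(reason)
    tokens = _sql.tokenize(sql)
    table_tokens, aliases = _sql.table_references(tokens)

    violations: list[SchemaViolation] = []
    known_tables: list[str] = []
    any_unknown_table = False
    for tok in table_tokens:
        name = tok.value.lower()
        if name in catalog.tables:
            if name not in known_tables:
                known_tables.append(name)
        else:
            any_unknown_table = True
            violations.append(
                SchemaViolation("unknown_table", name, None, tok.pos, f"unknown table {name!r}")
            )

    if not any_unknown_table:
        violations.extend(_column_violations(tokens, known_tables, aliases, catalog))
        violations.extend(_join_violations(tokens, known_tables, aliases, catalog))
    violations.sort(key=lambda v: v.position)
    return violations


def _resolve_qualifier(q: str, known_tables: list[str], aliases: dict[str, str]) -> str | None:
    q = q.lower()
    if q in aliases:
        t = aliases[q]
        return t if t in known_tables else None
    if q in known_tables:
        return q
    return None


_COMPARISON_OPS = frozenset({"=", "!=", "<>", "<", ">", "<=", ">="})


def _in_value_position(tokens, idx) -> bool:
    """True when tokens[idx] sits where a literal belongs (RHS of a
    comparison, or inside an IN (...) list) — bare words there are broken
    literals, which the auditor classifies; they are not column references."""
    prv = tokens[idx - 1] if idx > 0 else None
    if prv is None:
        return False
    if prv.kind == _sql.PUNCT and prv.text in _COMPARISON_OPS:
        return True
    if prv.kind == _sql.PUNCT and prv.text in ("(", ","):
        j = idx - 1
        depth = 0
        while j >= 0:
            t = tokens[j]
            if t.text == ")":
                depth += 1
            elif t.text == "(":
                if depth == 0:
                    before = tokens[j - 1] if j > 0 else None
                    return before is not None and before.kind == _sql.IDENT and before.value == "in"
                depth -= 1
            j -= 1
    return False


def _column_violations(tokens, known_tables, aliases, catalog) -> list[SchemaViolation]:
    out = []
    allowed = {c.lower() for t in known_tables for c in catalog.columns_by_table[t]}
    table_names = set(known_tables)
    alias_names = set(aliases)
    n = len(tokens)
    for idx, tok in enumerate(tokens):
        if tok.kind not in (_sql.IDENT, _sql.QIDENT):
            continue
        name = tok.value.lower()
        if tok.kind == _sql.IDENT and name in _sql.KEYWORDS:
            continue
        nxt = tokens[idx + 1] if idx + 1 < n else None
        prv = tokens[idx - 1] if idx > 0 else None
        if nxt is not None and nxt.text == "(":  # function call
            continue
        if nxt is not None and nxt.text == ".":  # qualifier, handled via the qualified pair
            continue
        if prv is not None and prv.text == ".":
            # qualified column: resolve the qualifier
            qual = tokens[idx - 2]
            table = _resolve_qualifier(qual.value, known_tables, aliases)
            if table is not None and name not in {c.lower() for c in catalog.columns_by_table[table]}:
                out.append(
                    SchemaViolation(
                        "unknown_column", table, name, tok.pos,
                        f"unknown column {name!r} in {table!r}",
                    )
                )
            continue
        if prv is not None and prv.kind == _sql.IDENT and prv.value in ("as", "from", "join"):
            continue  # alias definition or table position
        if _in_value_position(tokens, idx):
            continue
        if name in table_names or name in alias_names:
            continue
        if name not in allowed:
            table = known_tables[0] if len(known_tables) == 1 else None
            where = f" in {table!r}" if table else ""
            out.append(
                SchemaViolation("unknown_column", table, name, tok.pos,
                                f"unknown column {name!r}{where}")
            )
    return out


def _join_violations(tokens, known_tables, aliases, catalog) -> list[SchemaViolation]:
    """Flag ON equalities between two known tables where neither side is a join key."""
    out = []
    n = len(tokens)
    for idx, tok in enumerate(tokens):
        if not (tok.kind == _sql.IDENT and tok.value == "on"):
            continue
        # pattern: ON q1 . c1 = q2 . c2
        if idx + 7 >= n:
            continue
        seq = tokens[idx + 1 : idx + 8]
        if seq[1].text == "." and seq[3].text == "=" and seq[5].text == ".":
            q1, c1, q2, c2 = seq[0], seq[2], seq[4], seq[6]
            t1 = _resolve_qualifier(q1.value, known_tables, aliases)
            t2 = _resolve_qualifier(q2.value, known_tables, aliases)
            if t1 and t2 and t1 != t2:
                k1 = catalog.join_keys.get(t1)
                k2 = catalog.join_keys.get(t2)
                if c1.value.lower() != (k1 or "") and c2.value.lower() != (k2 or ""):
                    out.append(
                        SchemaViolation(
                            "nonkey_join", t1, c1.value.lower(), c1.pos,
                            f"join between {t1!r} and {t2!r} uses no join-key column",
                        )
                    )
    return out
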