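"""Assemble OMOP-conformant cohort SQL from extraction records.

Each criterion becomes a one-column subquery (``SELECT person_id FROM
<event table> WHERE <concept column> IN (...)``) over its domain's event
table, with the concept set optionally expanded through the ancestor
hierarchy, value constraints rendered on the domain's value column and
temporal constraints rendered as date cutoffs relative to a configurable
index date. Inclusion subqueries merge via INTERSECT; exclusions apply as a
set difference, either with EXCEPT or an equivalent NOT IN rewrite.

Dialect: a portable ANSI subset executable by the embedded engine used in
tests (sqlite); date cutoffs are precomputed in Python and rendered as ISO
literals so no engine-specific date arithmetic appears in the output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .cdm_schema import DomainRule
from .criteria_pipeline import ExtractionRecord
from .errors import AssemblyError, BuildError, UnknownConceptError
from .vocabulary import ConceptInventory, descendants

DEFAULT_INDEX_DATE = dt.date(2023, 12, 31)

#: day-count equivalents used when rendering month/year temporal windows
DAYS_PER_UNIT = {"day": 1, "week": 7, "month": 30, "year": 365}

#: domains whose concept sets expand through the hierarchy unless overridden
EXPAND_DEFAULT_DOMAINS = frozenset({"Condition", "Drug"})

_CMP_SQL = {"<": "<", "≤": "<=", "=": "=", "≥": ">=", ">": ">"}


class Placement(Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"
    REVIEW = "manual_review"


@dataclass
class CriterionQuery:
    """One criterion rendered as a single-column person-ID subquery."""

    criterion_ref: ExtractionRecord
    domain_id: str
    concept_ids: frozenset[int]
    expanded: bool
    sql_fragment: str
    constraints: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CohortQuery:
    """A full cohort definition: merged inclusions minus exclusions."""

    trial_id: str
    inclusion_fragments: list[CriterionQuery]
    exclusion_fragments: list[CriterionQuery]
    sql_text: str
    mode: str
    build_log: list[str] = field(default_factory=list)


def negation_route(record: ExtractionRecord) -> Placement:
    """Decide which cohort arm a criterion belongs to.

    A negated inclusion ("no history of X") is routed to the exclusion arm:
    requiring the absence of X equals excluding patients who have X. A
    negated *exclusion* is flagged for manual review rather than silently
    double-negated.
    """
    if record.polarity == "inclusion":
        return Placement.EXCLUSION if record.negation else Placement.INCLUSION
    return Placement.REVIEW if record.negation else Placement.EXCLUSION


def _temporal_cutoff(quantity: float, unit: str, index_date: dt.date) -> dt.date:
    days = int(round(quantity * DAYS_PER_UNIT[unit]))
    return index_date - dt.timedelta(days=days)


def build_criterion_query(
    record: ExtractionRecord,
    concept_ids: Iterable[int],
    rule: DomainRule,
    inventory: ConceptInventory,
    expand: bool | None = None,
    index_date: dt.date = DEFAULT_INDEX_DATE,
) -> CriterionQuery:
    """Render one extraction record as a person-ID subquery.

    ``expand=None`` applies the default policy: descendant expansion for
    Condition and Drug concepts, off elsewhere.
    """
    if expand is None:
        expand = rule.domain_id in EXPAND_DEFAULT_DOMAINS

    if rule.domain_id == "Demographic":
        return _build_demographic(record, rule, index_date)

    ids = set()
    for cid in concept_ids:
        if cid not in inventory:
            raise UnknownConceptError(f"concept {cid} not in inventory")
        ids.update(descendants(inventory, cid) if expand else {cid})
    if not ids:
        raise BuildError("empty concept set for a concept-backed criterion")

    constraints: list[tuple[str, str]] = []
    if record.value is not None:
        if rule.value_column is None:
            raise BuildError(
                f"value constraint on domain {rule.domain_id!r} which has no value column"
            )
        predicate = f"{rule.value_column} {_CMP_SQL[record.value.comparator]} {record.value.number:g}"
        constraints.append(("value", predicate))
    if record.temporal is not None:
        cutoff = _temporal_cutoff(record.temporal.quantity, record.temporal.unit, index_date)
        constraints.append(("temporal", f"{rule.date_column} >= '{cutoff.isoformat()}'"))

    id_list = ", ".join(str(i) for i in sorted(ids))
    sql = f"SELECT person_id FROM {rule.event_table} WHERE {rule.concept_column} IN ({id_list})"
    for _, predicate in constraints:
        sql += f" AND {predicate}"
    return CriterionQuery(
        criterion_ref=record,
        domain_id=rule.domain_id,
        concept_ids=frozenset(ids),
        expanded=expand,
        sql_fragment=sql,
        constraints=constraints,
    )


def _build_demographic(
    record: ExtractionRecord, rule: DomainRule, index_date: dt.date
) -> CriterionQuery:
    """Demographic criteria query the person table; age is age at index date."""
    if record.value is None:
        raise BuildError("demographic criterion without a value constraint is not renderable")
    cmp_sql = _CMP_SQL[record.value.comparator]
    predicate = f"({index_date.year} - year_of_birth) {cmp_sql} {record.value.number:g}"
    sql = f"SELECT person_id FROM person WHERE {predicate}"
    return CriterionQuery(
        criterion_ref=record,
        domain_id="Demographic",
        concept_ids=frozenset(),
        expanded=False,
        sql_fragment=sql,
        constraints=[("value", predicate)],
    )


def assemble_cohort(
    inclusions: list[CriterionQuery],
    exclusions: list[CriterionQuery],
    mode: str = "EXCEPT",
    trial_id: str = "",
) -> CohortQuery:
    """Merge criterion subqueries into one cohort query.

    ``mode="EXCEPT"`` chains set-difference operators; ``mode="NOT IN"``
    rewrites exclusions as a NOT IN over their union. Both produce
    set-identical person-ID results on any database.
    """
    mode = mode.upper().replace("_", " ")
    if mode not in ("EXCEPT", "NOT IN"):
        raise AssemblyError(f"unknown assembly mode {mode!r}")
    if not inclusions:
        raise AssemblyError("at least one inclusion criterion is required")

    log = [f"mode={mode}", f"inclusions={len(inclusions)}", f"exclusions={len(exclusions)}"]
    incl = "\nINTERSECT\n".join(q.sql_fragment for q in inclusions)
    if mode == "EXCEPT":
        sql = incl
        for q in exclusions:
            sql += f"\nEXCEPT\n{q.sql_fragment}"
    else:
        sql = f"SELECT person_id FROM (\n{incl}\n) AS included"
        if exclusions:
            union = "\nUNION\n".join(q.sql_fragment for q in exclusions)
            sql += f"\nWHERE person_id NOT IN (\n{union}\n)"
    return CohortQuery(
        trial_id=trial_id,
        inclusion_fragments=inclusions,
        exclusion_fragments=exclusions,
        sql_text=sql,
        mode=mode,
        build_log=log,
    )


def build_trial_cohort(
    records: list[ExtractionRecord],
    concept_map: dict[int, set[int]],
    rules: dict[int, DomainRule],
    inventory: ConceptInventory,
    mode: str = "EXCEPT",
    expand: bool | None = None,
    index_date: dt.date = DEFAULT_INDEX_DATE,
    trial_id: str = "",
) -> CohortQuery:
    """Convenience end-to-end assembly: route, render, and merge criteria.

    *concept_map* and *rules* are keyed by ``criterion_index``. Criteria
    routed to manual review are logged and skipped.
    """
    inclusions: list[CriterionQuery] = []
    exclusions: list[CriterionQuery] = []
    log: list[str] = []
    for record in records:
        placement = negation_route(record)
        if placement is Placement.REVIEW:
            log.append(f"criterion {record.criterion_index}: negated exclusion -> manual review")
            continue
        cq = build_criterion_query(
            record,
            concept_map.get(record.criterion_index, set()),
            rules[record.criterion_index],
            inventory,
            expand=expand,
            index_date=index_date,
        )
        if placement is Placement.INCLUSION:
            inclusions.append(cq)
        else:
            if record.polarity == "inclusion":
                log.append(f"criterion {record.criterion_index}: negated inclusion routed to exclusion")
            exclusions.append(cq)
    cohort = assemble_cohort(inclusions, exclusions, mode=mode, trial_id=trial_id)
    cohort.build_log = log + cohort.build_log
    return cohort
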