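"""Synthetic data generators: every input the toolkit needs, offline.

The central scenario emulated here is a *limited-coverage* vocabulary: a
"loadable" concept inventory that is a small fraction of a larger concept
universe, the situation that makes concept-ID hallucinations observable (a
generator that emits a real-looking ID outside the loaded inventory produces
a detectable nonexistent-concept error). On top of that sit a small
patient-level CDM for executing assembled cohort SQL, fixture queries with
seeded hallucination injection and a ground-truth manifest, cohort pairs
with a target Jaccard index, and a scripted mock text-model backend.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import _sql
from .audit import extract_concept_refs
from .cdm_schema import CdmCatalog, default_catalog, domain_to_rule
from .criteria_pipeline import BackendContract
from .errors import FeasibilityError, InjectionError, InputError, ScriptedMissError
from .vocabulary import Concept, ConceptInventory

# Default desk-scale study conditions: a 10,000-concept universe of which
# 10% is loadable, and a 500-person CDM -- seconds-scale yet large enough
# that injected errors cannot be found by accident.
DEFAULT_UNIVERSE_SIZE = 10_000
DEFAULT_LOADED_FRACTION = 0.1
DEFAULT_N_PERSONS = 500

DEFAULT_DOMAIN_WEIGHTS = {
    # proportions follow the empirical domain mix of extracted trial concepts
    "Condition": 0.495,
    "Drug": 0.154,
    "Procedure": 0.128,
    "Measurement": 0.096,
    "Observation": 0.074,
    "Device": 0.026,
    "Visit": 0.027,
}

_ADJECTIVES = (
    "chronic", "acute", "recurrent", "severe", "mild", "essential", "secondary",
    "primary", "congenital", "idiopathic", "generalized", "localized",
)
_NOUNS = {
    "Condition": ("hypertension", "diabetes", "anemia", "pneumonia", "dermatitis",
                  "carcinoma", "arrhythmia", "nephropathy", "hepatitis", "asthma"),
    "Drug": ("metformin", "lisinopril", "atorvastatin", "warfarin", "insulin",
             "amoxicillin", "omeprazole", "albuterol", "heparin", "aspirin"),
    "Procedure": ("angioplasty", "biopsy", "colonoscopy", "appendectomy",
                  "catheterization", "dialysis", "endoscopy", "resection"),
    "Measurement": ("hemoglobin", "creatinine", "glucose", "cholesterol",
                    "platelet count", "bilirubin", "albumin", "potassium"),
    "Observation": ("tobacco use", "alcohol use", "family history", "body weight",
                    "pregnancy status", "fall risk", "pain score"),
    "Device": ("pacemaker", "stent", "insulin pump", "defibrillator", "catheter"),
    "Visit": ("inpatient visit", "outpatient visit", "emergency visit"),
}


@dataclass(frozen=True)
class SynthVocabSpec:
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    loaded_fraction: float = DEFAULT_LOADED_FRACTION
    domains: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOMAIN_WEIGHTS))
    depth: int = 3
    branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.loaded_fraction <= 1.0):
            raise InputError("loaded_fraction must be in (0, 1]")
        if self.universe_size < 1:
            raise InputError("universe_size must be positive")


def generate_vocabulary(spec: SynthVocabSpec) -> tuple[ConceptInventory, ConceptInventory]:
    """Generate a concept universe and its loadable sub-inventory.

    Concepts are organized as a forest of rooted trees (per-domain, with the
    spec's depth and branching) so descendant expansion has real structure;
    the loaded inventory is a uniform sample of ``round(universe_size ×
    loaded_fraction)`` concepts, and its ancestor relation is the universe
    relation restricted to loaded endpoints (restriction of a transitive
    closure stays transitive).
    """
    rng = np.random.default_rng(spec.seed)
    domains = list(spec.domains)
    weights = np.array([spec.domains[d] for d in domains], dtype=float)
    weights = weights / weights.sum()

    concepts: dict[int, Concept] = {}
    pairs: set[tuple[int, int]] = set()
    next_id = 1001

    def new_concept(domain: str) -> int:
        nonlocal next_id
        cid = next_id
        next_id += 1
        adj = _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]
        noun_pool = _NOUNS[domain]
        noun = noun_pool[int(rng.integers(len(noun_pool)))]
        concepts[cid] = Concept(
            concept_id=cid,
            concept_name=f"{adj} {noun} variant {cid}",
            domain_id=domain,
            vocabulary_id="SNOMED",
            standard=True,
        )
        return cid

    # grow trees until the universe is full
    while len(concepts) < spec.universe_size:
        domain = domains[int(rng.choice(len(domains), p=weights))]
        frontier = [(new_concept(domain), [])]  # (node, ancestor chain)
        for _level in range(spec.depth):
            if len(concepts) >= spec.universe_size:
                break
            next_frontier = []
            for node, chain in frontier:
                n_children = int(rng.integers(1, spec.branching + 1))
                for _ in range(n_children):
                    if len(concepts) >= spec.universe_size:
                        break
                    child = new_concept(domain)
                    for anc in chain + [node]:
                        pairs.add((anc, child))
                    next_frontier.append((child, chain + [node]))
            frontier = next_frontier

    universe = ConceptInventory(concepts=concepts, ancestor_pairs=pairs)
    n_loaded = int(round(spec.universe_size * spec.loaded_fraction))
    loaded_ids = set(
        int(i) for i in rng.choice(sorted(concepts), size=n_loaded, replace=False)
    )
    loaded_concepts = {cid: concepts[cid] for cid in loaded_ids}
    loaded_pairs = {(a, d) for a, d in pairs if a in loaded_ids and d in loaded_ids}
    loaded = ConceptInventory(concepts=loaded_concepts, ancestor_pairs=loaded_pairs)
    return universe, loaded


@dataclass
class MiniCdm:
    """A small patient-level CDM held as DataFrames, executable via sqlite."""

    tables: dict[str, pd.DataFrame]
    seed: int
    draw_log: dict[int, set[int]] = field(default_factory=dict)  # concept -> persons drawn

    def connect(self) -> sqlite3.Connection:
        conn = sqlite3.connect(":memory:")
        for name, df in self.tables.items():
            df.to_sql(name, conn, index=False)
        return conn

    def execute(self, sql: str) -> set[int]:
        """Run a cohort query and return the distinct person-ID set."""
        conn = self.connect()
        try:
            rows = conn.execute(sql).fetchall()
        finally:
            conn.close()
        return {int(r[0]) for r in rows}

    def write_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(directory / f"{name}.csv", index=False)


def generate_mini_cdm(
    inventory: ConceptInventory,
    n_persons: int = DEFAULT_N_PERSONS,
    event_rates: dict[int, float] | None = None,
    seed: int = 0,
    n_random_concepts: int = 30,
    random_rate: float = 0.1,
    date_window: tuple[dt.date, dt.date] = (dt.date(2020, 1, 1), dt.date(2023, 12, 31)),
    catalog: CdmCatalog | None = None,
) -> MiniCdm:
    """Materialize a person table plus per-domain event tables.

    ``event_rates`` maps concept_id → per-person event probability; if not
    given, ``n_random_concepts`` inventory concepts get events at
    ``random_rate``. Every event's concept exists in the inventory and every
    event's person exists in the person table (referential integrity by
    construction); the draw log records exactly which persons received each
    concept, serving as the ground-truth oracle for cohort execution.
    """
    if len(inventory) == 0:
        raise InputError("inventory must be nonempty")
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(seed)
    persons = pd.DataFrame(
        {
            "person_id": np.arange(1, n_persons + 1),
            "gender_concept_id": rng.choice([8507, 8532], size=n_persons),
            "year_of_birth": rng.integers(1930, 2006, size=n_persons),
            "month_of_birth": rng.integers(1, 13, size=n_persons),
            "day_of_birth": rng.integers(1, 29, size=n_persons),
            "birth_datetime": "",
            "race_concept_id": 0,
            "ethnicity_concept_id": 0,
        }
    )
    if event_rates is None:
        pool = sorted(inventory.ids)
        chosen = rng.choice(pool, size=min(n_random_concepts, len(pool)), replace=False)
        event_rates = {int(c): random_rate for c in chosen}

    start, end = date_window
    span = (end - start).days
    rows_by_table: dict[str, list[dict]] = {}
    draw_log: dict[int, set[int]] = {}
    for cid, rate in sorted(event_rates.items()):
        if cid not in inventory:
            raise InputError(f"event concept {cid} not in inventory")
        if not (0.0 <= rate <= 1.0):
            raise InputError("event rates must be probabilities")
        rule = domain_to_rule(inventory.domain_of(cid), catalog)
        mask = rng.random(n_persons) < rate
        person_ids = persons["person_id"].to_numpy()[mask]
        draw_log[cid] = {int(p) for p in person_ids}
        offsets = rng.integers(0, span + 1, size=len(person_ids))
        for pid, off in zip(person_ids, offsets):
            row = {
                "person_id": int(pid),
                rule.concept_column: cid,
                rule.date_column: (start + dt.timedelta(days=int(off))).isoformat(),
            }
            if rule.value_column:
                row[rule.value_column] = float(np.round(rng.normal(10.0, 3.0), 2))
            rows_by_table.setdefault(rule.event_table, []).append(row)

    tables: dict[str, pd.DataFrame] = {"person": persons}
    for name, columns in catalog.columns_by_table.items():
        if name in ("person", "concept", "concept_ancestor"):
            continue
        rows = rows_by_table.get(name, [])
        df = pd.DataFrame(rows)
        for col in columns:
            if col not in df.columns:
                df[col] = pd.Series(dtype=object)
        tables[name] = df[columns] if len(df) else pd.DataFrame(columns=columns)
    return MiniCdm(tables=tables, seed=seed, draw_log=draw_log)


# ---------------------------------------------------------------------------
# Fixture queries and hallucination injection
# ---------------------------------------------------------------------------


def generate_valid_queries(
    loaded: ConceptInventory,
    n: int,
    seed: int = 0,
    catalog: CdmCatalog | None = None,
    max_concepts: int = 3,
) -> list[str]:
    """Render *n* audit-clean single-criterion cohort queries.

    Each query selects a random event domain present in the inventory and an
    IN-list of 1..max_concepts loaded concepts of that domain.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(seed)
    by_domain: dict[str, list[int]] = {}
    for cid in sorted(loaded.ids):
        by_domain.setdefault(loaded.domain_of(cid), []).append(cid)
    domains = sorted(d for d in by_domain if d in catalog.domain_rules and d != "Demographic")
    if not domains:
        raise InputError("inventory has no concepts in queryable domains")
    queries = []
    for _ in range(n):
        domain = domains[int(rng.integers(len(domains)))]
        rule = catalog.domain_rules[domain]
        pool = by_domain[domain]
        k = int(rng.integers(1, min(max_concepts, len(pool)) + 1))
        ids = sorted(int(c) for c in rng.choice(pool, size=k, replace=False))
        id_list = ", ".join(map(str, ids))
        queries.append(
            f"SELECT person_id FROM {rule.event_table} "
            f"WHERE {rule.concept_column} IN ({id_list})"
        )
    return queries


PLACEHOLDER_TOKENS = ("?", ":concept_id", "<INSERT_ID>", "{concept_id}", "CONCEPT_ID_HERE")


@dataclass(frozen=True)
class InjectedSite:
    query_index: int
    position: int
    column: str
    category: str
    original: str
    injected: str


@dataclass
class InjectionManifest:
    group: str
    sites: list[InjectedSite] = field(default_factory=list)

    def categories_for(self, query_index: int) -> list[str]:
        return sorted(s.category for s in self.sites if s.query_index == query_index)

    def tally(self) -> dict[str, int]:
        out = {c: 0 for c in "ABCDE"}
        for s in self.sites:
            out[s.category] += 1
        return out


def inject_errors(
    valid_queries: Sequence[str],
    profile: dict[str, float],
    universe: ConceptInventory,
    loaded: ConceptInventory,
    seed: int = 0,
    catalog: CdmCatalog | None = None,
    group: str = "synthetic",
) -> tuple[list[str], InjectionManifest]:
    """Seed hallucinations into audit-clean queries, recording ground truth.

    Per concept-reference site, one of categories A-D fires with the profile
    probability: A swaps the ID for a universe-minus-loaded ID (the
    limited-coverage mechanism), B for a loaded ID of a different domain, C
    for the concept's own name as a quoted string, D for a placeholder
    token. E corrupts the query's table name (at most once per query). At
    most one injection per site; the manifest records every edit.
    """
    if any(p < 0 for p in profile.values()):
        raise InjectionError("profile probabilities must be non-negative")
    site_mass = sum(profile.get(c, 0.0) for c in "ABCD")
    if site_mass > 1.0 + 1e-9:
        raise InjectionError("per-site probability mass for A-D exceeds 1")
    if profile.get("E", 0.0) > 1.0:
        raise InjectionError("E probability exceeds 1")

    catalog = catalog or default_catalog()
    rng = np.random.default_rng(seed)
    outside = sorted(universe.ids - loaded.ids)
    manifest = InjectionManifest(group=group)
    out_queries: list[str] = []

    for qi, sql in enumerate(valid_queries):
        sites = extract_concept_refs(sql, catalog)
        edits: list[InjectedSite] = []
        for site in sites:
            r = float(rng.random())
            acc = 0.0
            chosen = None
            for cat in "ABCD":
                acc += profile.get(cat, 0.0)
                if r < acc:
                    chosen = cat
                    break
            if chosen is None:
                continue
            replacement = _replacement_for(chosen, site, rng, outside, universe, loaded, catalog)
            edits.append(
                InjectedSite(qi, site.position, site.column, chosen, site.literal, replacement)
            )
        if float(rng.random()) < profile.get("E", 0.0):
            pos, original, corrupted = _corrupt_table(sql)
            if pos is not None:
                edits.append(InjectedSite(qi, pos, "", "E", original, corrupted))
        new_sql = sql
        for e in sorted(edits, key=lambda e: -e.position):
            new_sql = new_sql[: e.position] + e.injected + new_sql[e.position + len(e.original):]
        out_queries.append(new_sql)
        manifest.sites.extend(edits)
    return out_queries, manifest


def _replacement_for(category, site, rng, outside, universe, loaded, catalog) -> str:
    if category == "A":
        if outside:
            return str(outside[int(rng.integers(len(outside)))])
        return str(max(universe.ids) + 1 + int(rng.integers(1_000_000)))
    if category == "B":
        expected = catalog.domain_for_column(site.column)
        candidates = [c for c in sorted(loaded.ids) if loaded.domain_of(c) != expected]
        if not candidates:
            raise InjectionError(f"no wrong-domain concept available for {site.column}")
        return str(candidates[int(rng.integers(len(candidates)))])
    if category == "C":
        try:
            name = loaded.concepts[int(site.literal)].concept_name
        except (KeyError, ValueError):
            name = "type 2 diabetes mellitus"
        return "'" + name.replace("'", "''") + "'"
    if category == "D":
        return PLACEHOLDER_TOKENS[int(rng.integers(len(PLACEHOLDER_TOKENS)))]
    raise InjectionError(f"unknown category {category!r}")


def _corrupt_table(sql: str) -> tuple[int | None, str, str]:
    tokens = _sql.tokenize(sql)
    for idx, tok in enumerate(tokens):
        if tok.kind == _sql.IDENT and tok.value == "from" and idx + 1 < len(tokens):
            nxt = tokens[idx + 1]
            if nxt.kind == _sql.IDENT:
                return nxt.pos, nxt.text, nxt.text + "_tbl"
    return None, "", ""


# ---------------------------------------------------------------------------
# Cohort pairs with a target Jaccard index
# ---------------------------------------------------------------------------


def generate_cohort_pair(
    n_a: int, n_b: int, target_jaccard: float, seed: int = 0, tolerance: float = 0.01
) -> tuple[set[int], set[int]]:
    """Two patient-ID sets of given sizes whose Jaccard index hits the target.

    The intersection size i solves j = i/(n_a + n_b − i); the realized value
    is within ±tolerance of the target or a :class:`FeasibilityError` reports
    the nearest achievable value.
    """
    if n_a < 0 or n_b < 0:
        raise InputError("set sizes must be non-negative")
    if not (0.0 <= target_jaccard <= 1.0):
        raise InputError("target_jaccard must be in [0, 1]")
    if n_a == 0 or n_b == 0:
        if target_jaccard > tolerance:
            raise FeasibilityError("empty set cannot reach a positive Jaccard", nearest=0.0)
        return set(), set(range(1, n_b + 1))

    best_i, best_err = 0, float("inf")
    for i in range(0, min(n_a, n_b) + 1):
        j = i / (n_a + n_b - i)
        err = abs(j - target_jaccard)
        if err < best_err:
            best_i, best_err = i, err
    if best_err > tolerance:
        nearest = best_i / (n_a + n_b - best_i)
        raise FeasibilityError(
            f"target Jaccard {target_jaccard} infeasible for sizes ({n_a}, {n_b}); "
            f"nearest achievable is {nearest:.4f}",
            nearest=nearest,
        )
    rng = np.random.default_rng(seed)
    pool = rng.permutation(np.arange(1, (n_a + n_b) * 3 + 1))
    shared = [int(x) for x in pool[:best_i]]
    only_a = [int(x) for x in pool[best_i : best_i + (n_a - best_i)]]
    only_b = [int(x) for x in pool[best_i + (n_a - best_i) : best_i + (n_a - best_i) + (n_b - best_i)]]
    return set(shared + only_a), set(shared + only_b)


# ---------------------------------------------------------------------------
# Scripted mock backend
# ---------------------------------------------------------------------------


def _payload_key(task: str, payload: dict[str, Any]) -> str:
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    return f"{task}:{digest}"


def mock_backend(script: dict[str, dict[str, Any]], name: str = "mock") -> BackendContract:
    """A deterministic scripted backend: exact input → scripted output.

    Keys are ``task:sha256(payload-json)`` (build them with
    :func:`script_entry`). Unscripted input raises
    :class:`ScriptedMissError` — never a silent fallthrough.
    """

    def transform(task: str, payload: dict[str, Any]) -> dict[str, Any]:
        key = _payload_key(task, payload)
        if key not in script:
            raise ScriptedMissError(f"no scripted response for task {task!r} (key {key[:16]}…)")
        return script[key]

    return BackendContract(name=name, transform=transform, deterministic=True)


def script_entry(task: str, payload: dict[str, Any], output: dict[str, Any]) -> tuple[str, dict]:
    """Build one (key, output) script entry for :func:`mock_backend`."""
    return _payload_key(task, payload), output


def record_script(
    backend: BackendContract, calls: Sequence[tuple[str, dict[str, Any]]]
) -> dict[str, dict[str, Any]]:
    """Replay *calls* through *backend* and capture a script mirroring it."""
    return dict(script_entry(task, payload, backend.transform(task, payload)) for task, payload in calls)
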