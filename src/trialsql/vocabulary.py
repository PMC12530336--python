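"""Standardized-vocabulary concept inventory and a string-similarity baseline mapper.

The inventory mirrors the OMOP CONCEPT / CONCEPT_ANCESTOR pair of tables: a
set of concepts (id, name, domain, vocabulary, standard flag) plus the
transitively closed ancestor relation used for hierarchical concept-set
expansion. It is the ground truth the SQL auditor validates concept IDs
against, and the search space for the edit-distance baseline mapper that
stands in for OHDSI USAGI (string normalization + normalized Levenshtein
similarity; no claim of bit-compatibility with USAGI's internals).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .errors import FormatError, InputError, IntegrityError, UnknownConceptError

CONCEPT_COLUMNS = ["concept_id", "concept_name", "domain_id", "vocabulary_id", "standard_concept"]
ANCESTOR_COLUMNS = ["ancestor_concept_id", "descendant_concept_id"]

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class Concept:
    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str = "SNOMED"
    standard: bool = True

    def __post_init__(self) -> None:
        if self.concept_id <= 0:
            raise ValueError("concept_id must be a positive integer")


@dataclass(frozen=True)
class MappingCandidate:
    query_term: str
    concept_id: int
    score: float
    rank: int


@dataclass
class ConceptInventory:
    """Concept collection with reflexive+transitive ancestor closure.

    The closure is computed once at construction so ``descendants`` is a pure
    dictionary lookup, matching OMOP's convention that concept_ancestor holds
    the full transitive closure including zero-level (self) pairs.
    """

    concepts: dict[int, Concept]
    ancestor_pairs: set[tuple[int, int]]
    _descendants: dict[int, frozenset[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for a, d in self.ancestor_pairs:
            if a not in self.concepts or d not in self.concepts:
                raise IntegrityError(f"ancestor pair ({a}, {d}) references unknown concept")
        self.ancestor_pairs = _close(self.ancestor_pairs, set(self.concepts))
        children: dict[int, set[int]] = {}
        for a, d in self.ancestor_pairs:
            children.setdefault(a, set()).add(d)
        self._descendants = {cid: frozenset(children.get(cid, {cid})) for cid in self.concepts}

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self.concepts

    @property
    def ids(self) -> set[int]:
        return set(self.concepts)

    def domain_of(self, concept_id: int) -> str:
        return self.concepts[concept_id].domain_id


def _close(pairs: set[tuple[int, int]], ids: set[int]) -> set[tuple[int, int]]:
    """Reflexive-transitive closure of the ancestor relation over *ids*."""
    children: dict[int, set[int]] = {}
    for a, d in pairs:
        if a != d:
            children.setdefault(a, set()).add(d)
    closed: set[tuple[int, int]] = {(i, i) for i in ids}
    for root in ids:
        seen: set[int] = set()
        stack = list(children.get(root, ()))
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            closed.add((root, node))
            stack.extend(children.get(node, ()))
    return closed


def _read_delimited(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_inventory(concept_table: str | Path, ancestor_table: str | Path) -> ConceptInventory:
    """Load an inventory from OMOP-layout CONCEPT / CONCEPT_ANCESTOR files.

    Files are tab- or comma-delimited with a header row. Reflexive ancestor
    pairs are added if absent and the transitive closure is completed.
    """
    cdf = _read_delimited(concept_table, CONCEPT_COLUMNS)
    ids = cdf["concept_id"].astype(int)
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise IntegrityError(f"duplicate concept_id(s): {sorted(set(dupes))}")
    concepts = {
        int(row.concept_id): Concept(
            concept_id=int(row.concept_id),
            concept_name=row.concept_name,
            domain_id=row.domain_id,
            vocabulary_id=row.vocabulary_id,
            standard=row.standard_concept == "S",
        )
        for row in cdf.itertuples()
    }
    adf = _read_delimited(ancestor_table, ANCESTOR_COLUMNS)
    pairs = {
        (int(r.ancestor_concept_id), int(r.descendant_concept_id)) for r in adf.itertuples()
    }
    return ConceptInventory(concepts=concepts, ancestor_pairs=pairs)


def write_inventory(
    inventory: ConceptInventory, concept_table: str | Path, ancestor_table: str | Path
) -> None:
    """Write an inventory back out in the OMOP CONCEPT / CONCEPT_ANCESTOR layout."""
    rows = [
        {
            "concept_id": c.concept_id,
            "concept_name": c.concept_name,
            "domain_id": c.domain_id,
            "vocabulary_id": c.vocabulary_id,
            "standard_concept": "S" if c.standard else "",
        }
        for c in sorted(inventory.concepts.values(), key=lambda c: c.concept_id)
    ]
    pd.DataFrame(rows, columns=CONCEPT_COLUMNS).to_csv(concept_table, index=False)
    pairs = sorted(inventory.ancestor_pairs)
    pd.DataFrame(pairs, columns=ANCESTOR_COLUMNS).to_csv(ancestor_table, index=False)


def exists(inventory: ConceptInventory, concept_id: int) -> bool:
    """True iff *concept_id* is present in the inventory."""
    return concept_id in inventory


def descendants(inventory: ConceptInventory, concept_id: int) -> set[int]:
    """All descendants of *concept_id*, including itself (reflexive closure)."""
    if concept_id not in inventory:
        raise UnknownConceptError(f"concept {concept_id} not in inventory")
    return set(inventory._descendants[concept_id])


def normalize_term(term: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    t = _PUNCT.sub(" ", term.lower())
    return _WS.sub(" ", t).strip()


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity: 1 − d(a,b) / max(|a|,|b|).

    Operates on already-normalized strings; symmetric; 1.0 iff equal.
    """
    if a == b:
        return 1.0
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / longest


def baseline_map(term: str, inventory: ConceptInventory, top_k: int = 5) -> list[MappingCandidate]:
    """Rank inventory concepts by string similarity to *term*.

    Scores are normalized Levenshtein similarity between the normalized term
    and each normalized concept name; ties break toward the lower concept_id
    so output is deterministic.
    """
    if not term or not term.strip():
        raise InputError("term must be nonempty")
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    q = normalize_term(term)
    scored = sorted(
        ((similarity(q, normalize_term(c.concept_name)), -cid) for cid, c in inventory.concepts.items()),
        reverse=True,
    )
    return [
        MappingCandidate(query_term=term, concept_id=-negid, score=score, rank=i + 1)
        for i, (score, negid) in enumerate(scored[:top_k])
    ]
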