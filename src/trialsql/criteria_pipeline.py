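"""Eligibility-criteria preprocessing and structured information extraction.

Free-text inclusion/exclusion blocks pass through three stages —
segmentation (one criterion per bullet/clause, nested items inheriting their
parent context), filtration (dropping non-queryable, trial-administrative
criteria such as consent requirements), and simplification (normalizing
temporal and comparator phrasing and trimming elaborations so token counts
fall monotonically) — followed by extraction of seven structured elements:
clinical terms, terminology system, codes, value constraint, attributes,
temporal constraint, and negation.

Every stage delegates to a pluggable text-model backend so an LLM adapter can
be swapped in; the shipped default is a deterministic rule backend, which
keeps the whole path offline and bit-stable. Backend outputs cross a schema
gate (pydantic validation) before they are allowed downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Callable, Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .errors import InputError, SchemaValidationError

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Criterion:
    """One eligibility criterion tracked through the preprocessing stages."""

    trial_id: str
    index: int
    polarity: Literal["inclusion", "exclusion"]
    raw_text: str
    segmented_text: str
    queryable: bool = True
    non_queryable_reason: str | None = None
    simplified_text: str | None = None
    token_counts: dict[str, int] = field(default_factory=dict)


class ValueConstraint(BaseModel):
    comparator: Literal["<", "≤", "=", "≥", ">"]
    number: float
    unit: str = ""


class TemporalConstraint(BaseModel):
    quantity: float
    unit: Literal["day", "week", "month", "year"]
    anchor: str = "index date"


class ExtractionRecord(BaseModel):
    """The seven structured elements extracted from one simplified criterion."""

    trial_id: str = ""
    criterion_index: int = 0
    polarity: Literal["inclusion", "exclusion"] = "inclusion"
    text: str = ""
    clinical_terms: list[str] = Field(default_factory=list)
    terminology_system: Optional[Literal["SNOMED CT", "ICD-10", "RxNorm", "LOINC"]] = None
    codes: list[str] = Field(default_factory=list)
    value: Optional[ValueConstraint] = None
    attributes: list[str] = Field(default_factory=list)
    temporal: Optional[TemporalConstraint] = None
    negation: bool = False

    @model_validator(mode="after")
    def _codes_need_system(self):
        if self.codes and self.terminology_system is None:
            raise ValueError("codes present without a terminology system")
        return self


@dataclass(frozen=True)
class BackendContract:
    """A pluggable text-model backend: named, JSON-in/JSON-out, per task tag."""

    name: str
    transform: Callable[[str, dict[str, Any]], dict[str, Any]]
    deterministic: bool = True


# ---------------------------------------------------------------------------
# Tokenizer (the token measure used by all stage statistics)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def token_count(text: str) -> int:
    """Whitespace-delimited count after isolating punctuation as tokens."""
    return len(_TOKEN.findall(text))


# ---------------------------------------------------------------------------
# Stage 1: segmentation rules
# ---------------------------------------------------------------------------

_BULLET = re.compile(r"^\s*(?:\d+\s*[\.\):]|[A-Za-z]\s*[\.\)]|[-*•·])\s+")
_NUMBERED = re.compile(r"^\s*\d+\s*[\.\):]\s+")
_LETTERED = re.compile(r"^\s*[A-Za-z]\s*[\.\)]\s+")
_INLINE_SUBITEMS = re.compile(r"^(?P<parent>.*?:)\s*(?P<items>a\s*[\.\)].+)$", re.IGNORECASE)
_SUBITEM_SPLIT = re.compile(r";?\s*\b[a-z]\s*[\.\)]\s*")


def _rules_segment(block: str) -> list[str]:
    items: list[str] = []
    prefix = ""
    for raw in block.splitlines() or [block]:
        line = raw.strip()
        if not line:
            continue
        m = _INLINE_SUBITEMS.match(line)
        if m and _SUBITEM_SPLIT.search(m.group("items")[1:]):
            parent = _BULLET.sub("", m.group("parent")).strip()
            for sub in _SUBITEM_SPLIT.split(m.group("items")):
                sub = sub.strip(" ;.")
                if sub:
                    items.append(f"{parent} {sub}".strip())
            prefix = ""
            continue
        stripped = _BULLET.sub("", line).strip()
        if stripped.endswith(":"):
            prefix = stripped
            continue
        if _LETTERED.match(line) and prefix:
            items.append(f"{prefix} {stripped}".strip())
            continue
        prefix = ""
        items.append(stripped)
    if not items and block.strip():
        items = [block.strip()]
    return items


# ---------------------------------------------------------------------------
# Stage 2: filtration rules (non-queryable criteria)
# ---------------------------------------------------------------------------

# Reason code -> cue pattern. The published example names consent; the rest
# are the standard trial-administrative criteria that have no CDM footprint.
# User-extensible: pass an extended mapping to filter_queryable.
NON_QUERYABLE_RULES: dict[str, re.Pattern] = {
    "consent": re.compile(r"informed consent|consent form|written consent|able to consent", re.I),
    "willingness": re.compile(
        r"\bwilling(?:ness)?\b|able to comply|ability to comply|compli(?:ance|ant) with (?:the )?(?:protocol|study)",
        re.I,
    ),
    "investigator_judgment": re.compile(
        r"(?:opinion|judgment|discretion) of the investigator|investigator'?s (?:opinion|judgment|discretion)",
        re.I,
    ),
    "contraception": re.compile(r"contracept|birth control", re.I),
    "co_enrollment": re.compile(
        r"(?:participat\w+|enroll\w+) in (?:any |an ?)?other (?:clinical )?(?:trial|study)"
        r"|another (?:clinical )?(?:trial|study)|concurrent enrollment",
        re.I,
    ),
}


def _rules_filter(text: str, rules: dict[str, re.Pattern] | None = None) -> tuple[bool, str | None]:
    for reason, pattern in (rules or NON_QUERYABLE_RULES).items():
        if pattern.search(text):
            return False, reason
    return True, None


# ---------------------------------------------------------------------------
# Stage 3: simplification rules
# ---------------------------------------------------------------------------

_NUMBER_WORDS = {
    "one": "1", "two": "2", "three": "3", "four": "4", "five": "5", "six": "6",
    "seven": "7", "eight": "8", "nine": "9", "ten": "10", "eleven": "11",
    "twelve": "12", "eighteen": "18", "twenty": "20", "thirty": "30",
    "sixty": "60", "ninety": "90",
}

_PARENTHETICAL = re.compile(r"\s*\([^()]*\)")
_TIME_UNIT = r"(day|week|month|year)s?"
_REWRITES: list[tuple[re.Pattern, str]] = [
    # temporal phrases -> "≤/≥ N unit" form
    (re.compile(rf"\b(?:with)?in (?:the )?(?:past|last|previous|prior)?\s*(\d+)\s*{_TIME_UNIT}\b", re.I),
     "≤ \\1 \\2s"),
    (re.compile(rf"\b(?:during|over) the (?:past|last|previous)\s*(\d+)\s*{_TIME_UNIT}\b", re.I),
     "≤ \\1 \\2s"),
    (re.compile(rf"\b(?:at least|more than)\s*(\d+)\s*{_TIME_UNIT} (?:ago|prior|before|earlier)\b", re.I),
     "≥ \\1 \\2s"),
    # age phrasing
    (re.compile(r"\bage[d]?\s+(\d+)(?:\s*years?)?(?:\s*of age)?\s*(?:or|and) older\b", re.I),
     "age ≥ \\1 years"),
    (re.compile(r"\bage[d]?\s+(\d+)(?:\s*years?)?(?:\s*of age)?\s*(?:or|and) younger\b", re.I),
     "age ≤ \\1 years"),
    (re.compile(r"\b(\d+)\s*years?(?:\s*of age)?\s*or older\b", re.I), "≥ \\1 years"),
    (re.compile(r"\b(\d+)\s*years?(?:\s*of age)?\s*or younger\b", re.I), "≤ \\1 years"),
    # comparator phrases -> symbols
    (re.compile(r"\bgreater than or equal to\b", re.I), "≥"),
    (re.compile(r"\bless than or equal to\b", re.I), "≤"),
    (re.compile(r"\bgreater than\b", re.I), ">"),
    (re.compile(r"\bless than\b", re.I), "<"),
    (re.compile(r"\bat least\b", re.I), "≥"),
    (re.compile(r"\bat most\b", re.I), "≤"),
    (re.compile(r"\bno more than\b", re.I), "≤"),
    (re.compile(r"\bno less than\b", re.I), "≥"),
    (re.compile(r"\bequal to or (?:above|greater)\b", re.I), "≥"),
    # courtesy lead-ins with no clinical content
    (re.compile(r"^\s*(?:patients?|subjects?|participants?)\s+(?:must|should|will)\s+(?:have|be)\s+", re.I), ""),
    (re.compile(r"^\s*(?:patients?|subjects?|participants?)\s+(?:with|who have|who are)\s+", re.I), ""),
    (re.compile(r"^\s*must\s+(?:have|be)\s+", re.I), ""),
]


def _rules_simplify(text: str) -> str:
    out = _PARENTHETICAL.sub("", text)
    for word, digit in _NUMBER_WORDS.items():
        out = re.sub(rf"\b{word}\b", digit, out, flags=re.I)
    for pattern, repl in _REWRITES:
        out = pattern.sub(repl, out)
    out = re.sub(r"\s+", " ", out).strip(" \t,;.")
    # singular units after "1"
    out = re.sub(r"\b1 (day|week|month|year)s\b", r"1 \1", out)
    if not out or token_count(out) > token_count(text):
        return text.strip()
    return out


# ---------------------------------------------------------------------------
# Element extraction rules
# ---------------------------------------------------------------------------

NEGATION_CUES = ("no history of", "without", "excluding", "absence of", "no evidence of")

_CMP_MAP = {"<=": "≤", ">=": "≥", "=<": "≤", "=>": "≥"}
_VALUE = re.compile(
    r"(?P<cmp><=|>=|=<|=>|[<>=≤≥])\s*(?P<num>\d+(?:\.\d+)?)\s*"
    r"(?P<unit>%|[A-Za-zµ][\w%]*(?:/[A-Za-z]+)?)?"
)
_TIME_UNITS = {"day", "days", "week", "weeks", "month", "months", "year", "years"}
_SYSTEMS = {
    "SNOMED CT": re.compile(r"\bsnomed(?:\s*ct)?\b", re.I),
    "ICD-10": re.compile(r"\bicd-?10\b", re.I),
    "RxNorm": re.compile(r"\brxnorm\b", re.I),
    "LOINC": re.compile(r"\bloinc\b", re.I),
}
_ICD_CODE = re.compile(r"\b[A-Z]\d{2}(?:\.\d{1,2})?\b")
ATTRIBUTE_WORDS = (
    "severe", "mild", "moderate", "acute", "chronic", "uncontrolled", "active",
    "recurrent", "advanced", "metastatic", "symptomatic", "unstable",
)


def _singular(unit: str) -> str:
    return unit[:-1] if unit.endswith("s") else unit


def _rules_extract(payload: dict[str, Any]) -> dict[str, Any]:
    text = payload["text"]
    lower = text.lower()
    record: dict[str, Any] = {
        "trial_id": payload.get("trial_id", ""),
        "criterion_index": payload.get("criterion_index", 0),
        "polarity": payload.get("polarity", "inclusion"),
        "text": text,
        "clinical_terms": [],
        "codes": [],
        "attributes": [],
        "negation": False,
    }

    negation = False
    stripped = text
    for cue in NEGATION_CUES:
        idx = lower.find(cue)
        if idx >= 0:
            negation = True
            stripped = (text[:idx] + text[idx + len(cue):]).strip(" ,;:")
            break
    record["negation"] = negation

    value = None
    temporal = None
    remainder = stripped
    for m in _VALUE.finditer(stripped):
        unit = (m.group("unit") or "").strip()
        cmp_ = _CMP_MAP.get(m.group("cmp"), m.group("cmp"))
        is_time = unit.lower() in _TIME_UNITS
        age_context = "age" in stripped[: m.start()].lower()
        if is_time and not age_context and temporal is None:
            temporal = {
                "quantity": float(m.group("num")),
                "unit": _singular(unit.lower()),
                "anchor": "index date",
            }
            remainder = remainder.replace(m.group(0), " ", 1)
        elif value is None:
            value = {"comparator": cmp_, "number": float(m.group("num")), "unit": unit}
            remainder = remainder.replace(m.group(0), " ", 1)
    record["value"] = value
    record["temporal"] = temporal

    system = None
    for name, pattern in _SYSTEMS.items():
        if pattern.search(text):
            system = name
            break
    record["terminology_system"] = system
    if system:
        record["codes"] = _ICD_CODE.findall(stripped)

    terms = []
    for phrase in re.split(r"\s+(?:and|or)\s+|[,;]", remainder):
        phrase = re.sub(r"[<>=≤≥]", " ", phrase)
        phrase = re.sub(r"\s+", " ", phrase).strip(" .,:;-")
        phrase = re.sub(r"^(?:of|with|the|a|an|on|for|to|in)\s+", "", phrase, flags=re.I)
        phrase = re.sub(r"\s+(?:of|with|the|a|an|on|for|to|in)$", "", phrase, flags=re.I)
        if phrase and not phrase.isdigit():
            terms.append(phrase)
    if not terms:
        fallback = re.sub(r"\s+", " ", remainder).strip(" .,:;") or text.strip()
        terms = [fallback]
    record["clinical_terms"] = terms
    record["attributes"] = [w for w in ATTRIBUTE_WORDS if re.search(rf"\b{w}\b", lower)]
    return record


# ---------------------------------------------------------------------------
# The default deterministic backend
# ---------------------------------------------------------------------------


def _rules_transform(task: str, payload: dict[str, Any]) -> dict[str, Any]:
    if task == "segment":
        return {"criteria": _rules_segment(payload["block"])}
    if task == "filter":
        queryable, reason = _rules_filter(payload["text"], payload.get("rules"))
        return {"queryable": queryable, "reason": reason}
    if task == "simplify":
        return {"text": _rules_simplify(payload["text"])}
    if task == "extract":
        return _rules_extract(payload)
    raise InputError(f"unknown task {task!r}")


RULES_BACKEND = BackendContract(name="rules", transform=_rules_transform, deterministic=True)


# ---------------------------------------------------------------------------
# Public stage operations
# ---------------------------------------------------------------------------


def segment(
    block: str,
    trial_id: str = "",
    polarity: Literal["inclusion", "exclusion"] = "inclusion",
    backend: BackendContract | None = None,
    start_index: int = 0,
) -> list[Criterion]:
    """Split a free-text criteria block into individual criteria."""
    if not block or not block.strip():
        raise InputError("criteria block must be nonempty")
    backend = backend or RULES_BACKEND
    out = backend.transform("segment", {"block": block})
    texts = out.get("criteria")
    if not isinstance(texts, list) or not all(isinstance(t, str) for t in texts):
        raise SchemaValidationError(f"backend {backend.name!r}: segment output malformed")
    return [
        Criterion(
            trial_id=trial_id,
            index=start_index + i,
            polarity=polarity,
            raw_text=block,
            segmented_text=t,
            token_counts={"segmentation": token_count(t)},
        )
        for i, t in enumerate(texts)
    ]


def filter_queryable(
    criteria: list[Criterion],
    backend: BackendContract | None = None,
    rules: dict[str, re.Pattern] | None = None,
) -> list[Criterion]:
    """Annotate criteria as queryable or not; ordering preserved."""
    backend = backend or RULES_BACKEND
    for crit in criteria:
        out = backend.transform("filter", {"text": crit.segmented_text, "rules": rules})
        if not isinstance(out.get("queryable"), bool):
            raise SchemaValidationError(f"backend {backend.name!r}: filter output malformed")
        crit.queryable = out["queryable"]
        crit.non_queryable_reason = out.get("reason")
        if crit.queryable:
            crit.token_counts["filtering"] = token_count(crit.segmented_text)
    return criteria


def simplify(criterion: Criterion, backend: BackendContract | None = None) -> Criterion:
    """Normalize temporal/comparator phrasing; never increases token count."""
    if not criterion.queryable:
        raise InputError("only queryable criteria are simplified")
    backend = backend or RULES_BACKEND
    out = backend.transform("simplify", {"text": criterion.segmented_text})
    text = out.get("text")
    if not isinstance(text, str) or not text:
        raise SchemaValidationError(f"backend {backend.name!r}: simplify output malformed")
    if token_count(text) > criterion.token_counts.get("filtering", token_count(criterion.segmented_text)):
        text = criterion.segmented_text  # backend guard: reject token inflation
    criterion.simplified_text = text
    criterion.token_counts["simplification"] = token_count(text)
    return criterion


def extract_elements(criterion: Criterion, backend: BackendContract | None = None) -> ExtractionRecord:
    """Extract the seven structured elements from a simplified criterion.

    Backend output is validated against the record schema; invalid output
    raises :class:`SchemaValidationError` so it never propagates downstream.
    """
    if criterion.simplified_text is None:
        raise InputError("criterion must be simplified before extraction")
    backend = backend or RULES_BACKEND
    payload = {
        "text": criterion.simplified_text,
        "trial_id": criterion.trial_id,
        "criterion_index": criterion.index,
        "polarity": criterion.polarity,
    }
    out = backend.transform("extract", payload)
    try:
        return ExtractionRecord.model_validate(out)
    except Exception as exc:
        raise SchemaValidationError(f"backend {backend.name!r}: extraction output invalid: {exc}") from exc


def percent_reduction(initial_tokens: float, final_tokens: float) -> float:
    """Percent token reduction 100 × (1 − final/initial)."""
    if initial_tokens <= 0:
        raise InputError("initial token count must be positive")
    return 100.0 * (1.0 - final_tokens / initial_tokens)


def preprocess_trial(
    trial: dict[str, Any], backend: BackendContract | None = None
) -> tuple[list[Criterion], dict[str, Any]]:
    """Run the full three-stage pipeline on one trial record.

    *trial* is ``{"trial_id": str, "inclusion": block or [blocks],
    "exclusion": block or [blocks]}``. Returns the annotated criteria and
    per-stage statistics (criterion counts, token totals/means, and the
    percent token reduction from segmentation to simplification).
    """
    backend = backend or RULES_BACKEND
    trial_id = trial.get("trial_id", "")
    criteria: list[Criterion] = []
    for polarity in ("inclusion", "exclusion"):
        blocks = trial.get(polarity) or []
        if isinstance(blocks, str):
            blocks = [blocks]
        for block in blocks:
            criteria.extend(
                segment(block, trial_id=trial_id, polarity=polarity, backend=backend,
                        start_index=len(criteria))
            )
    if not criteria:
        raise InputError(f"trial {trial_id!r} has no criteria")
    filter_queryable(criteria, backend=backend)
    retained = [c for c in criteria if c.queryable]
    for crit in retained:
        simplify(crit, backend=backend)

    def _stage(stage: str, subset: list[Criterion]) -> dict[str, float]:
        totals = [c.token_counts[stage] for c in subset]
        return {
            "n_criteria": len(subset),
            "total_tokens": int(sum(totals)),
            "mean_tokens": (sum(totals) / len(subset)) if subset else 0.0,
        }

    stats = {
        "segmentation": _stage("segmentation", criteria),
        "filtering": _stage("filtering", retained),
        "simplification": _stage("simplification", retained),
    }
    initial = stats["segmentation"]["total_tokens"]
    final = stats["simplification"]["total_tokens"]
    stats["token_reduction_pct"] = percent_reduction(initial, final) if initial else 0.0
    return criteria, stats
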