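"""Evaluation statistics for the pipeline and its audits.

Covers the rate arithmetic (generation, hallucination, and their product the
effective-SQL rate), binomial proportions with 95% confidence intervals,
paired-outcome comparison of two mapping systems (accuracy, rescue rate,
McNemar's test on the discordant cells), cohort set-concordance (Jaccard
index and overlap coefficient over patient-ID sets), and dual-rater score
aggregation with Cohen's kappa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from .errors import DegenerateInputError, InputError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RateReport:
    numerator: int
    denominator: int
    rate: float
    ci95: tuple[float, float]

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


@dataclass(frozen=True)
class PairedMappingTable:
    """2×2 paired-correctness table for two mapping systems on the same terms."""

    both_correct: int
    sys1_only: int
    sys2_only: int
    both_wrong: int

    def __post_init__(self) -> None:
        if min(self.both_correct, self.sys1_only, self.sys2_only, self.both_wrong) < 0:
            raise InputError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.both_correct + self.sys1_only + self.sys2_only + self.both_wrong


@dataclass(frozen=True)
class CohortPairMetrics:
    size_a: int
    size_b: int
    intersection: int
    jaccard: float
    overlap: float


@dataclass(frozen=True)
class ScoreItem:
    criterion_id: str
    dimension: str
    rater1: int
    rater2: int

    def __post_init__(self) -> None:
        for r in (self.rater1, self.rater2):
            if not (1 <= r <= 4):
                raise InputError("scores must be integers on the 1-4 scale")

    @property
    def mean(self) -> float:
        return (self.rater1 + self.rater2) / 2.0


@dataclass
class ExpertScoreSheet:
    items: list[ScoreItem] = field(default_factory=list)


def effective_rate(generation_rate: float, hallucination_rate: float) -> float:
    """Effective SQL rate = generation rate × (1 − hallucination rate)."""
    for name, x in (("generation_rate", generation_rate), ("hallucination_rate", hallucination_rate)):
        if not (0.0 <= x <= 1.0):
            raise InputError(f"{name} must be in [0, 1], got {x}")
    return generation_rate * (1.0 - hallucination_rate)


def rate_with_ci(k: int, n: int, method: str = "wald") -> RateReport:
    """Binomial proportion k/n with a 95% CI (Wald default, Wilson optional).

    The Wald interval is p ± z·√(p(1−p)/n), clipped to [0, 1].
    """
    if n <= 0:
        raise InputError("denominator must be positive")
    if not (0 <= k <= n):
        raise InputError("numerator must satisfy 0 <= k <= n")
    p = k / n
    if method == "wald":
        half = Z_95 * math.sqrt(p * (1.0 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    elif method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    else:
        raise InputError(f"unknown CI method {method!r}")
    return RateReport(numerator=k, denominator=n, rate=p, ci95=(lo, hi))


def mapping_accuracy(
    table: PairedMappingTable,
    domain_strata: Mapping[str, tuple[int, int]] | None = None,
) -> dict:
    """Per-system accuracies, rescue rate, and optional per-domain rates.

    System 1 accuracy = (both_correct + sys1_only)/total; the rescue rate is
    the share of system-2 failures that system 1 recovered,
    sys1_only / (sys1_only + both_wrong).
    """
    if table.total == 0:
        raise InputError("empty paired table")
    sys1 = rate_with_ci(table.both_correct + table.sys1_only, table.total)
    sys2 = rate_with_ci(table.both_correct + table.sys2_only, table.total)
    sys2_failures = table.sys1_only + table.both_wrong
    rescue = rate_with_ci(table.sys1_only, sys2_failures) if sys2_failures else None
    by_domain = {}
    if domain_strata:
        for domain, (correct, total) in domain_strata.items():
            by_domain[domain] = rate_with_ci(correct, total)
    return {"sys1": sys1, "sys2": sys2, "rescue": rescue, "by_domain": by_domain}


def mcnemar_test(
    table: PairedMappingTable, correction: bool = False, exact: bool = False
) -> tuple[float, float]:
    """McNemar's test on the discordant cells b = sys1_only, c = sys2_only.

    Default is the uncorrected chi-square (|b−c|)²/(b+c) with df=1;
    ``correction=True`` subtracts the 0.5 continuity correction;
    ``exact=True`` uses the exact binomial test on min(b, c) of b+c trials.
    """
    b, c = table.sys1_only, table.sys2_only
    if b + c == 0:
        raise DegenerateInputError("no discordant pairs; McNemar statistic undefined")
    if exact:
        result = sps.binomtest(min(b, c), b + c, 0.5, alternative="two-sided")
        return float(min(b, c)), float(result.pvalue)
    diff = abs(b - c) - (0.5 if correction else 0.0)
    diff = max(diff, 0.0)
    statistic = diff**2 / (b + c)
    p = float(sps.chi2.sf(statistic, df=1))
    return float(statistic), p


def cohort_concordance(set_a: Iterable[int], set_b: Iterable[int]) -> CohortPairMetrics:
    """Jaccard index and overlap coefficient of two patient-ID sets.

    If either set is empty both metrics are reported as 0 (with a warning):
    a retrieval that matched nobody has zero concordance by convention.
    """
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    if not a or not b:
        warnings.warn("empty cohort: concordance metrics reported as 0", stacklevel=2)
        return CohortPairMetrics(len(a), len(b), inter, 0.0, 0.0)
    jaccard = inter / len(a | b)
    overlap = inter / min(len(a), len(b))
    return CohortPairMetrics(len(a), len(b), inter, jaccard, overlap)


def aggregate_expert_scores(sheet: ExpertScoreSheet) -> dict:
    """Dimension-level mean ± sd of item means, plus unweighted Cohen's kappa.

    Item scores are the average of the two raters; kappa is computed on the
    raw 4-level labels across all items.
    """
    if not sheet.items:
        raise InputError("score sheet has no items")
    r1 = [it.rater1 for it in sheet.items]
    r2 = [it.rater2 for it in sheet.items]
    if r1 == r2 and len(set(r1)) == 1:
        kappa = 1.0  # both raters constant and identical: agreement is total
    else:
        kappa = float(cohen_kappa_score(r1, r2, labels=[1, 2, 3, 4]))
    dims: dict[str, list[float]] = {}
    for it in sheet.items:
        dims.setdefault(it.dimension, []).append(it.mean)
    rollup = {}
    for dim, means in dims.items():
        n = len(means)
        mu = sum(means) / n
        sd = math.sqrt(sum((m - mu) ** 2 for m in means) / (n - 1)) if n > 1 else 0.0
        rollup[dim] = {"mean": mu, "sd": sd, "n_items": n}
    return {"dimensions": rollup, "kappa": kappa}
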