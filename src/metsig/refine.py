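"""Multi-cohort signature refinement.

Two stages mirror the focused-signature construction: (1) keep the genes
whose one-gene signature associates with survival in the same direction in
every cohort at some quantile breakdown; (2) enumerate subsets of those
candidates (largest first, then lexicographic) and return the first subset
whose sum z-score signature is significant with a concordant survival
direction in all cohorts at the target breakdown.  The search is
exploratory: alpha is applied per test with no multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .datatypes import ExpressionCohort, IntegratedSignature
from .exceptions import MetsigError
from .signature import signature_score
from .survival import logrank_test, partition_by_score, threshold_scan

logger = logging.getLogger(__name__)

MAX_CANDIDATES = 20  # enumeration guard: 2^20 - 1 subsets at most


@dataclass
class RefinementResult:
    candidate_genes: list[str]
    chosen_subset: list[str]
    per_cohort: pd.DataFrame  # cohort_id, f_low, f_high, chi_square, p, direction
    subsets_evaluated: int
    all_passing: list[tuple[str, ...]] = field(default_factory=list)


def _cohort_scores(cohort: ExpressionCohort, signature: IntegratedSignature) -> pd.Series:
    surv = cohort.survival_records()
    scores = signature_score(cohort.expression[list(surv.index)], signature)["score"]
    return scores


def direction_consistent_genes(
    signature: IntegratedSignature,
    cohorts: list[ExpressionCohort],
    grid=None,
    alpha: float = 0.05,
    require_all_grid_points: bool = False,
) -> list[str]:
    """Genes prognostic in the same direction in every cohort.

    Each gene is scored as a one-gene signature (keeping its integrated
    direction) and scanned over the threshold grid per cohort.  A gene is
    kept iff every cohort has at least one grid point with p < alpha
    (or all grid points, with ``require_all_grid_points``) and the survival
    direction — the sign of observed-minus-expected events in the
    high-score group — agrees across all significant grid points of all
    cohorts.  Genes absent from any cohort are dropped with a warning.
    """
    if len(cohorts) < 2:
        raise MetsigError("direction consistency needs >= 2 cohorts")
    if len(signature) == 0:
        raise MetsigError("empty signature")

    kept: list[str] = []
    for gene in signature.genes:
        if any(gene not in c.expression.index for c in cohorts):
            logger.warning("gene %s absent from at least one cohort; dropped", gene)
            continue
        one_gene = signature.subset([gene])
        directions: set[int] = set()
        ok = True
        for cohort in cohorts:
            surv = cohort.survival_records()
            scores = _cohort_scores(cohort, one_gene)
            scan = threshold_scan(scores, surv, grid)
            usable = scan[~scan["failed"]]
            significant = usable[usable["p"] < alpha]
            need = len(usable) if require_all_grid_points else 1
            if len(significant) < need or len(usable) == 0:
                ok = False
                break
            directions.update(int(d) for d in significant["direction"])
        if ok and len(directions) == 1 and 0 not in directions:
            kept.append(gene)
    return kept


def enumerate_subsets(candidates: list[str]):
    """All non-empty subsets, size-descending then lexicographic."""
    ordered = sorted(candidates)
    for size in range(len(ordered), 0, -1):
        yield from combinations(ordered, size)


def combinatorial_subset_search(
    candidates: list[str],
    signature: IntegratedSignature,
    cohorts: list[ExpressionCohort],
    breakdown: tuple[float, float] = (0.25, 0.75),
    alpha: float = 0.05,
    max_size: int | None = None,
    collect_all: bool = False,
) -> RefinementResult:
    """First subset significant with concordant direction in all cohorts.

    Subsets are enumerated deterministically (size-descending, then
    lexicographic by gene symbol); each is scored by the sum z-score
    machinery in every cohort, partitioned at ``breakdown`` and tested by
    log-rank.  If no subset passes, ``chosen_subset`` is empty and the
    evaluation log is still returned.
    """
    if not candidates:
        raise MetsigError("no candidate genes to search")
    if max_size is None and len(candidates) > MAX_CANDIDATES:
        raise MetsigError(
            f"{len(candidates)} candidates exceed the enumeration guard of "
            f"{MAX_CANDIDATES}; set max_size to bound the search"
        )
    missing = [g for g in candidates if g not in set(signature.genes)]
    if missing:
        raise MetsigError(f"candidates not in the signature: {missing}")

    f_low, f_high = breakdown
    evaluated = 0
    chosen: tuple[str, ...] | None = None
    chosen_rows: list[tuple] = []
    passing: list[tuple[str, ...]] = []

    for subset in enumerate_subsets(list(candidates)):
        if max_size is not None and len(subset) > max_size:
            continue
        evaluated += 1
        rows = []
        directions: set[int] = set()
        ok = True
        for cohort in cohorts:
            try:
                surv = cohort.survival_records()
                scores = _cohort_scores(cohort, signature.subset(subset))
                groups = partition_by_score(scores, f_low, f_high)
                res = logrank_test(groups, surv)
            except MetsigError as exc:
                logger.debug("subset %s failed in cohort %s: %s", subset, cohort.cohort_id, exc)
                ok = False
                break
            rows.append(
                (cohort.cohort_id, f_low, f_high, res.chi_square, res.p, res.direction)
            )
            if not (res.p < alpha and res.direction != 0):
                ok = False
                break
            directions.add(res.direction)
        if ok and len(directions) == 1:
            passing.append(subset)
            if chosen is None:
                chosen = subset
                chosen_rows = rows
                if not collect_all:
                    break

    per_cohort = pd.DataFrame(
        chosen_rows,
        columns=["cohort_id", "f_low", "f_high", "chi_square", "p", "direction"],
    )
    if chosen is None:
        logger.warning(
            "no subset of %d candidates passed in all cohorts (%d evaluated)",
            len(candidates),
            evaluated,
        )
    return RefinementResult(
        candidate_genes=sorted(candidates),
        chosen_subset=list(chosen) if chosen else [],
        per_cohort=per_cohort,
        subsets_evaluated=evaluated,
        all_passing=passing,
    )


def audit_chosen_subset(
    result: RefinementResult,
    signature: IntegratedSignature,
    cohorts: list[ExpressionCohort],
    breakdown: tuple[float, float] = (0.25, 0.75),
    alpha: float = 0.05,
) -> bool:
    """Re-evaluate the chosen subset from scratch (self-consistency audit)."""
    if not result.chosen_subset:
        return False
    f_low, f_high = breakdown
    directions: set[int] = set()
    for cohort in cohorts:
        surv = cohort.survival_records()
        scores = _cohort_scores(cohort, signature.subset(result.chosen_subset))
        res = logrank_test(partition_by_score(scores, f_low, f_high), surv)
        if not (res.p < alpha and res.direction != 0):
            return False
        directions.add(res.direction)
    return len(directions) == 1
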