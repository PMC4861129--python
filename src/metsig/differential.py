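"""Two-group differential testing with Benjamini-Hochberg FDR control.

The same machinery serves two feature classes with different significance
rules: metabolites are called at FDR q <= 0.15; transcripts at raw p < 0.05
combined with a twofold change gate (|log2 mean difference| >= 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GROUP_BENIGN, GROUP_TUMOR, SampleAnnotation
from .exceptions import MetsigError

logger = logging.getLogger(__name__)

RULE_METABOLITE = "metabolite"
RULE_TRANSCRIPT = "transcript"

#: minimum non-missing observations per group for a feature to be testable
MIN_GROUP_N = 3


@dataclass
class DifferentialRule:
    """Significance rule applied after testing."""

    kind: str
    fdr_q: float = 0.15  # metabolite rule: q <= fdr_q (inclusive)
    alpha_p: float = 0.05  # transcript rule: p < alpha_p (strict)
    log2fc_gate: float = 1.0  # transcript rule: |mean_diff| >= gate

    def is_significant(self, p: float, q: float, mean_diff: float) -> bool:
        if self.kind == RULE_METABOLITE:
            return bool(q <= self.fdr_q)
        if self.kind == RULE_TRANSCRIPT:
            return bool(p < self.alpha_p and abs(mean_diff) >= self.log2fc_gate)
        raise ValueError(f"unknown rule kind {self.kind!r}")


def two_sample_ttest(a, b, variant: str = "pooled"):
    """Two-sided two-sample t-test.

    Returns ``(t_stat, df, p, mean_diff)`` with ``mean_diff = mean(a) -
    mean(b)``.  ``variant`` selects the classical pooled-variance statistic
    or Welch's unequal-variance form.  Identical constant groups give
    ``t=0, p=1``; a zero pooled variance with unequal means gives ``p=0``
    with a degeneracy warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise MetsigError(f"two_sample_ttest needs >= 2 values per group, got {n1} and {n2}")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    mean_diff = float(a.mean() - b.mean())
    v1 = float(a.var(ddof=1))
    v2 = float(b.var(ddof=1))

    if variant == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = np.sqrt(se2_1 + se2_2)
        if se > 0:
            df = (se2_1 + se2_2) ** 2 / (
                se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
            )
        else:
            df = float(n1 + n2 - 2)

    if se == 0:
        if mean_diff == 0:
            return 0.0, df, 1.0, 0.0
        warnings.warn(
            "degenerate t-test: zero within-group variance with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.inf if mean_diff > 0 else -np.inf
        return float(t), df, 0.0, mean_diff

    t = mean_diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), mean_diff


def ttest_matrix(a: np.ndarray, b: np.ndarray):
    """Vectorized pooled-variance t-test over feature rows (no missing data).

    ``a``/``b`` are 2-D arrays (features x samples).  Returns arrays
    ``(t, df, p, mean_diff)``.  Used by calibration loops; the scalar
    :func:`two_sample_ttest` is the contract-bearing API.
    """
    n1, n2 = a.shape[1], b.shape[1]
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = float(n1 + n2 - 2)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.full_like(t, df), p, mean_diff


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    bad = np.where((p < 0) | (p > 1) | np.isnan(p))[0]
    if bad.size:
        raise MetsigError(f"p-value outside [0, 1] at index {int(bad[0])}: {p[bad[0]]!r}")
    m = p.size
    if m == 0:
        return np.array([], dtype=float)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def differential_features(
    matrix: pd.DataFrame,
    annot: SampleAnnotation,
    rule: DifferentialRule | str,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Test every feature for a tumor-vs-benign difference.

    ``matrix`` is features x samples in log2 units (normalized metabolites
    or expression).  Features with fewer than ``MIN_GROUP_N`` non-missing
    values in either group are excluded from testing.  Returns a DataFrame
    indexed by feature id with columns ``mean_diff, t, df, p, q,
    significant, direction`` (direction: up = higher in tumor).
    """
    if isinstance(rule, str):
        rule = DifferentialRule(kind=rule)
    tumor_ids = [s for s in annot.ids_in_group(GROUP_TUMOR) if s in matrix.columns]
    benign_ids = [s for s in annot.ids_in_group(GROUP_BENIGN) if s in matrix.columns]
    if len(tumor_ids) < 2 or len(benign_ids) < 2:
        raise MetsigError(
            f"need >= 2 usable samples per group, got {len(tumor_ids)} tumor "
            f"and {len(benign_ids)} benign"
        )

    a_all = matrix[tumor_ids]
    b_all = matrix[benign_ids]
    testable = (a_all.notna().sum(axis=1) >= MIN_GROUP_N) & (
        b_all.notna().sum(axis=1) >= MIN_GROUP_N
    )
    excluded = matrix.index[~testable].tolist()
    if excluded:
        logger.info("excluding %d feature(s) with insufficient data", len(excluded))

    rows = []
    for feature in matrix.index[testable]:
        t, df, p, mean_diff = two_sample_ttest(
            a_all.loc[feature], b_all.loc[feature], variant=variant
        )
        rows.append((feature, mean_diff, t, df, p))
    result = pd.DataFrame(
        rows, columns=["feature_id", "mean_diff", "t", "df", "p"]
    ).set_index("feature_id")
    result["q"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    result["significant"] = [
        rule.is_significant(row.p, row.q, row.mean_diff) for row in result.itertuples()
    ]
    result["direction"] = np.where(result["mean_diff"] >= 0, "up", "down")
    return result


def significant_features(result: pd.DataFrame) -> list[str]:
    return list(result.index[result["significant"]])
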