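"""Integrated gene-signature construction and sum z-score activity scoring.

The integrated signature is the intersection of metabolite-derived genes
with transcriptome-differential genes, carrying the transcript log2
fold-change; its direction partition (induced = positive fold-change,
repressed = negative) drives the per-specimen activity score

    S_s = sum_{g induced} z_{g,s} - sum_{g repressed} z_{g,s}

with z computed gene-wise across the cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import IntegratedSignature
from .exceptions import MetsigError

logger = logging.getLogger(__name__)


def integrate_signature(mapped_genes, transcript_diff: pd.DataFrame) -> IntegratedSignature:
    """Intersect metabolite-mapped genes with significant transcripts.

    ``transcript_diff`` must come from the transcript differential rule
    (twofold change and p < 0.05).  The signature carries the transcript
    log2 fold-change; an empty intersection yields an empty signature with
    a warning (scoring then refuses).
    """
    mapped = frozenset(g.upper() for g in mapped_genes)
    significant = transcript_diff.index[transcript_diff["significant"]]
    hits = [g for g in significant if g.upper() in mapped]
    if not hits:
        logger.warning("metabolite-derived genes and differential transcripts do not intersect")
        return IntegratedSignature.from_fold_changes(pd.Series(dtype=float))
    fc = transcript_diff.loc[hits, "mean_diff"]
    fc.index = [g.upper() for g in hits]
    return IntegratedSignature.from_fold_changes(fc)


def zscore_expression(expr: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Gene-wise z-scores across the cohort.

    Uses the sample standard deviation (``ddof=1``) by default; zero-variance
    genes are excluded with a warning naming them.  Missing values are
    ignored in the gene mean/sd and stay missing in the output.
    """
    mean = expr.mean(axis=1, skipna=True)
    sd = expr.std(axis=1, ddof=ddof, skipna=True)
    degenerate = expr.index[(sd == 0) | sd.isna()].tolist()
    if degenerate:
        logger.warning("excluding zero-variance gene(s) from scoring: %s", degenerate[:10])
    keep = expr.index.difference(degenerate, sort=False)
    z = expr.loc[keep].sub(mean.loc[keep], axis=0).div(sd.loc[keep], axis=0)
    return z


def signature_score(
    expr: pd.DataFrame, signature: IntegratedSignature, ddof: int = 1
) -> pd.DataFrame:
    """Per-specimen sum z-score signature activity.

    Signature genes absent from the matrix (or excluded as zero-variance)
    are dropped with a log message, so one signature can be applied across
    platforms that measure different gene subsets.  Returns a DataFrame
    indexed by specimen id with columns ``score`` and ``n_genes_used``.

    Raises
    ------
    MetsigError
        If no signature gene is present in the matrix.
    """
    if len(signature) == 0:
        raise MetsigError("cannot score an empty signature")
    present = [g for g in signature.genes if g in expr.index]
    absent = sorted(set(signature.genes) - set(present))
    if absent:
        logger.info("signature gene(s) absent from matrix: %s", absent)
    if not present:
        raise MetsigError(f"no signature gene present in the matrix; signature: {signature.genes}")

    z = zscore_expression(expr.loc[present], ddof=ddof)
    induced = [g for g in signature.induced if g in z.index]
    repressed = [g for g in signature.repressed if g in z.index]
    if not induced and not repressed:
        raise MetsigError("all signature genes were zero-variance in this cohort")

    up_sum = z.loc[induced].sum(axis=0, skipna=True) if induced else 0.0
    down_sum = z.loc[repressed].sum(axis=0, skipna=True) if repressed else 0.0
    scores = up_sum - down_sum
    n_used = z.loc[induced + repressed].notna().sum(axis=0)
    out = pd.DataFrame({"score": scores, "n_genes_used": n_used})
    out.index.name = "specimen_id"
    return out
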