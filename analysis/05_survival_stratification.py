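"""Survival stratification of the scored cohort.

Bottom-25%/top-75% split of the 377 scored specimens, log-rank test,
continuous-score Cox fit, and the exploratory multi-threshold scan.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, STUDY

from metsig import (
    SampleAnnotation,
    cox_univariate,
    differential_features,
    generate_expression_cohort,
    generate_mapping_and_genesets,
    generate_metabolomics,
    integrate_signature,
    logrank_test,
    map_metabolites_to_genes,
    normalize_metabolites,
    partition_by_score,
    signature_score,
    significant_features,
    threshold_scan,
)


def build_scores():
    matrix, annot, _ = generate_metabolomics(STUDY)
    diff_mets = significant_features(
        differential_features(normalize_metabolites(matrix), annot, "metabolite")
    )
    mapping, _ = generate_mapping_and_genesets(STUDY)
    mapped_genes, _ = map_metabolites_to_genes(diff_mets, mapping)
    cohort, _ = generate_expression_cohort(STUDY)
    expr_annot = SampleAnnotation(cohort.clinical[["group", "cohort"]])
    tdiff = differential_features(cohort.expression, expr_annot, "transcript")
    signature = integrate_signature(mapped_genes, tdiff)
    surv = cohort.survival_records()
    scores = signature_score(cohort.expression[list(surv.index)], signature)["score"]
    return signature, scores, surv


def main():
    signature, scores, surv = build_scores()
    groups = partition_by_score(scores, 0.25, 0.75)
    res = logrank_test(groups, surv)
    beta, se, p_wald, p_score = cox_univariate(scores, surv)
    scan = threshold_scan(scores, surv)

    RESULTS.mkdir(exist_ok=True)
    scan.to_csv(RESULTS / "05_threshold_scan.tsv", sep="\t", index=False,
                float_format="%.6g")
    pd.DataFrame([{
        "n_low": len(groups.low_ids), "n_high": len(groups.high_ids),
        "logrank_chi_square": res.chi_square, "logrank_p": res.p,
        "direction": res.direction, "cox_beta": beta, "cox_se": se,
        "cox_p_wald": p_wald, "cox_p_score": p_score,
    }]).to_csv(RESULTS / "05_survival.tsv", sep="\t", index=False,
               float_format="%.6g")
    print(f"{len(signature)}-gene signature scored on {len(scores)} specimens")
    print(f"25/75 split: {len(groups.low_ids)} low vs {len(groups.high_ids)} high")
    print(f"log-rank: chi2={res.chi_square:.3f}, p={res.p:.3g}, "
          f"direction={'worse' if res.direction > 0 else 'better'} survival for high scores")
    print(f"Cox (continuous score): beta={beta:.3f} (se {se:.3f}), "
          f"Wald p={p_wald:.3g}, score p={p_score:.3g}")
    print("threshold scan:")
    print(scan[["f_low", "f_high", "n_low", "n_high", "chi_square", "p",
                "direction"]].to_string(index=False))


if __name__ == "__main__":
    main()
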