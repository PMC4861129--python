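"""End-to-end orchestration of the integrative analysis.

Stages run in the study's order: metabolite normalization, metabolite
differential testing (FDR 15%), metabolite-to-gene mapping, pathway
overrepresentation, transcript differential testing (twofold, p < 0.05),
signature integration, sum z-score scoring, quantile survival
stratification, and optionally the multi-cohort combinatorial refinement.
Each stage writes a TSV artifact and appends its row counts to a run
manifest; a failing stage halts the run with a stage-named error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata, resources
from pathlib import Path

import pandas as pd

from . import io as msio
from .config import RunConfig
from .datatypes import ExpressionCohort, IntegratedSignature
from .differential import DifferentialRule, differential_features, significant_features
from .exceptions import MetsigError, StageError
from .normalize import normalize_metabolites
from .pathways import hypergeometric_enrichment, map_metabolites_to_genes
from .refine import audit_chosen_subset, combinatorial_subset_search, direction_consistent_genes
from .signature import integrate_signature, signature_score
from .survival import logrank_test, partition_by_score, threshold_scan

logger = logging.getLogger(__name__)

_FIXTURES = {
    "table2_30gene": "table2_30gene.tsv",
    "focused_6gene": "focused_6gene.tsv",
}


def load_signature_fixture(name: str) -> IntegratedSignature:
    """Load a bundled signature fixture by name.

    ``table2_30gene`` is the 30-gene integrated metabolomic/transcriptomic
    signature with its published log2 fold-changes; ``focused_6gene`` is
    the refined 6-gene subset (directions inherited from the 30-gene set).
    """
    if name not in _FIXTURES:
        raise MetsigError(
            f"unknown signature fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    ref = resources.files("metsig.fixtures") / _FIXTURES[name]
    with resources.as_file(ref) as path:
        return msio.read_signature(path)


def load_demo_metabolite_map():
    """Bundled illustrative metabolite->gene map (synthetic, demos only)."""
    ref = resources.files("metsig.fixtures") / "demo_metabolite_gene_map.tsv"
    with resources.as_file(ref) as path:
        return msio.read_metabolite_gene_map(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute every configured stage, writing artifacts and a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("metsig")
    except metadata.PackageNotFoundError:  # running from a source tree
        version = "unknown"
    manifest = RunManifest(
        config={
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
            if k != "extra_cohorts"
        },
        package_version=version,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.config["extra_cohorts"] = [
        [str(e), str(c)] for e, c in config.extra_cohorts
    ]

    def require(path, stage: str):
        if path is None or not Path(path).exists():
            raise StageError(stage, f"required input file missing: {path}")
        manifest.input_checksums[str(path)] = _sha256(Path(path))
        return Path(path)

    def halt(stage: str, exc: Exception):
        manifest.stage_counts[f"{stage}:failed"] = 1
        manifest.write(out / "run_manifest.json")
        if isinstance(exc, StageError):
            raise exc
        raise StageError(stage, str(exc)) from exc

    # --- metabolomics arm -------------------------------------------------
    stage = "normalize"
    try:
        metab_path = require(config.metabolite_table, stage)
        annot_path = require(config.sample_annotation, stage)
        raw = msio.read_abundance_table(metab_path, dialect="metabolite")
        annot = msio.read_sample_annotation(annot_path)
        normalized = normalize_metabolites(raw)
        msio.write_abundance_table(out / "metabolites_normalized.tsv", normalized,
                                   dialect="expression")
        manifest.stage_counts["normalize:metabolites"] = len(normalized)
    except MetsigError as exc:
        halt(stage, exc)

    stage = "differential_metabolites"
    try:
        rule = DifferentialRule(kind="metabolite", fdr_q=config.fdr_metab)
        metab_diff = differential_features(normalized, annot, rule)
        metab_diff.to_csv(out / "differential_metabolites.tsv", sep="\t",
                          float_format="%.10g")
        diff_metabolites = significant_features(metab_diff)
        manifest.stage_counts["differential_metabolites:tested"] = len(metab_diff)
        manifest.stage_counts["differential_metabolites:significant"] = len(diff_metabolites)
    except MetsigError as exc:
        halt(stage, exc)

    stage = "map_genes"
    try:
        map_path = require(config.mapping_table, stage)
        mapping = msio.read_metabolite_gene_map(map_path)
        mapped_genes, provenance = map_metabolites_to_genes(diff_metabolites, mapping)
        provenance.to_csv(out / "mapped_genes.tsv", sep="\t", index=False)
        manifest.stage_counts["map_genes:genes"] = len(mapped_genes)
    except MetsigError as exc:
        halt(stage, exc)

    stage = "enrichment"
    if config.geneset_gmt is not None:
        try:
            gmt_path = require(config.geneset_gmt, stage)
            collection = msio.read_gmt(gmt_path)
            if mapped_genes and collection.sets:
                enrichment = hypergeometric_enrichment(
                    mapped_genes, collection, alpha=config.alpha_surv
                )
                enrichment.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.10g")
                manifest.stage_counts["enrichment:sets_tested"] = len(enrichment)
                manifest.stage_counts["enrichment:significant"] = int(
                    enrichment["significant"].sum()
                )
        except MetsigError as exc:
            halt(stage, exc)

    # --- transcriptomics arm ----------------------------------------------
    stage = "differential_transcripts"
    try:
        expr_path = require(config.expression_table, stage)
        clin_path = require(config.clinical_table, stage)
        cohort = msio.read_expression_cohort(expr_path, clin_path)
        from .datatypes import SampleAnnotation

        expr_annot = SampleAnnotation(cohort.clinical[["group", "cohort"]])
        rule = DifferentialRule(
            kind="transcript", alpha_p=config.p_transcript, log2fc_gate=config.log2fc_gate
        )
        transcript_diff = differential_features(cohort.expression, expr_annot, rule)
        transcript_diff.to_csv(out / "differential_transcripts.tsv", sep="\t",
                               float_format="%.10g")
        manifest.stage_counts["differential_transcripts:tested"] = len(transcript_diff)
        manifest.stage_counts["differential_transcripts:significant"] = int(
            transcript_diff["significant"].sum()
        )
    except MetsigError as exc:
        halt(stage, exc)

    stage = "integrate"
    try:
        signature = integrate_signature(mapped_genes, transcript_diff)
        msio.write_signature(out / "integrated_signature.tsv", signature)
        manifest.stage_counts["integrate:signature_genes"] = len(signature)
        if len(signature) == 0:
            raise StageError(stage, "empty integrated signature; scoring refused")
    except MetsigError as exc:
        halt(stage, exc)

    stage = "score"
    try:
        surv = cohort.survival_records()
        scores = signature_score(cohort.expression[list(surv.index)], signature)
        scores.to_csv(out / "signature_scores.tsv", sep="\t", float_format="%.10g")
        manifest.stage_counts["score:specimens"] = len(scores)
    except MetsigError as exc:
        halt(stage, exc)

    stage = "survival"
    try:
        f_low, f_high = config.breakdown
        groups = partition_by_score(scores["score"], f_low, f_high)
        res = logrank_test(groups, surv)
        scan = threshold_scan(scores["score"], surv, config.grid)
        scan.to_csv(out / "threshold_scan.tsv", sep="\t", index=False,
                    float_format="%.10g")
        pd.DataFrame(
            [
                {
                    "f_low": f_low,
                    "f_high": f_high,
                    "n_low": len(groups.low_ids),
                    "n_high": len(groups.high_ids),
                    "chi_square": res.chi_square,
                    "p": res.p,
                    "direction": res.direction,
                }
            ]
        ).to_csv(out / "survival_primary.tsv", sep="\t", index=False,
                 float_format="%.10g")
        manifest.stage_counts["survival:n_low"] = len(groups.low_ids)
        manifest.stage_counts["survival:n_high"] = len(groups.high_ids)
    except MetsigError as exc:
        halt(stage, exc)

    if config.run_refinement:
        stage = "refine"
        try:
            cohorts = [cohort]
            for i, (epath, cpath) in enumerate(config.extra_cohorts, start=2):
                epath = require(epath, stage)
                cpath = require(cpath, stage)
                cohorts.append(
                    msio.read_expression_cohort(epath, cpath, cohort_id=f"cohort{i}")
                )
            if len(cohorts) < 2:
                raise StageError(stage, "refinement needs >= 2 cohorts")
            candidates = direction_consistent_genes(
                signature, cohorts, grid=config.grid, alpha=config.alpha_surv
            )
            manifest.stage_counts["refine:candidates"] = len(candidates)
            if candidates:
                result = combinatorial_subset_search(
                    candidates,
                    signature,
                    cohorts,
                    breakdown=config.breakdown,
                    alpha=config.alpha_surv,
                    max_size=(
                        None if len(candidates) <= config.max_refine_candidates else 1
                    ),
                )
                result.per_cohort.to_csv(out / "refinement_per_cohort.tsv", sep="\t",
                                         index=False, float_format="%.10g")
                pd.Series(result.chosen_subset, name="gene_symbol").to_csv(
                    out / "refined_signature.tsv", sep="\t", index=False
                )
                manifest.stage_counts["refine:chosen_genes"] = len(result.chosen_subset)
                manifest.stage_counts["refine:subsets_evaluated"] = result.subsets_evaluated
                manifest.stage_counts["refine:audit_passed"] = int(
                    audit_chosen_subset(
                        result, signature, cohorts,
                        breakdown=config.breakdown, alpha=config.alpha_surv,
                    )
                )
        except MetsigError as exc:
            halt(stage, exc)

    manifest.write(out / "run_manifest.json")
    return manifest
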