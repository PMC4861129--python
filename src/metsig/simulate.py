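"""Synthetic study generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* a targeted-metabolomics experiment acquired under several chromatography
  methods, each with two spiked internal-standard rows, per-sample
  per-method instrument scale variation, and planted log2 tumor-vs-benign
  shifts for a subset of metabolites;
* a gene-expression cohort with planted tumor-vs-normal differential genes
  and survival times drawn from a proportional-hazards model whose log
  hazard is linear in the standardized latent activity of a planted
  up/down gene signature, with independent uniform censoring calibrated to
  a requested expected censoring fraction;
* a metabolite-to-gene map in which planted metabolites map preferentially
  onto planted differential genes, plus a chunked gene-set collection
  including the planted pathway.

All randomness flows from ``config.seed`` through per-generator independent
streams, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .config import SimulationConfig
from .datatypes import (
    ExpressionCohort,
    GeneSetCollection,
    GroundTruth,
    MetaboliteGeneMap,
    MetaboliteMatrix,
    SampleAnnotation,
)
from .exceptions import ConfigError

# independent RNG stream ids per generator
_STREAM_METAB = 1
_STREAM_EXPR = 2
_STREAM_MAP = 3

_STANDARD_BASENAMES = ("IS_ZEATIN", "IS_TRP15N2")
# log2 baselines of the two spiked standards (arbitrary instrument units)
_STANDARD_BASELINES = (5.0, 6.0)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def metabolite_names(config: SimulationConfig) -> list[str]:
    return [f"MET{i + 1:04d}" for i in range(config.n_metabolites)]


def planted_metabolites(config: SimulationConfig) -> list[str]:
    return metabolite_names(config)[: config.n_diff_metabolites]


def gene_universe(config: SimulationConfig) -> list[str]:
    """Deterministic gene-symbol universe including the signature genes."""
    generic = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    extras = [
        g
        for g in list(config.signature_genes_up) + list(config.signature_genes_down)
        if g not in set(generic)
    ]
    return generic + extras


def planted_diff_genes(config: SimulationConfig) -> dict[str, int]:
    """Planted differential genes with signs; the signature genes lead."""
    out: dict[str, int] = {}
    for g in config.signature_genes_up:
        out[g] = +1
    for g in config.signature_genes_down:
        out[g] = -1
    if config.n_diff_genes < len(out):
        raise ConfigError(
            f"n_diff_genes={config.n_diff_genes} smaller than the "
            f"{len(out)} planted signature genes"
        )
    sign = +1
    for g in gene_universe(config):
        if len(out) >= config.n_diff_genes:
            break
        if g in out:
            continue
        out[g] = sign
        sign = -sign
    return out


def generate_metabolomics(
    config: SimulationConfig,
) -> tuple[MetaboliteMatrix, SampleAnnotation, GroundTruth]:
    """Raw metabolite peak areas with internal standards and group effects.

    Raw abundance is exp2 of (per-sample per-method scale + metabolite
    baseline + planted tumor shift + Gaussian noise); each method carries
    two internal-standard rows following the same scale, so dividing by the
    per-sample standard median cancels the scale term exactly.
    """
    rng = _rng(config, _STREAM_METAB)
    samples = [f"TUM{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"BEN{i + 1:03d}" for i in range(config.n_benign)
    ]
    is_tumor = np.array([s.startswith("TUM") for s in samples])
    mets = metabolite_names(config)
    planted = set(planted_metabolites(config))
    methods = [f"M{(i % config.n_batches) + 1}" for i in range(config.n_metabolites)]

    # per-sample, per-method log2 scale factors: raw scale log-uniform in [0.5, 2]
    scale_log2 = rng.uniform(-1.0, 1.0, size=(config.n_batches, len(samples)))
    baselines = rng.uniform(3.0, 10.0, size=config.n_metabolites)

    log2_vals = np.empty((config.n_metabolites, len(samples)))
    for i, met in enumerate(mets):
        b = int(methods[i][1:]) - 1
        effect = config.metabolite_effect if met in planted else 0.0
        noise = rng.normal(0.0, config.noise_sd, size=len(samples)) if config.noise_sd > 0 else 0.0
        log2_vals[i] = scale_log2[b] + baselines[i] + effect * is_tumor + noise

    rows = {m: log2_vals[i] for i, m in enumerate(mets)}
    method_map = dict(zip(mets, methods))
    std_flags = dict.fromkeys(mets, False)
    for b in range(config.n_batches):
        for name, base in zip(_STANDARD_BASENAMES, _STANDARD_BASELINES):
            sid = f"{name}_M{b + 1}"
            noise = (
                rng.normal(0.0, config.noise_sd, size=len(samples))
                if config.noise_sd > 0
                else 0.0
            )
            rows[sid] = scale_log2[b] + base + noise
            method_map[sid] = f"M{b + 1}"
            std_flags[sid] = True

    values = pd.DataFrame(
        {s: np.exp2(np.array([rows[m][j] for m in rows])) for j, s in enumerate(samples)},
        index=list(rows),
    )
    if config.missing_rate > 0:
        analyte = ~np.array([std_flags[m] for m in values.index])
        mask = rng.random(values.shape) < config.missing_rate
        mask[~analyte, :] = False
        values = values.mask(mask)

    matrix = MetaboliteMatrix(
        values=values,
        method=pd.Series(method_map),
        is_internal_standard=pd.Series(std_flags),
    )
    annot = SampleAnnotation(
        pd.DataFrame(
            {
                "group": np.where(is_tumor, "tumor", "benign"),
                "cohort": "sim_metabolomics",
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = GroundTruth(true_diff_metabolites=frozenset(planted))
    return matrix, annot, truth


def _calibrate_uniform_censoring(
    hazards: np.ndarray, censoring_rate: float
) -> float:
    """Upper bound u of Uniform(0, u) censoring hitting the target rate.

    For T ~ Exp(h) and C ~ U(0, u), P(censored) = (1 - exp(-h u)) / (h u);
    the expected rate over specimens is monotone decreasing in u, so a
    bisection solves it.
    """

    def expected_rate(u: float) -> float:
        hu = hazards * u
        return float(np.mean((1.0 - np.exp(-hu)) / hu))

    lo, hi = 1e-12, 1.0
    while expected_rate(hi) > censoring_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_rate(mid) > censoring_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_expression_cohort(
    config: SimulationConfig, cohort_id: str = "sim_expression"
) -> tuple[ExpressionCohort, GroundTruth]:
    """Expression cohort with planted differentials and survival outcomes.

    Tumor specimens carry the planted log2 shifts; survival times are
    exponential with hazard = baseline_hazard * exp(beta * standardized
    latent score), where the latent score sums the planted up-gene z-scores
    minus the down-gene z-scores over tumor specimens.  Benign specimens
    (for the tumor-vs-normal differential) have no survival records.
    """
    rng = _rng(config, _STREAM_EXPR)
    genes = gene_universe(config)
    diff_genes = planted_diff_genes(config)

    tumors = [f"SPC{i + 1:04d}" for i in range(config.n_specimens)]
    normals = [f"NRM{i + 1:03d}" for i in range(config.n_benign)]
    specimens = tumors + normals
    is_tumor = np.array([s.startswith("SPC") for s in specimens])

    baselines = rng.uniform(4.0, 12.0, size=len(genes))
    expr = np.empty((len(genes), len(specimens)))
    for i, g in enumerate(genes):
        effect = config.gene_effect * diff_genes.get(g, 0)
        noise = (
            rng.normal(0.0, config.noise_sd, size=len(specimens))
            if config.noise_sd > 0
            else 0.0
        )
        expr[i] = baselines[i] + effect * is_tumor + noise
    expression = pd.DataFrame(expr, index=genes, columns=specimens)

    # latent signature activity over tumor specimens
    tumor_expr = expression[tumors]
    up = [g for g in config.signature_genes_up]
    down = [g for g in config.signature_genes_down]
    z = tumor_expr.loc[up + down]
    sd = z.std(axis=1, ddof=1)
    sd = sd.replace(0.0, 1.0)  # degenerate only when noise_sd = 0
    z = z.sub(z.mean(axis=1), axis=0).div(sd, axis=0)
    latent = z.loc[up].sum(axis=0) - z.loc[down].sum(axis=0)
    lsd = float(latent.std(ddof=1))
    latent = (latent - float(latent.mean())) / (lsd if lsd > 0 else 1.0)

    hazards = config.baseline_hazard * np.exp(
        config.hazard_coefficient * latent.to_numpy()
    )
    event_times = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        u = _calibrate_uniform_censoring(hazards, config.censoring_rate)
        censor_times = rng.uniform(0.0, u, size=len(tumors))
        observed = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(float)
    else:
        observed = event_times
        event = np.ones(len(tumors))

    clinical = pd.DataFrame(
        {
            "time": np.concatenate([observed, np.full(len(normals), np.nan)]),
            "event": np.concatenate([event, np.full(len(normals), np.nan)]),
            "group": np.where(is_tumor, "tumor", "benign"),
            "cohort": cohort_id,
        },
        index=pd.Index(specimens, name="specimen_id"),
    )
    cohort = ExpressionCohort(cohort_id=cohort_id, expression=expression, clinical=clinical)
    truth = GroundTruth(
        true_diff_genes=dict(diff_genes),
        planted_signature=[(g, +1) for g in up] + [(g, -1) for g in down],
        latent_score=latent,
    )
    return cohort, truth


def generate_mapping_and_genesets(
    config: SimulationConfig,
) -> tuple[MetaboliteGeneMap, GeneSetCollection]:
    """Metabolite->gene map plus a gene-set collection over the universe.

    Planted differential metabolites map round-robin onto the planted
    differential genes (covering all of them), so the metabolomics and
    transcriptomics arms intersect by construction; other metabolites map
    to 0..genes_per_metabolite genes drawn from the non-differential pool.
    """
    rng = _rng(config, _STREAM_MAP)
    genes = gene_universe(config)
    diff = list(planted_diff_genes(config))
    non_diff = [g for g in genes if g not in set(diff)]
    planted = planted_metabolites(config)

    entries: dict[str, frozenset[str]] = {}
    k = config.genes_per_metabolite
    for i, met in enumerate(planted):
        if diff and k > 0:
            assigned = {diff[(i * k + j) % len(diff)] for j in range(k)}
        else:
            assigned = set()
        entries[met] = frozenset(assigned)
    for met in metabolite_names(config)[config.n_diff_metabolites :]:
        count = int(rng.integers(0, k + 1)) if k > 0 else 0
        if count and non_diff:
            chosen = rng.choice(len(non_diff), size=min(count, len(non_diff)), replace=False)
            entries[met] = frozenset(non_diff[j] for j in chosen)
        else:
            entries[met] = frozenset()

    sets: dict[str, frozenset[str]] = {}
    for start in range(0, len(genes), config.geneset_size):
        chunk = genes[start : start + config.geneset_size]
        sets[f"SET{start // config.geneset_size + 1:04d}"] = frozenset(chunk)
    if diff:
        sets["PLANTED_PATHWAY"] = frozenset(diff)
    collection = GeneSetCollection(sets=sets, universe=frozenset(genes))
    return MetaboliteGeneMap(entries=entries), collection


def write_simulated_study(out_dir: str | Path, config: SimulationConfig) -> dict:
    """Generate a full synthetic study and write every interchange file.

    Writes metabolite/expression/clinical/annotation TSVs, the
    metabolite->gene map, the GMT collection, ground-truth TSVs and a
    manifest recording the config; returns a dict of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, annot, truth_m = generate_metabolomics(config)
    cohort, truth_e = generate_expression_cohort(config)
    mapping, collection = generate_mapping_and_genesets(config)

    paths = {
        "metabolite_table": out_dir / "metabolites_raw.tsv",
        "sample_annotation": out_dir / "sample_annotation.tsv",
        "expression_table": out_dir / "expression_log2.tsv",
        "clinical_table": out_dir / "clinical.tsv",
        "mapping_table": out_dir / "metabolite_gene_map.tsv",
        "geneset_gmt": out_dir / "genesets.gmt",
        "truth_metabolites": out_dir / "truth_diff_metabolites.tsv",
        "truth_genes": out_dir / "truth_diff_genes.tsv",
        "manifest": out_dir / "simulation_manifest.json",
    }
    msio.write_abundance_table(paths["metabolite_table"], matrix, dialect="metabolite")
    msio.write_sample_annotation(paths["sample_annotation"], annot)
    msio.write_abundance_table(paths["expression_table"], cohort.expression, dialect="expression")
    msio.write_clinical_table(paths["clinical_table"], cohort.clinical)
    msio.write_metabolite_gene_map(paths["mapping_table"], mapping)
    msio.write_gmt(paths["geneset_gmt"], collection)
    pd.Series(sorted(truth_m.true_diff_metabolites), name="metabolite_id").to_csv(
        paths["truth_metabolites"], sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth_e.true_diff_genes.items()), columns=["gene_symbol", "sign"]
    ).to_csv(paths["truth_genes"], sep="\t", index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump({"config": config.to_dict()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
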