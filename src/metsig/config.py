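"""Simulation and pipeline run configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

from .exceptions import ConfigError

#: grid of (f_low, f_high) quantile breakdowns used by the exploratory
#: threshold scan: bottom quartile vs rest, tertile splits, median split.
DEFAULT_GRID: tuple[tuple[float, float], ...] = (
    (0.25, 0.75),
    (0.33, 0.67),
    (0.33, 0.33),
    (0.5, 0.5),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study generator.

    Defaults mirror the real study's design: 145 targeted metabolites
    acquired under 4 chromatography methods with spiked internal standards,
    46 tumor vs 14 benign tissues with 31 differential metabolites, and a
    377-specimen expression cohort with survival follow-up.

    ``metabolite_effect`` and ``gene_effect`` are log2-unit group shifts
    planted in tumor samples; ``hazard_coefficient`` is the log-hazard slope
    per standard deviation of the latent signature score;
    ``baseline_hazard`` is in events per study-time unit.
    """

    n_metabolites: int = 145
    n_tumor: int = 46
    n_benign: int = 14
    n_batches: int = 4
    n_diff_metabolites: int = 31
    metabolite_effect: float = 2.0
    n_genes: int = 1000
    n_diff_genes: int = 100
    gene_effect: float = 1.5
    n_specimens: int = 377
    signature_genes_up: tuple[str, ...] = ("GENE0001", "GENE0002", "GENE0003")
    signature_genes_down: tuple[str, ...] = ("GENE0004", "GENE0005", "GENE0006")
    hazard_coefficient: float = 1.5
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.05
    noise_sd: float = 0.5
    genes_per_metabolite: int = 3
    geneset_size: int = 25
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_metabolites": self.n_metabolites,
            "n_tumor": self.n_tumor,
            "n_benign": self.n_benign,
            "n_batches": self.n_batches,
            "n_genes": self.n_genes,
            "n_specimens": self.n_specimens,
            "geneset_size": self.geneset_size,
        }
        for name, value in counts.items():
            if not isinstance(value, (int,)) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        for name in ("n_diff_metabolites", "n_diff_genes", "genes_per_metabolite"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_diff_metabolites > self.n_metabolites:
            raise ConfigError("n_diff_metabolites exceeds n_metabolites")
        if self.n_diff_genes > self.n_genes:
            raise ConfigError("n_diff_genes exceeds n_genes")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must lie in [0, 1), got {self.missing_rate!r}")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigError(f"censoring_rate must lie in [0, 1), got {self.censoring_rate!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be non-negative, got {self.noise_sd!r}")
        if self.baseline_hazard <= 0:
            raise ConfigError(f"baseline_hazard must be positive, got {self.baseline_hazard!r}")
        overlap = set(self.signature_genes_up) & set(self.signature_genes_down)
        if overlap:
            raise ConfigError(f"signature_genes_up/down overlap: {sorted(overlap)}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signature_genes_up"] = list(self.signature_genes_up)
        d["signature_genes_down"] = list(self.signature_genes_down)
        return d


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration.

    Thresholds default to the study's analysis constants: metabolite FDR
    15%, transcript p < 0.05 with a twofold (|log2 FC| >= 1) gate, survival
    alpha 0.05, bottom-25%/top-75% score breakdown.
    """

    metabolite_table: Path | None = None
    sample_annotation: Path | None = None
    expression_table: Path | None = None
    clinical_table: Path | None = None
    mapping_table: Path | None = None
    geneset_gmt: Path | None = None
    extra_cohorts: list[tuple[Path, Path]] = field(default_factory=list)
    output_dir: Path = Path("metsig_out")

    fdr_metab: float = 0.15
    p_transcript: float = 0.05
    log2fc_gate: float = 1.0
    alpha_surv: float = 0.05
    breakdown: tuple[float, float] = (0.25, 0.75)
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    run_refinement: bool = False
    max_refine_candidates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_metab", "p_transcript", "alpha_surv"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v!r}")
        if self.log2fc_gate < 0:
            raise ConfigError(f"log2fc_gate must be non-negative, got {self.log2fc_gate!r}")
        f_low, f_high = self.breakdown
        if not (0 < f_low <= 1 and 0 < f_high <= 1):
            raise ConfigError(f"breakdown fractions must lie in (0, 1], got {self.breakdown!r}")
        for p in (
            self.metabolite_table,
            self.sample_annotation,
            self.expression_table,
            self.clinical_table,
            self.mapping_table,
            self.geneset_gmt,
        ):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")
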