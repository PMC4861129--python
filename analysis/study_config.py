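"""Shared configuration for the narrative analysis scripts.

One synthetic study, shaped like the real design: 145 targeted metabolites
(31 planted differential) in 46 tumor vs 14 benign tissues under 4
chromatography methods, and a 377-specimen expression cohort whose hazard
follows a planted 6-gene signature.  Every script regenerates its inputs
deterministically from this config, so the scripts can run in any order.
"""

from pathlib import Path

from metsig import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = SimulationConfig(
    n_metabolites=145,
    n_tumor=46,
    n_benign=14,
    n_batches=4,
    n_diff_metabolites=31,
    metabolite_effect=2.0,
    n_genes=1000,
    n_diff_genes=100,
    gene_effect=1.5,
    n_specimens=377,
    hazard_coefficient=1.5,
    censoring_rate=0.3,
    noise_sd=0.5,
    seed=42,
)
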