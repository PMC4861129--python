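import pandas as pd
import pytest

from metsig import SimulationConfig, generate_expression_cohort, write_simulated_study


@pytest.fixture
def small_config():
    """Small but non-trivial study: 5 planted metabolites, 8 planted genes."""
    return SimulationConfig(
        n_metabolites=20,
        n_diff_metabolites=5,
        n_tumor=10,
        n_benign=10,
        n_genes=40,
        n_diff_genes=8,
        n_specimens=120,
        noise_sd=0.1,
        metabolite_effect=2.0,
        gene_effect=1.5,
        seed=7,
    )


@pytest.fixture
def expression_cohort(small_config):
    cohort, truth = generate_expression_cohort(small_config)
    return cohort, truth


@pytest.fixture
def simulated_study_dir(tmp_path, small_config):
    paths = write_simulated_study(tmp_path / "study", small_config)
    return paths


@pytest.fixture
def toy_survival():
    """Four specimens, all events, at times 1..4; L = {1,2}, H = {3,4}."""
    surv = pd.DataFrame(
        {"time": [1.0, 2.0, 3.0, 4.0], "event": [1.0, 1.0, 1.0, 1.0]},
        index=["a", "b", "c", "d"],
    )
    return surv
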