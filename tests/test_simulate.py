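"""Synthetic-study generator: determinism, planted effects, survival model."""

import numpy as np
import pandas as pd
import pytest

from metsig import (
    ConfigError,
    SimulationConfig,
    differential_features,
    generate_expression_cohort,
    generate_mapping_and_genesets,
    generate_metabolomics,
    integrate_signature,
    logrank_from_arrays,
    normalize_metabolites,
    significant_features,
)
from metsig.simulate import planted_diff_genes


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_metabolites": 0},
            {"n_tumor": -1},
            {"n_diff_metabolites": 50, "n_metabolites": 20},
            {"n_diff_genes": 2000, "n_genes": 100},
            {"censoring_rate": 1.0},
            {"noise_sd": -0.1},
            {"baseline_hazard": 0.0},
            {"missing_rate": 1.5},
        ],
    )
    def test_invalid_fields_rejected_by_name(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_overlapping_signature_lists_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            SimulationConfig(
                signature_genes_up=("GENE0001",), signature_genes_down=("GENE0001",)
            )


class TestMetabolomicsGenerator:
    def test_determinism_bit_identical(self, small_config):
        m1, a1, t1 = generate_metabolomics(small_config)
        m2, a2, t2 = generate_metabolomics(small_config)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(a1.table, a2.table)
        assert t1.true_diff_metabolites == t2.true_diff_metabolites

    def test_zero_noise_zero_effect_groups_identical(self):
        cfg = SimulationConfig(
            n_metabolites=10, n_diff_metabolites=3, n_tumor=5, n_benign=5,
            metabolite_effect=0.0, noise_sd=0.0, seed=1,
        )
        matrix, annot, _ = generate_metabolomics(cfg)
        norm = normalize_metabolites(matrix)
        tum = norm[annot.ids_in_group("tumor")].mean(axis=1)
        ben = norm[annot.ids_in_group("benign")].mean(axis=1)
        np.testing.assert_allclose(tum, ben, atol=1e-12)

    def test_zero_noise_group_difference_equals_planted_effect(self):
        cfg = SimulationConfig(
            n_metabolites=12, n_diff_metabolites=4, n_tumor=6, n_benign=6,
            metabolite_effect=1.7, noise_sd=0.0, seed=2,
        )
        matrix, annot, truth = generate_metabolomics(cfg)
        norm = normalize_metabolites(matrix)
        diff = norm[annot.ids_in_group("tumor")].mean(axis=1) - norm[
            annot.ids_in_group("benign")
        ].mean(axis=1)
        for met in norm.index:
            expected = 1.7 if met in truth.true_diff_metabolites else 0.0
            assert diff[met] == pytest.approx(expected, abs=1e-9)

    def test_planted_metabolites_recovered_at_fdr15(self, small_config):
        matrix, annot, truth = generate_metabolomics(small_config)
        result = differential_features(normalize_metabolites(matrix), annot, "metabolite")
        assert set(significant_features(result)) == set(truth.true_diff_metabolites)

    def test_two_standards_per_method(self, small_config):
        matrix, _, _ = generate_metabolomics(small_config)
        per_method = matrix.method[matrix.is_internal_standard].value_counts()
        assert (per_method == 2).all()
        assert len(per_method) == small_config.n_batches

    def test_uniform_missingness_option(self):
        cfg = SimulationConfig(
            n_metabolites=50, n_diff_metabolites=5, n_tumor=10, n_benign=10,
            missing_rate=0.2, seed=4,
        )
        matrix, _, _ = generate_metabolomics(cfg)
        analyte = matrix.values.loc[~matrix.is_internal_standard]
        frac = analyte.isna().to_numpy().mean()
        assert 0.1 < frac < 0.3
        assert not matrix.values.loc[matrix.is_internal_standard].isna().to_numpy().any()


class TestExpressionGenerator:
    def test_determinism(self, small_config):
        c1, _ = generate_expression_cohort(small_config)
        c2, _ = generate_expression_cohort(small_config)
        pd.testing.assert_frame_equal(c1.expression, c2.expression)
        pd.testing.assert_frame_equal(c1.clinical, c2.clinical)

    def test_no_censoring_means_all_events(self):
        cfg = SimulationConfig(n_specimens=50, censoring_rate=0.0, seed=5)
        cohort, _ = generate_expression_cohort(cfg)
        assert (cohort.survival_records()["event"] == 1.0).all()

    def test_censoring_rate_near_requested(self):
        cfg = SimulationConfig(n_specimens=2000, censoring_rate=0.3, seed=6)
        cohort, _ = generate_expression_cohort(cfg)
        observed = 1.0 - cohort.survival_records()["event"].mean()
        assert observed == pytest.approx(0.3, abs=0.05)

    def test_positive_hazard_coefficient_gives_worse_high_score_survival(self):
        cfg = SimulationConfig(n_specimens=400, hazard_coefficient=1.5,
                               censoring_rate=0.3, seed=11)
        cohort, truth = generate_expression_cohort(cfg)
        surv = cohort.survival_records()
        high = truth.latent_score.loc[surv.index] > truth.latent_score.median()
        res = logrank_from_arrays(
            surv["time"].to_numpy(), surv["event"].to_numpy(), high.to_numpy()
        )
        assert res.direction == 1  # more deaths than expected among high scores
        assert res.p < 0.05

    def test_null_hazard_gives_uniform_logrank_p(self):
        """With beta=0 survival is independent of score: p approximately uniform."""
        pvals = []
        for seed in range(40):
            cfg = SimulationConfig(n_specimens=80, hazard_coefficient=0.0,
                                   censoring_rate=0.2, n_genes=10, n_diff_genes=6,
                                   seed=seed)
            cohort, truth = generate_expression_cohort(cfg)
            surv = cohort.survival_records()
            high = truth.latent_score.loc[surv.index] > truth.latent_score.median()
            pvals.append(
                logrank_from_arrays(
                    surv["time"].to_numpy(), surv["event"].to_numpy(), high.to_numpy()
                ).p
            )
        # rejection fraction near 5% and no pile-up at small p
        assert np.mean(np.array(pvals) < 0.05) < 0.2
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.2)


class TestMappingGenerator:
    def test_planted_mapping_yields_planted_integration(self):
        """Five planted metabolites linked to 8 planted genes: integration
        recovers exactly those genes (set arithmetic on the ground truth)."""
        cfg = SimulationConfig(
            n_metabolites=20, n_diff_metabolites=5, n_tumor=10, n_benign=10,
            n_genes=40, n_diff_genes=8, n_specimens=60, noise_sd=0.1, seed=3,
        )
        mapping, _ = generate_mapping_and_genesets(cfg)
        matrix, annot, truth_m = generate_metabolomics(cfg)
        diff_mets = significant_features(
            differential_features(normalize_metabolites(matrix), annot, "metabolite")
        )
        mapped = set()
        for met in diff_mets:
            mapped |= mapping.genes_for(met)
        expected = set(planted_diff_genes(cfg))
        assert mapped == expected

        cohort, truth_e = generate_expression_cohort(cfg)
        from metsig.datatypes import SampleAnnotation

        annot_e = SampleAnnotation(cohort.clinical[["group", "cohort"]])
        tdiff = differential_features(cohort.expression, annot_e, "transcript")
        sig = integrate_signature(mapped, tdiff)
        assert set(sig.genes) == expected

    def test_empty_mapping_gives_empty_signature(self, small_config):
        from metsig import MetaboliteGeneMap

        empty = MetaboliteGeneMap(entries={})
        cohort, _ = generate_expression_cohort(small_config)
        from metsig.datatypes import SampleAnnotation

        annot = SampleAnnotation(cohort.clinical[["group", "cohort"]])
        tdiff = differential_features(cohort.expression, annot, "transcript")
        mapped = empty.genes_for("MET0001")
        assert mapped == frozenset()
        sig = integrate_signature(mapped, tdiff)
        assert len(sig) == 0

    def test_determinism(self, small_config):
        m1, c1 = generate_mapping_and_genesets(small_config)
        m2, c2 = generate_mapping_and_genesets(small_config)
        assert m1.entries == m2.entries
        assert c1.sets == c2.sets
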