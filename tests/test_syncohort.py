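"""Unit tests for synthetic cohort generation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from epicohort.syncohort import (
    CohortConfig,
    calibrate_mu,
    generate_cohort,
    generate_genotypes,
    generate_participants,
    generate_surveys,
    read_cohort,
    standardized_confounders,
    write_cohort,
)
from epicohort.syncohort.phenotype import generate_phenotype


class TestConfigValidation:
    def test_bad_maf_range(self):
        with pytest.raises(ValueError, match="maf_range"):
            CohortConfig(maf_range=(0.0, 0.6))

    def test_bad_fraction(self):
        with pytest.raises(ValueError, match="wgs_fraction"):
            CohortConfig(wgs_fraction=1.2)

    def test_unknown_variant_effect(self):
        with pytest.raises(ValueError, match="unknown variants"):
            CohortConfig(n_variants=5, variant_effects={"v00099": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(n_variants=10, gxe_effects=[("v00001", "smoker", 0.3)])
        cfg.to_yaml(tmp_path / "c.yaml")
        back = CohortConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestGenotypes:
    def test_dosages_in_012(self):
        cfg = CohortConfig(n_participants=300, n_variants=40, seed=3)
        g = generate_genotypes(cfg)
        assert set(np.unique(g.dosages)) <= {0, 1, 2}

    def test_single_population_mean_dosage(self):
        # one population, p = 0.3 for every variant -> mean dosage ~ 2p = 0.6
        cfg = CohortConfig(
            n_participants=20000, n_variants=5, n_populations=1,
            maf_range=(0.3, 0.3), seed=11,
        )
        g = generate_genotypes(cfg)
        assert g.dosages.mean() == pytest.approx(0.6, abs=0.01)

    def test_maf_half_expected_dosage_one(self):
        cfg = CohortConfig(
            n_participants=10000, n_variants=8, n_populations=1,
            maf_range=(0.5, 0.5), seed=5,
        )
        g = generate_genotypes(cfg)
        np.testing.assert_allclose(g.dosages.mean(axis=0), 1.0, atol=0.05)

    def test_two_population_pooled_maf(self):
        # Oracle: two populations at p=0.1 and p=0.4 mixed ~50/50 pool to
        # 0.25; checked by direct allele counting on the realized matrix.
        # A huge Dirichlet concentration pins admixture at 50/50.
        cfg = CohortConfig(
            n_participants=20000, n_variants=4, n_populations=2,
            maf_range=(0.25, 0.25), admixture_concentration=1e6, seed=99,
        )
        pop_freq = np.array([[0.1] * 4, [0.4] * 4])
        g = generate_genotypes(cfg, pop_freq=pop_freq)
        pooled = g.dosages.sum() / (2 * g.dosages.size)
        assert pooled == pytest.approx(0.25, abs=0.01)

    def test_metadata_populated(self):
        cfg = CohortConfig(n_participants=200, n_variants=10, seed=1)
        g = generate_genotypes(cfg)
        assert list(g.variants.columns) == ["id", "chrom", "pos", "ref", "alt", "maf"]
        np.testing.assert_allclose(
            g.variants["maf"], g.minor_allele_frequencies(), atol=1e-12
        )


class TestSurveys:
    def test_block_missingness_row_counts(self):
        # completion fraction 0.347 on n=9184 -> row count within binomial
        # noise (4 sd) of 9184 * 0.347 ~ 3187
        cfg = CohortConfig(
            n_participants=9184, n_variants=2, exposome_a_fraction=0.347, seed=21
        )
        participants = generate_participants(cfg)
        tables, _ = generate_surveys(cfg, participants)
        n, p = 9184, 0.347
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(tables["survey_a"]) - n * p) < 4 * sd
        assert len(tables["survey_he"]) == n

    def test_rows_match_completion_flags(self):
        cfg = CohortConfig(n_participants=400, n_variants=2, seed=2)
        participants = generate_participants(cfg)
        tables, _ = generate_surveys(cfg, participants)
        expected = set(participants.loc[participants["completed_int"], "id"])
        assert set(tables["survey_b"].index) == expected

    def test_gate_forces_dependents_missing(self):
        cfg = CohortConfig(n_participants=500, n_variants=2, seed=3)
        participants = generate_participants(cfg)
        tables, _ = generate_surveys(cfg, participants)
        he = tables["survey_he"]
        non_smokers = he["smoker"] == "no"
        assert he.loc[non_smokers, "cigarettes_per_day"].isna().all()

    def test_no_missing_when_rates_zero(self):
        cfg = CohortConfig(
            n_participants=300, n_variants=2, item_missing_rate=0.0, seed=4
        )
        participants = generate_participants(cfg)
        tables, _ = generate_surveys(cfg, participants)
        he = tables["survey_he"].drop(columns=["cigarettes_per_day"])  # gated
        assert not he.isna().any().any()
        smokers = tables["survey_he"]["smoker"] == "yes"
        assert not tables["survey_he"].loc[smokers, "cigarettes_per_day"].isna().any()


class TestPhenotype:
    def test_null_model_prevalence_half(self):
        cfg = CohortConfig(n_participants=20000, n_variants=2, mu=0.0, seed=6)
        cohort = generate_cohort(cfg)
        assert cohort.outcome.mean() == pytest.approx(0.5, abs=0.02)

    def test_mu_calibration_hits_target(self):
        # [PAPER-anchored target] test-set prevalence was 32.8%
        cfg = CohortConfig(
            n_participants=6000, n_variants=5, prevalence_target=0.328,
            env_effects={"smoker": 1.0}, seed=8,
        )
        cohort = generate_cohort(cfg)
        assert cohort.truth.prevalence == pytest.approx(0.328, abs=0.02)

    def test_single_variant_odds_ratio(self):
        # Oracle: w=1 per dosage -> empirical odds(d=2)/odds(d=0) ~ e^2
        cfg = CohortConfig(
            n_participants=50000, n_variants=1, n_populations=1,
            maf_range=(0.5, 0.5), mu=-1.0,
            variant_effects={"v00000": 1.0}, item_missing_rate=0.0, seed=9,
        )
        participants = generate_participants(cfg)
        from epicohort.syncohort import generate_genotypes as gg

        geno = gg(cfg, sample_ids=participants["id"].tolist())
        _, latent = generate_surveys(cfg, participants)
        outcome, _ = generate_phenotype(cfg, participants, geno, latent)
        d = geno.dosages[:, 0]
        y = outcome.to_numpy()

        def odds(mask):
            p = y[mask].mean()
            return p / (1 - p)

        ratio = odds(d == 2) / odds(d == 0)
        assert ratio == pytest.approx(np.exp(2.0), rel=0.15)

    def test_linear_predictor_round_trip(self, signal_cohort, signal_config):
        truth = signal_cohort.truth
        from epicohort.syncohort import generate_genotypes

        geno_full = generate_genotypes(
            signal_config, sample_ids=signal_cohort.participants["id"].tolist()
        )
        vidx = {v: j for j, v in enumerate(geno_full.variants["id"])}
        conf = standardized_confounders(signal_cohort.participants)
        eta = truth.recompute_linear_predictor(
            geno_full.dosages.astype(float), vidx, conf
        )
        np.testing.assert_allclose(eta, truth.linear_predictor, rtol=0, atol=1e-12)

    def test_unknown_env_effect_raises(self):
        cfg = CohortConfig(
            n_participants=200, n_variants=2, env_effects={"nope": 1.0}, seed=1
        )
        with pytest.raises(ValueError, match="unknown variable"):
            generate_cohort(cfg)


class TestCalibrateMu:
    def test_zero_predictor(self):
        eta = np.zeros(1000)
        assert calibrate_mu(eta, 0.5) == pytest.approx(0.0, abs=1e-6)

    def test_known_logit(self):
        eta = np.zeros(1000)
        mu = calibrate_mu(eta, 0.33)
        assert expit(mu) == pytest.approx(0.33, abs=1e-6)


class TestCohortInvariants:
    def test_genotype_rows_match_wgs_flags(self, signal_cohort):
        participants = signal_cohort.participants
        wgs_ids = set(participants.loc[participants["wgs_available"], "id"])
        assert set(signal_cohort.genotypes.samples) == wgs_ids

    def test_ids_unique_outcome_total(self, signal_cohort):
        assert signal_cohort.participants["id"].is_unique
        assert len(signal_cohort.outcome) == len(signal_cohort.participants)

    def test_io_round_trip(self, tmp_path, signal_cohort):
        write_cohort(signal_cohort, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        pd.testing.assert_frame_equal(
            back.participants, signal_cohort.participants, check_dtype=False
        )
        np.testing.assert_array_equal(back.outcome, signal_cohort.outcome)
        np.testing.assert_array_equal(
            back.genotypes.dosages, signal_cohort.genotypes.dosages
        )
        np.testing.assert_allclose(
            back.truth.linear_predictor, signal_cohort.truth.linear_predictor
        )

    def test_seed_reproducibility(self):
        cfg = CohortConfig(n_participants=300, n_variants=10, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.outcome, b.outcome)
        pd.testing.assert_frame_equal(a.survey_he, b.survey_he)

    def test_exact_count_overrides(self):
        cfg = CohortConfig(n_participants=1000, n_variants=2, n_wgs=400,
                           n_qc_flagged=50, seed=13)
        participants = generate_participants(cfg)
        assert participants["wgs_available"].sum() == 400
        flagged = participants[["qc_outlier", "qc_related", "qc_race_mismatch"]].any(axis=1)
        assert flagged.sum() == 50
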