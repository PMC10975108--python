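"""Cohort simulator: determinism, HWE fidelity, planted-effect calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pedprs import (
    SimConfig,
    apply_qc_chain,
    gen_genotypes,
    gen_phenotypes,
    gen_snp_panel,
    gen_subjects,
    make_preset,
    synthetic_lms_reference,
)


class TestPanel:
    def test_cardinality_and_uniqueness(self):
        panel = gen_snp_panel(55, (0.05, 0.5), 0.02, seed=1)
        assert len(panel) == 55
        assert panel.table["snp_id"].is_unique
        assert (panel.table["effect_allele"] != panel.table["other_allele"]).all()

    def test_single_snp(self):
        assert len(gen_snp_panel(1, (0.05, 0.5), 0.02, seed=1)) == 1

    def test_seed_determinism(self):
        a = gen_snp_panel(20, (0.05, 0.5), 0.02, seed=7)
        b = gen_snp_panel(20, (0.05, 0.5), 0.02, seed=7)
        assert a.table.to_csv() == b.table.to_csv()

    def test_betas_straddle_zero(self):
        panel = gen_snp_panel(200, (0.05, 0.5), 0.02, seed=2)
        assert (panel.betas > 0).any() and (panel.betas < 0).any()

    def test_invalid_maf_range(self):
        with pytest.raises(ValueError):
            gen_snp_panel(5, (0.0, 0.7), 0.02, seed=1)


class TestGenotypes:
    def test_full_inbreeding_no_heterozygotes(self):
        panel = gen_snp_panel(10, (0.1, 0.5), 0.02, seed=3)
        geno = gen_genotypes(panel, 500, inbreeding_f=1.0, seed=3)
        assert not (geno.dosage == 1).any()

    def test_hwe_frequencies_within_binomial_bounds(self):
        panel = gen_snp_panel(1, (0.3, 0.3), 0.02, seed=4)
        panel.table["source_maf"] = 0.3
        n = 10000
        geno = gen_genotypes(panel, n, seed=4)
        col = geno.dosage[:, 0]
        for dosage, p in ((2, 0.09), (1, 0.42), (0, 0.49)):
            obs = (col == dosage).mean()
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * sd

    def test_no_missing_when_rate_zero(self):
        panel = gen_snp_panel(5, (0.1, 0.5), 0.02, seed=5)
        geno = gen_genotypes(panel, 100, missing_rate=0.0, seed=5)
        assert not np.isnan(geno.dosage).any()

    def test_hwe_fidelity_under_null(self):
        """Clean draws essentially never fail the exact test at p < 1e-6."""
        panel = gen_snp_panel(1000, (0.05, 0.5), 0.02, seed=6)
        geno = gen_genotypes(panel, 500, seed=6)
        rep = apply_qc_chain(geno, maf_min=0.0)
        assert rep.counts()["fail_hwe"] == 0


class TestSubjects:
    def test_vitd_median_matches_target(self):
        df = gen_subjects(10000, vitd_median=33.63, seed=7)
        assert 32.5 <= df["vitd_ng_ml"].median() <= 34.8

    def test_single_complete_record(self):
        df = gen_subjects(1, seed=8)
        assert len(df) == 1 and not df.isna().any().any()

    def test_seed_determinism(self):
        assert gen_subjects(50, seed=9).equals(gen_subjects(50, seed=9))

    def test_age_span(self):
        df = gen_subjects(2000, seed=10)
        assert df["age_months"].between(44, 80).all()


class TestPhenotypes:
    def _cohort(self, n, effect_prs, effect_vitd, seed):
        panel = gen_snp_panel(30, (0.1, 0.5), 0.02, seed=seed)
        geno = gen_genotypes(panel, n, seed=seed)
        subj = gen_subjects(n, seed=seed)
        lms = synthetic_lms_reference()
        return gen_phenotypes(subj, geno, panel, lms, effect_prs, effect_vitd, seed=seed)

    def test_null_effects_give_null_correlation(self):
        out = self._cohort(10000, 0.0, 0.0, seed=11)
        rs = spearmanr(out["true_prs"], out["true_z"]).statistic
        assert abs(rs) < 0.05

    def test_planted_effect_recovered(self):
        out = self._cohort(10000, 0.10, 0.0, seed=12)
        rs = spearmanr(out["true_prs"], out["true_z"]).statistic
        assert 0.07 <= rs <= 0.13

    def test_zero_noise_perfect_rank_correlation(self):
        out = self._cohort(500, 1.0, 0.0, seed=13)
        rs = spearmanr(out["true_prs"], out["true_z"]).statistic
        assert rs == pytest.approx(1.0)

    def test_misaligned_subjects_raise(self):
        panel = gen_snp_panel(5, (0.1, 0.5), 0.02, seed=14)
        geno = gen_genotypes(panel, 10, seed=14)
        subj = gen_subjects(10, seed=14).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="subject_ids"):
            gen_phenotypes(subj, geno, panel, synthetic_lms_reference(), 0.1, -0.1, seed=14)

    def test_effect_planting_calibrated_over_replicates(self):
        """Mean realized Spearman over 200 cohorts at n=1046 hits 0.10 +/- 0.02."""
        lms = synthetic_lms_reference()
        rs_vals = []
        for seed in range(200):
            panel = gen_snp_panel(55, (0.05, 0.5), 0.02, seed=seed)
            geno = gen_genotypes(panel, 1046, seed=seed)
            subj = gen_subjects(1046, seed=seed)
            out = gen_phenotypes(subj, geno, panel, lms, 0.10, -0.11, seed=seed)
            rs_vals.append(spearmanr(out["true_prs"], out["true_z"]).statistic)
        assert abs(np.mean(rs_vals) - 0.10) < 0.02


class TestPresets:
    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            make_preset("nope", seed=0)

    def test_qc_stress_has_nine_fully_missing(self, qc_stress):
        _, geno, _ = qc_stress
        fully_missing = np.isnan(geno.dosage).all(axis=0).sum()
        assert fully_missing == 9

    def test_paper_cohort_dimensions(self, paper_cohort):
        panel, geno, subjects = paper_cohort
        assert geno.dosage.shape == (1046, 55)
        assert len(panel) == 55
        assert len(subjects) == 1046

    def test_preset_determinism(self):
        p1, g1, s1 = make_preset("paper_cohort", seed=21)
        p2, g2, s2 = make_preset("paper_cohort", seed=21)
        assert p1.table.equals(p2.table)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)
        assert s1.equals(s2)


def test_simconfig_validation():
    with pytest.raises(ValueError):
        SimConfig(n_subjects=0)
    with pytest.raises(ValueError):
        SimConfig(missing_rate=1.5)
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.0, 0.5))
    assert SimConfig().n_subjects == 1046
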