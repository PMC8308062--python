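import numpy as np
import pandas as pd
import pytest

from gbmrs.errors import ConfigurationError, SimulationError
from gbmrs.synthdata import (
    DiseaseSpec,
    SimulationConfig,
    base_allele_frequencies,
    draw_architecture,
    simulate_biomarkers,
    simulate_cohort,
    simulate_disease,
    simulate_diverged_cohort,
    simulate_genotypes,
    simulate_sibling_pairs,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 0},
            {"n_snps": -1},
            {"maf_range": (0.0, 0.5)},  # degenerate f=0 rejected
            {"maf_range": (0.1, 0.6)},
            {"heritability_h2": 0.8, "shared_env_var": 0.3},
            {"fst_divergence": 1.0},
            {"disease_specs": [DiseaseSpec("d", {}, prevalence=1.0)]},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestGenotypes:
    def test_dosage_moments_match_binomial(self):
        cfg = SimulationConfig(n_samples=20_000, n_snps=10, n_causal_per_biomarker=5, maf_range=(0.5, 0.5), seed=1)
        g = simulate_genotypes(cfg)
        assert np.allclose(g.dosages.mean(axis=0), 1.0, atol=0.03)
        assert np.allclose(g.dosages.var(axis=0), 0.5, atol=0.03)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_samples=1000, n_snps=100, seed=7)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(SimulationConfig(n_samples=1000, n_snps=100, seed=7))
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.snps, b.snps)

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n_samples=200, n_snps=50, seed=7)
        other = SimulationConfig(n_samples=200, n_snps=50, seed=8)
        assert not np.array_equal(simulate_genotypes(cfg).dosages, simulate_genotypes(other).dosages)

    def test_metadata_round_robin_chromosomes(self):
        cfg = SimulationConfig(n_samples=10, n_snps=50, seed=0)
        g = simulate_genotypes(cfg)
        assert set(g.snps["chrom"]) <= set(range(1, 23))
        for _, grp in g.snps.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing


class TestSiblings:
    @staticmethod
    def _standardized(g, cfg):
        # standardize by the population frequencies: in-sample constants over
        # a handful of related individuals would bias the correlation down
        f = base_allele_frequencies(cfg)
        return (g.dosages - 2 * f) / np.sqrt(2 * f * (1 - f))

    def test_sibling_genotype_correlation_half(self):
        cfg = SimulationConfig(n_samples=10, n_snps=12_000, n_sibling_pairs=12, seed=5)
        g, pairs = simulate_sibling_pairs(cfg)
        idx = {s: i for i, s in enumerate(g.sample_ids)}
        z = self._standardized(g, cfg)
        corrs = [np.corrcoef(z[idx[a]], z[idx[b]])[0, 1] for a, b in pairs]
        # expectation 0.5 under Mendelian transmission; SE ~ 1/sqrt(n_snps)
        se = 1.0 / np.sqrt(cfg.n_snps)
        assert abs(np.mean(corrs) - 0.5) < 3 * se

    def test_unrelated_samples_uncorrelated(self):
        cfg = SimulationConfig(n_samples=10, n_snps=12_000, n_sibling_pairs=12, seed=5)
        g, pairs = simulate_sibling_pairs(cfg)
        idx = {s: i for i, s in enumerate(g.sample_ids)}
        z = self._standardized(g, cfg)
        r = np.corrcoef(z[idx[pairs[0][0]]], z[idx[pairs[1][1]]])[0, 1]
        assert abs(r) < 4.0 / np.sqrt(cfg.n_snps)

    def test_parent_frequencies_respect_maf_range(self):
        cfg = SimulationConfig(n_samples=10, n_snps=500, n_sibling_pairs=300, maf_range=(0.2, 0.4), seed=2)
        g, _ = simulate_sibling_pairs(cfg)
        freqs = g.realized_mafs()
        assert freqs.min() > 0.1 and freqs.max() < 0.5


class TestBiomarkers:
    def test_zero_h2_gives_no_genetic_correlation(self):
        cfg = SimulationConfig(
            n_samples=2000, n_snps=100, n_biomarkers=1, heritability_h2=0.0,
            shared_env_var=0.0, n_sibling_pairs=0, repeat_noise_sd=0.0, seed=3,
        )
        g = simulate_genotypes(cfg)
        pheno = simulate_biomarkers(g, cfg)
        gen = pheno.truth["genetic"]["bm01"].to_numpy()
        assert np.allclose(gen, 0.0)

    def test_h2_half_gives_sqrt_h2_correlation(self):
        cfg = SimulationConfig(
            n_samples=12_000, n_snps=200, n_biomarkers=1, n_causal_per_biomarker=20,
            heritability_h2=0.5, shared_env_var=0.0, n_sibling_pairs=0,
            repeat_noise_sd=0.0, sex_offset=0.0, age_slope=0.0, seed=4,
        )
        g = simulate_genotypes(cfg)
        pheno = simulate_biomarkers(g, cfg)
        gen = pheno.truth["genetic"].set_index("sample_id")["bm01"]
        single = pheno.measurements[pheno.measurements["visit"] == 1].set_index("sample_id")["value"]
        r = np.corrcoef(gen.loc[single.index], single)[0, 1]
        assert abs(r - np.sqrt(0.5)) < 0.03

    def test_variance_bookkeeping(self):
        cfg = SimulationConfig(
            n_samples=12_000, n_snps=200, n_biomarkers=1, heritability_h2=0.4,
            shared_env_var=0.0, n_sibling_pairs=0, repeat_noise_sd=0.0,
            sex_offset=0.0, age_slope=0.0, seed=9,
        )
        g = simulate_genotypes(cfg)
        pheno = simulate_biomarkers(g, cfg)
        gen = pheno.truth["genetic"]["bm01"].to_numpy()
        lat = pheno.truth["latent"]["bm01"].to_numpy()
        assert abs(gen.var() / lat.var() - 0.4) < 0.03

    def test_shared_environment_identical_within_pair_and_raises_sib_corr(self, demo_config, demo_cohort):
        g, pheno = demo_cohort
        lat = pheno.truth["latent"].set_index("sample_id")
        gen = pheno.truth["genetic"].set_index("sample_id")
        pairs = pheno.sibling_pairs()
        env = lat - gen  # environment + residual noise
        sib_corr = np.corrcoef(
            [env.loc[a, "bm01"] for a, b in pairs], [env.loc[b, "bm01"] for a, b in pairs]
        )[0, 1]
        rng = np.random.default_rng(0)
        ids = rng.permutation(pheno.sample_ids)
        rnd_corr = np.corrcoef(
            [env.loc[a, "bm01"] for a in ids[: len(pairs)]],
            [env.loc[b, "bm01"] for b in ids[len(pairs) : 2 * len(pairs)]],
        )[0, 1]
        assert sib_corr > rnd_corr

    def test_zero_causal_variance_raises(self):
        cfg = SimulationConfig(n_samples=100, n_snps=10, n_biomarkers=1,
                               n_causal_per_biomarker=0, heritability_h2=0.5, n_sibling_pairs=0, seed=1)
        with pytest.raises(SimulationError):
            draw_architecture(cfg, base_allele_frequencies(cfg))


class TestDisease:
    def test_prevalence_exact_up_to_rounding(self, demo_cohort):
        _, pheno = demo_cohort
        n = len(pheno.samples)
        assert pheno.status("metabolic").sum() == round(n * 0.15)

    def test_null_disease_auc_half(self):
        cfg = SimulationConfig(
            n_samples=4000, n_snps=50, n_biomarkers=2, n_sibling_pairs=0,
            disease_specs=[DiseaseSpec("null", {}, 0.0, 1.0, 0.2)], seed=6,
        )
        g, pheno = simulate_cohort(cfg)
        from gbmrs.evaluate import auc

        lat = pheno.truth["latent"]["bm01"].to_numpy()
        status = pheno.status("null").to_numpy()
        assert abs(auc(lat, status) - 0.5) < 0.03

    def test_liability_oracle_auc_is_maximal(self, demo_cohort):
        # the true liability separates cases from controls better than any
        # other score; its AUC equals the brute-force value of thresholding
        from gbmrs.evaluate import auc

        _, pheno = demo_cohort
        liab = pheno.truth["liability"]["metabolic"].to_numpy()
        status = pheno.status("metabolic").to_numpy()
        assert auc(liab, status) == 1.0  # thresholded on its own order statistics

    def test_too_few_samples_raise(self):
        cfg = SimulationConfig(
            n_samples=5, n_snps=10, n_biomarkers=1, n_causal_per_biomarker=5, n_sibling_pairs=0,
            disease_specs=[DiseaseSpec("d", {"bm01": 1.0}, prevalence=0.01)], seed=1,
        )
        with pytest.raises(SimulationError):
            simulate_cohort(cfg)


class TestDivergedCohort:
    def test_fst_zero_keeps_frequencies(self):
        cfg = SimulationConfig(n_samples=500, n_snps=100, seed=12)
        base = base_allele_frequencies(cfg)
        g = simulate_diverged_cohort(cfg, base, fst=0.0)
        assert np.allclose(g.realized_mafs(), base, atol=0.1)

    def test_divergence_scales_with_fst(self):
        cfg = SimulationConfig(n_samples=2000, n_snps=2000, seed=12)
        base = base_allele_frequencies(cfg)
        drift = {}
        for fst in (0.01, 0.15):
            g = simulate_diverged_cohort(cfg, base, fst=fst)
            drift[fst] = np.mean((g.realized_mafs() - base) ** 2 / (base * (1 - base)))
        assert drift[0.15] > drift[0.01]
        assert abs(drift[0.15] - 0.15) < 0.03

    def test_pgs_performance_falls_off_with_fst(self):
        # causal effects are held fixed, so larger allele-frequency divergence
        # shrinks the realized genetic variance and the trained score's
        # correlation with the phenotype in the diverged cohort
        from gbmrs.predictors import apply_to_genotypes
        from gbmrs.sparse_model import lasso_path, select_lambda
        from gbmrs.synthdata import draw_architecture

        drop = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_samples=2500, n_snps=300, n_biomarkers=1, n_causal_per_biomarker=20,
                heritability_h2=0.6, shared_env_var=0.0, n_sibling_pairs=0,
                repeat_noise_sd=0.0, sex_offset=0.0, age_slope=0.0, seed=40 + seed,
            )
            base_f = base_allele_frequencies(cfg)
            arch = draw_architecture(cfg, base_f)
            geno = simulate_genotypes(cfg)
            pheno = simulate_biomarkers(geno, cfg, architecture=arch)
            first = pheno.measurements[pheno.measurements["visit"] == 1]
            y = first.set_index("sample_id")["value"].reindex(geno.sample_ids).to_numpy()
            path = lasso_path(geno.dosages[:2000], y[:2000], feature_ids=geno.snp_ids, n_lambda=25)
            best = select_lambda(path, geno.dosages[2000:], y[2000:], metric="correlation")
            corr = {}
            for fst in (0.01, 0.15):
                div = simulate_diverged_cohort(cfg, base_f, fst=fst, n_samples=2500)
                div_pheno = simulate_biomarkers(div, cfg, architecture=arch)
                dfirst = div_pheno.measurements[div_pheno.measurements["visit"] == 1]
                yd = dfirst.set_index("sample_id")["value"].reindex(div.sample_ids).to_numpy()
                corr[fst] = np.corrcoef(apply_to_genotypes(best, div), yd)[0, 1]
            drop.append(corr[0.01] - corr[0.15])
        assert np.mean(drop) > 0

    def test_frequencies_stay_in_unit_interval(self):
        cfg = SimulationConfig(n_samples=100, n_snps=500, seed=1)
        base = base_allele_frequencies(cfg)
        g = simulate_diverged_cohort(cfg, base, fst=0.3)
        assert ((g.dosages >= 0) & (g.dosages <= 2)).all()


def test_full_cohort_deterministic(demo_config):
    g1, p1 = simulate_cohort(demo_config)
    g2, p2 = simulate_cohort(demo_config)
    assert np.array_equal(g1.dosages, g2.dosages)
    pd.testing.assert_frame_equal(p1.samples, p2.samples)
    pd.testing.assert_frame_equal(p1.measurements, p2.measurements)
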