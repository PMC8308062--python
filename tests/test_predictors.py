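import numpy as np
import pandas as pd
import pytest

from gbmrs.data import GenotypeMatrix
from gbmrs.errors import ApplicationError, UsageError
from gbmrs.evaluate import auc, correlation
from gbmrs.predictors import (
    apply_predictor,
    apply_to_genotypes,
    combine_scores,
    concatenate_gbmrs,
    gbmrs_score,
    pgs_reference_constants,
    quadratic_features,
    quadratic_interaction_check,
    relative_weight_table,
    snp_variance_accounted,
    train_bmrs,
    train_pgs,
)
from gbmrs.preprocess import preprocess_biomarkers
from gbmrs.sparse_model import SparseLinearPredictor, lasso_path, make_splits
from gbmrs.synthdata import (
    DiseaseSpec,
    SimulationConfig,
    base_allele_frequencies,
    simulate_biomarkers,
    simulate_cohort,
    simulate_genotypes,
    single_locus_architecture,
)


def _predictor(weights, ids=None, intercept=0.0, means=None, sds=None, namespace="snps"):
    weights = np.asarray(weights, float)
    p = len(weights)
    return SparseLinearPredictor(
        namespace=namespace,
        feature_ids=ids or [f"f{j}" for j in range(p)],
        weights=weights,
        intercept=intercept,
        lam=0.1,
        feature_means=means if means is not None else np.zeros(p),
        feature_sds=sds if sds is not None else np.ones(p),
    )


class TestApplyPredictor:
    def test_all_zero_weights_constant_intercept(self):
        pred = _predictor([0.0, 0.0], intercept=1.5)
        feats = pd.DataFrame({"f0": [1.0, 2.0], "f1": [0.0, 5.0]})
        np.testing.assert_array_equal(apply_predictor(pred, feats), [1.5, 1.5])

    def test_training_scores_reproduced(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4))
        y = X[:, 0] + rng.standard_normal(50)
        pred = lasso_path(X, y, n_lambda=10)[-1]
        feats = pd.DataFrame(X, columns=pred.feature_ids)
        np.testing.assert_allclose(apply_predictor(pred, feats), pred.predict(X), atol=1e-12)

    def test_duplicated_feature_errors(self):
        pred = _predictor([1.0, 1.0])
        feats = pd.DataFrame(np.ones((3, 2)), columns=["f0", "f0"])
        with pytest.raises(ApplicationError):
            apply_predictor(pred, feats)

    def test_excess_missing_features_error(self):
        pred = _predictor(np.ones(20))
        feats = pd.DataFrame(np.ones((3, 2)), columns=["f0", "f1"])
        with pytest.raises(ApplicationError):
            apply_predictor(pred, feats)


class TestPGS:
    def test_single_locus_trait_dominates_support(self):
        cfg = SimulationConfig(
            n_samples=2500, n_snps=150, n_biomarkers=1, n_causal_per_biomarker=1,
            heritability_h2=0.6, shared_env_var=0.0, n_sibling_pairs=60,
            repeat_noise_sd=0.1, seed=21,
        )
        arch = single_locus_architecture(cfg, base_allele_frequencies(cfg))
        geno, pheno = simulate_cohort(cfg, architecture=arch)
        vals, _ = preprocess_biomarkers(pheno, pheno.sample_ids)
        split = make_splits(pheno.sample_ids, pheno.sibling_pairs(), n_validation=150, seed=1)
        ens = train_pgs(geno, vals["bm01"], split, n_lambda=30)
        causal_snp = geno.snp_ids[arch.causal_idx["bm01"][0]]
        for pred in ens:
            top = pred.feature_ids[np.argmax(np.abs(pred.weights))]
            assert top == causal_snp
        # and that locus carries essentially all the variance accounted for
        arch_report = snp_variance_accounted(ens[0], geno.snps)
        tab = arch_report.table.set_index("snp_id")
        assert tab.loc[causal_snp, "var_accounted"] / arch_report.table["var_accounted"].sum() > 0.9

    def test_null_trait_evaluation_correlation_near_zero(self):
        cfg = SimulationConfig(
            n_samples=1500, n_snps=100, n_biomarkers=1, n_causal_per_biomarker=10,
            heritability_h2=0.0, shared_env_var=0.0, n_sibling_pairs=100, seed=22,
        )
        geno, pheno = simulate_cohort(cfg)
        vals, _ = preprocess_biomarkers(pheno, pheno.sample_ids)
        split = make_splits(pheno.sample_ids, pheno.sibling_pairs(), n_validation=100, seed=1)
        ens = train_pgs(geno, vals["bm01"], split, n_lambda=20)
        ev = geno.subset_samples(split.evaluation)
        y = vals.loc[split.evaluation, "bm01"].to_numpy()
        corrs = [correlation(apply_to_genotypes(p, ev), y) for p in ens]
        assert abs(np.mean(corrs)) < 3.0 / np.sqrt(len(split.evaluation))


class TestGBMRS:
    def test_perfect_pgs_identity_with_bmrs(self, demo_cohort):
        # when PGS outputs equal the true biomarker values and the z-scoring
        # reference is the BMRS training set, the concatenated score is an
        # exact affine image of the BMRS score: Spearman rho = 1
        from scipy.stats import spearmanr

        geno, pheno = demo_cohort
        feats, _ = preprocess_biomarkers(pheno, pheno.sample_ids, mode="first")
        status = pheno.status("metabolic")
        split = make_splits(pheno.sample_ids, pheno.sibling_pairs(), n_validation=120, seed=2)
        ens = train_bmrs(feats, status, split, n_lambda=20)
        bmrs = ens[0]
        train_ids = split.training[0]
        ev = split.evaluation
        # z-reference from the BMRS training population's *true* values
        z_ref = {
            bm: (feats.loc[train_ids, bm].mean(), feats.loc[train_ids, bm].std(ddof=0))
            for bm in feats.columns
        }

        class PerfectPGS:
            pass

        # emulate gbmrs_score by hand with perfect "PGS outputs"
        score = np.full(len(ev), bmrs.intercept)
        for j in bmrs.support:
            bm = bmrs.feature_ids[j]
            mu, sd = z_ref[bm]
            score += bmrs.weights[j] * (feats.loc[ev, bm].to_numpy() - mu) / sd
        bmrs_scores = apply_predictor(bmrs, feats.loc[ev])
        rho = spearmanr(score, bmrs_scores).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_pgs_gives_half_auc(self, demo_cohort):
        geno, pheno = demo_cohort
        feats, _ = preprocess_biomarkers(pheno, pheno.sample_ids, mode="first")
        status = pheno.status("metabolic")
        split = make_splits(pheno.sample_ids, pheno.sibling_pairs(), n_validation=120, seed=2)
        bmrs = train_bmrs(feats, status, split, n_lambda=20)[0]
        rng = np.random.default_rng(0)
        noise_pgs = {
            bm: _predictor(rng.standard_normal(geno.n_snps) * 0.01, ids=geno.snp_ids)
            for bm in feats.columns
        }
        z_ref = pgs_reference_constants(noise_pgs, geno.subset_samples(split.training[0]))
        ev = geno.subset_samples(split.evaluation)
        s = gbmrs_score(noise_pgs, bmrs, ev, z_ref)
        y = status.reindex(split.evaluation).to_numpy()
        assert abs(auc(s, y) - 0.5) < 0.15  # pure noise scores

    def test_all_combination_count(self, demo_cohort):
        geno, pheno = demo_cohort
        feats, _ = preprocess_biomarkers(pheno, pheno.sample_ids, mode="first")
        status = pheno.status("metabolic")
        split = make_splits(pheno.sample_ids, pheno.sibling_pairs(), n_validation=120, seed=2)
        bmrs_ens = train_bmrs(feats, status, split, n_lambda=10)
        rng = np.random.default_rng(1)
        pgs_ens = {
            bm: [_predictor(rng.standard_normal(geno.n_snps) * 0.01, ids=geno.snp_ids) for _ in range(5)]
            for bm in feats.columns
        }
        ev = geno.subset_samples(split.evaluation[:40])
        ref = geno.subset_samples(split.training[0][:200])
        scores = concatenate_gbmrs(pgs_ens, bmrs_ens, ev, ref)
        assert len(scores) == 25
        assert all(len(s) == 40 for s in scores)


class TestCombineScores:
    def test_constant_second_score_preserves_ranks(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        combined = combine_scores(a, np.zeros(100))
        assert np.array_equal(np.argsort(combined), np.argsort(a))

    def test_identical_scores_preserve_ranks(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(100)
        combined = combine_scores(a, a.copy())
        assert np.array_equal(np.argsort(combined), np.argsort(a))

    def test_independent_signals_combine_better(self):
        rng = np.random.default_rng(2)
        n = 30_000
        liab = rng.standard_normal(n)
        status = (liab > 1.0).astype(int)
        gains = []
        for _ in range(5):
            a = liab + 1.5 * rng.standard_normal(n)
            b = liab + 1.5 * rng.standard_normal(n)
            both = auc(combine_scores(a, b), status)
            gains.append(both - max(auc(a, status), auc(b, status)))
        assert np.mean(gains) > 0

    def test_length_mismatch_errors(self):
        with pytest.raises(UsageError):
            combine_scores(np.ones(3), np.ones(4))


class TestArchitecture:
    def _meta(self, p, mafs=None):
        return pd.DataFrame(
            {
                "snp_id": [f"f{j}" for j in range(p)],
                "chrom": [(j % 22) + 1 for j in range(p)],
                "pos": range(1, p + 1),
                "effect_allele": ["A"] * p,
                "maf": mafs if mafs is not None else [0.5] * p,
            }
        )

    def test_formula_substitution(self):
        pred = _predictor([1.0, 0.0], means=np.array([1.0, 1.0]), sds=np.array([1.0, 1.0]))
        rep = snp_variance_accounted(pred, self._meta(2))
        assert rep.table.set_index("snp_id").loc["f0", "var_accounted"] == pytest.approx(0.25)
        assert rep.n_nonzero == 1

    def test_zero_weight_contributes_nothing(self):
        pred = _predictor([0.5, 0.0])
        rep = snp_variance_accounted(pred, self._meta(2))
        assert "f1" not in set(rep.table["snp_id"])

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(3)
        p = 60
        pred = _predictor(rng.standard_normal(p), sds=np.abs(rng.standard_normal(p)) + 0.5)
        rep = snp_variance_accounted(pred, self._meta(p, mafs=rng.uniform(0.05, 0.5, p)))
        assert rep.chromosome_shares.sum() == pytest.approx(1.0)
        assert (rep.table["var_accounted"] >= 0).all()

    def test_factor_two_flag_doubles_but_keeps_shares(self):
        rng = np.random.default_rng(4)
        p = 10
        pred = _predictor(rng.standard_normal(p))
        meta = self._meta(p, mafs=rng.uniform(0.1, 0.5, p))
        a = snp_variance_accounted(pred, meta)
        b = snp_variance_accounted(pred, meta, factor_two=True)
        np.testing.assert_allclose(b.table["var_accounted"], 2 * a.table["var_accounted"])
        pd.testing.assert_series_equal(a.chromosome_shares, b.chromosome_shares)

    def test_shares_invariant_under_chromosome_relabeling(self):
        rng = np.random.default_rng(5)
        p = 44
        pred = _predictor(rng.standard_normal(p))
        meta = self._meta(p, mafs=rng.uniform(0.1, 0.5, p))
        a = snp_variance_accounted(pred, meta)
        perm = dict(zip(range(1, 23), rng.permutation(np.arange(1, 23))))
        meta2 = meta.assign(chrom=meta["chrom"].map(perm))
        b = snp_variance_accounted(pred, meta2)
        for c_old, c_new in perm.items():
            if c_old in a.chromosome_shares.index:
                assert a.chromosome_shares[c_old] == pytest.approx(b.chromosome_shares[c_new])

    def test_bad_maf_errors(self):
        pred = _predictor([1.0])
        with pytest.raises(UsageError):
            snp_variance_accounted(pred, self._meta(1, mafs=[1.5]))


class TestRelativeWeights:
    def test_top_entry_is_unit(self):
        ens = [_predictor([0.5, -1.0, 0.2], namespace="biomarkers") for _ in range(3)]
        tab = relative_weight_table(ens)
        assert tab["relative_weight"].iloc[0] == pytest.approx(-1.0)
        assert tab["feature_id"].iloc[0] == "f1"


class TestQuadraticInteractions:
    def test_k1_adds_single_square(self):
        feats = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]})
        out = quadratic_features(feats, ["a"])
        assert list(out.columns) == ["a", "b", "a^2"]

    def test_k3_adds_six_columns(self):
        feats = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 4)), columns=list("abcd"))
        out = quadratic_features(feats, ["a", "b", "c"])
        assert out.shape[1] == 4 + 6

    def test_product_driven_disease_detected(self):
        rng = np.random.default_rng(6)
        n = 4000
        ids = [f"s{i}" for i in range(n)]
        feats = pd.DataFrame(
            {f"x{j}": rng.standard_normal(n) for j in range(6)}, index=ids
        )
        liab = (
            0.4 * feats["x0"] + 0.4 * feats["x1"]
            + 2.0 * feats["x0"] * feats["x1"] + 0.5 * rng.standard_normal(n)
        )
        status = pd.Series((liab > np.quantile(liab, 0.8)).astype(int), index=ids)
        pairs = [(ids[2 * i], ids[2 * i + 1]) for i in range(60)]
        split = make_splits(ids, pairs, n_validation=300, seed=0)
        out = quadratic_interaction_check(feats, status, split, top_k=3, n_lambda=20)
        assert out["n_new_columns"] == 6
        assert np.mean(out["augmented_auc"]) > np.mean(out["linear_auc"])

    def test_linear_disease_no_gain(self, demo_cohort):
        _, pheno = demo_cohort
        feats, _ = preprocess_biomarkers(pheno, pheno.sample_ids, mode="first")
        status = pheno.status("metabolic")
        split = make_splits(pheno.sample_ids, pheno.sibling_pairs(), n_validation=120, seed=3)
        out = quadratic_interaction_check(feats, status, split, top_k=2, n_lambda=15)
        diff = np.mean(out["augmented_auc"]) - np.mean(out["linear_auc"])
        spread = max(np.std(out["linear_auc"]), 0.01)
        assert abs(diff) < 3 * spread
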