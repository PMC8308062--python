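"""Concatenate PGS through BMRS (gBMRS) and compare with a direct PRS.

The concatenation F(G(x)) applies the trained biomarker risk score, without
retraining, to z-scored polygenic predictions of each biomarker, so disease
risk is predicted from genotype alone with biomarkers as an intermediate
layer. The direct route trains the sparse model straight on case status.
The AUC ordering BMRS > gBMRS is expected: replacing measured biomarkers by
noisy genetic predictions of them cannot help the same fixed function.
Summing the two genotype-only scores probes whether they carry
complementary information.
"""

import numpy as np

from gbmrs import (
    DiseaseSpec,
    SimulationConfig,
    combine_scores,
    concatenate_gbmrs,
    simulate_cohort,
    train_bmrs,
    train_pgs,
    train_prs,
)
from gbmrs.evaluate import auc, ensemble_stats
from gbmrs.predictors import apply_predictor, apply_to_genotypes
from gbmrs.preprocess import preprocess_biomarkers
from gbmrs.sparse_model import make_splits

config = SimulationConfig(
    n_samples=8000, n_snps=400, n_biomarkers=8, n_causal_per_biomarker=12,
    heritability_h2=0.6, shared_env_var=0.1, n_sibling_pairs=300,
    disease_specs=[
        DiseaseSpec("dz", {"bm01": 1.0, "bm02": 0.8}, 0.4, 0.25, 0.10)
    ],
    seed=9,
)
genotypes, phenotypes = simulate_cohort(config)
splits = make_splits(phenotypes.sample_ids, phenotypes.sibling_pairs(),
                     n_validation=600, seed=9)
status = phenotypes.status("dz")
eval_ids = splits.evaluation
y_eval = status.reindex(eval_ids).to_numpy(float)
eval_geno = genotypes.subset_samples(eval_ids)
train_geno = genotypes.subset_samples(splits.training[0])

feats_first, _ = preprocess_biomarkers(phenotypes, splits.training[0], mode="first")
bmrs = train_bmrs(feats_first, status, splits, n_lambda=25)
bmrs_auc = ensemble_stats(
    [auc(apply_predictor(p, feats_first.loc[eval_ids]), y_eval) for p in bmrs]
)

vals_mean, _ = preprocess_biomarkers(phenotypes, splits.training[0], mode="mean")
pgs = {bm: train_pgs(genotypes, vals_mean[bm], splits, n_lambda=25)[:2] for bm in feats_first.columns}
gbmrs_scores = concatenate_gbmrs(pgs, bmrs[:2], eval_geno, train_geno)
gbmrs_auc = ensemble_stats([auc(s, y_eval) for s in gbmrs_scores])

prs = train_prs(genotypes, status, splits, n_lambda=25)
prs_scores = [apply_to_genotypes(p, eval_geno) for p in prs]
prs_auc = ensemble_stats([auc(s, y_eval) for s in prs_scores])

combined = combine_scores(gbmrs_scores[0], prs_scores[0])

print(f"BMRS  (measured biomarkers -> status): AUC {bmrs_auc.mean:.3f} +- {bmrs_auc.sd:.3f}")
print(f"gBMRS (SNPs -> biomarkers -> status) : AUC {gbmrs_auc.mean:.3f} +- {gbmrs_auc.sd:.3f} "
      f"({len(gbmrs_scores)} concatenation combinations)")
print(f"PRS   (SNPs -> status directly)      : AUC {prs_auc.mean:.3f} +- {prs_auc.sd:.3f}")
print(f"gBMRS + PRS (z-scored sum)           : AUC {auc(combined, y_eval):.3f}")
print(f"corr(gBMRS, PRS) on the evaluation set: "
      f"{np.corrcoef(gbmrs_scores[0], prs_scores[0])[0, 1]:.3f}")
print("(the two genotype-only routes overlap heavily here; the summed score "
      "helps only when they capture complementary signal)")
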