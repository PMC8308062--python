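"""The four predictor types and the genetic-architecture decomposition.

PGS    — sparse linear predictors of a quantitative biomarker from SNP
         dosages, trained per cross-validation fold (lambda by validation
         correlation).
BMRS   — sparse linear predictors of disease status from measured
         biomarkers (lambda by validation AUC; sex-stratified by the
         caller passing one stratum at a time).
gBMRS  — the concatenation F(G(x)): BMRS weights applied, without
         retraining, to z-scored PGS outputs, so only genotypes are needed
         at application time.
PRS    — a sparse linear predictor of disease status trained directly on
         SNP dosages.

The architecture report decomposes a SNP predictor's signal into per-SNP
variance accounted for, beta_i^2 * (1 - f_i) * f_i, aggregated per
chromosome. The conventional additive-genotype variance carries a factor 2;
the report uses the unscaled form by default (the factor cancels in
normalized shares) and exposes the factor-2 variant behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .errors import ApplicationError, UsageError
from .evaluate import auc as _auc
from .sparse_model import (
    FoldSplit,
    SparseLinearPredictor,
    train_ensemble,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# training wrappers


def train_pgs(
    genotypes: GenotypeMatrix,
    biomarker: pd.Series,
    folds: FoldSplit,
    **path_kwargs,
) -> list[SparseLinearPredictor]:
    """Five-fold ensemble predicting a preprocessed biomarker from dosages."""
    y = biomarker.reindex(genotypes.sample_ids).to_numpy(float)
    if np.isnan(y).any():
        raise UsageError("biomarker values missing for some genotyped samples")
    return train_ensemble(
        genotypes.dosages,
        y,
        genotypes.sample_ids,
        folds,
        metric="correlation",
        feature_ids=genotypes.snp_ids,
        namespace="snps",
        **path_kwargs,
    )


def train_bmrs(
    features: pd.DataFrame,
    status: pd.Series,
    folds: FoldSplit,
    **path_kwargs,
) -> list[SparseLinearPredictor]:
    """Five-fold ensemble predicting case status from biomarker features.

    Features should be first-measurement, sex-z-scored, age-corrected values
    with the excluded biomarkers already dropped; ``folds`` must be built on
    the same (possibly sex-stratified) sample set.
    """
    sample_ids = list(features.index)
    y = status.reindex(sample_ids).to_numpy(float)
    if np.isnan(y).any():
        raise UsageError("status missing for some samples")
    return train_ensemble(
        features.to_numpy(float),
        y,
        sample_ids,
        folds,
        metric="auc",
        feature_ids=list(features.columns),
        namespace="biomarkers",
        **path_kwargs,
    )


def train_prs(
    genotypes: GenotypeMatrix,
    status: pd.Series,
    folds: FoldSplit,
    **path_kwargs,
) -> list[SparseLinearPredictor]:
    """Polygenic risk score: case status regressed directly on dosages."""
    y = status.reindex(genotypes.sample_ids).to_numpy(float)
    if np.isnan(y).any():
        raise UsageError("status missing for some genotyped samples")
    return train_ensemble(
        genotypes.dosages,
        y,
        genotypes.sample_ids,
        folds,
        metric="auc",
        feature_ids=genotypes.snp_ids,
        namespace="snps",
        **path_kwargs,
    )


# ---------------------------------------------------------------------------
# application


def apply_predictor(
    predictor: SparseLinearPredictor,
    features: pd.DataFrame,
    max_missing_fraction: float = 0.05,
) -> np.ndarray:
    """Score a feature table (columns keyed by feature id).

    Features absent from the table contribute their training-mean
    standardized value, i.e. zero; more than ``max_missing_fraction`` of the
    predictor's features absent is an error, as is a duplicated column.
    """
    if features.columns.duplicated().any():
        dup = features.columns[features.columns.duplicated()][0]
        raise ApplicationError(f"duplicated feature id in input: {dup!r}")
    present = [f for f in predictor.feature_ids if f in features.columns]
    missing = len(predictor.feature_ids) - len(present)
    if missing > max_missing_fraction * len(predictor.feature_ids):
        raise ApplicationError(
            f"{missing}/{len(predictor.feature_ids)} predictor features absent from input"
        )
    if missing:
        logger.warning("%d predictor features absent; contributing zero", missing)
    scores = np.full(len(features), predictor.intercept, dtype=float)
    col = {f: j for j, f in enumerate(predictor.feature_ids)}
    for f in present:
        j = col[f]
        z = (features[f].to_numpy(float) - predictor.feature_means[j]) / predictor.feature_sds[j]
        scores += predictor.weights[j] * z
    return scores


def apply_to_genotypes(predictor: SparseLinearPredictor, genotypes: GenotypeMatrix) -> np.ndarray:
    """Score genotypes; only the support columns are touched (sparse apply)."""
    idx = {s: j for j, s in enumerate(genotypes.snp_ids)}
    scores = np.full(genotypes.n_samples, predictor.intercept)
    support = predictor.support
    missing = sum(1 for j in support if predictor.feature_ids[j] not in idx)
    if missing > 0.05 * max(len(support), 1):
        raise ApplicationError(f"{missing}/{len(support)} support SNPs absent from genotypes")
    for j in support:
        f = predictor.feature_ids[j]
        if f not in idx:
            continue
        z = (genotypes.dosages[:, idx[f]] - predictor.feature_means[j]) / predictor.feature_sds[j]
        scores += predictor.weights[j] * z
    return scores


# ---------------------------------------------------------------------------
# concatenation (gBMRS)


def pgs_reference_constants(
    pgs_by_biomarker: dict[str, SparseLinearPredictor],
    reference_genotypes: GenotypeMatrix,
) -> dict[str, tuple[float, float]]:
    """Freeze z-scoring constants from the training population's PGS outputs."""
    out = {}
    for bm, pred in pgs_by_biomarker.items():
        s = apply_to_genotypes(pred, reference_genotypes)
        sd = float(s.std())
        out[bm] = (float(s.mean()), sd if sd > 0 else 1.0)
    return out


def gbmrs_score_from_outputs(
    outputs: pd.DataFrame,
    bmrs: SparseLinearPredictor,
    z_reference: dict[str, tuple[float, float]],
) -> np.ndarray:
    """Apply BMRS weights, as trained, to z-scored predicted-biomarker values.

    ``outputs`` holds one column per biomarker of raw PGS outputs; each is
    z-scored against the reference (training-population) distribution before
    the BMRS weight is applied. Biomarkers without a column contribute zero
    (their training-mean value) and are logged.
    """
    score = np.full(len(outputs), bmrs.intercept)
    for j in bmrs.support:
        bm = bmrs.feature_ids[j]
        if bm not in outputs.columns:
            logger.warning("no PGS output for biomarker %r; contributes zero to gBMRS", bm)
            continue
        if bm not in z_reference:
            raise UsageError(f"no frozen z-scoring constants for biomarker {bm!r}")
        mu, sd = z_reference[bm]
        score += bmrs.weights[j] * (outputs[bm].to_numpy(float) - mu) / sd
    return score


def gbmrs_score(
    pgs_by_biomarker: dict[str, SparseLinearPredictor],
    bmrs: SparseLinearPredictor,
    genotypes: GenotypeMatrix,
    z_reference: dict[str, tuple[float, float]],
) -> np.ndarray:
    """Concatenated score: BMRS weights over z-scored PGS outputs.

    A pure function of genotypes: each biomarker with nonzero BMRS weight is
    replaced by its PGS output before the (frozen) z-scoring and weighting.
    """
    needed = {bmrs.feature_ids[j] for j in bmrs.support} & set(pgs_by_biomarker)
    outputs = pd.DataFrame(
        {bm: apply_to_genotypes(pgs_by_biomarker[bm], genotypes) for bm in sorted(needed)},
        index=genotypes.sample_ids,
    )
    return gbmrs_score_from_outputs(outputs, bmrs, z_reference)


def concatenate_gbmrs(
    pgs_ensembles: dict[str, list[SparseLinearPredictor]],
    bmrs_ensemble: list[SparseLinearPredictor],
    genotypes: GenotypeMatrix,
    reference_genotypes: GenotypeMatrix,
) -> list[np.ndarray]:
    """All ensemble-member concatenation combinations (5 x 5 = 25 scores).

    For PGS ensemble index j and BMRS member i, the PGS member j of every
    biomarker is concatenated through BMRS member i; z-scoring constants are
    frozen per (biomarker, j) from the reference (training) genotypes.
    """
    n_pgs = min(len(e) for e in pgs_ensembles.values()) if pgs_ensembles else 0
    scores = []
    for j in range(n_pgs):
        member = {bm: ens[j] for bm, ens in pgs_ensembles.items()}
        z_ref = pgs_reference_constants(member, reference_genotypes)
        for bmrs in bmrs_ensemble:
            scores.append(gbmrs_score(member, bmrs, genotypes, z_ref))
    return scores


def combine_scores(score_a: np.ndarray, score_b: np.ndarray) -> np.ndarray:
    """Sum of the two risk scores after z-scoring over the evaluated cohort."""
    a = np.asarray(score_a, float)
    b = np.asarray(score_b, float)
    if a.shape != b.shape:
        raise UsageError("scores cover different numbers of samples")

    def _z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    return _z(a) + _z(b)


# ---------------------------------------------------------------------------
# genetic architecture


@dataclass
class ArchitectureReport:
    """Per-SNP variance decomposition of a SNP-space predictor."""

    table: pd.DataFrame  # snp_id, chrom, pos, beta, maf, var_accounted, cum_share
    chromosome_shares: pd.Series  # normalized, sums to 1 when total > 0
    n_nonzero: int

    def top_loci(self, k: int = 10) -> pd.DataFrame:
        return self.table.nlargest(k, "var_accounted").reset_index(drop=True)


def snp_variance_accounted(
    predictor: SparseLinearPredictor,
    snp_meta: pd.DataFrame,
    factor_two: bool = False,
) -> ArchitectureReport:
    """Variance accounted for by each SNP: beta_i^2 * (1 - f_i) * f_i.

    ``beta`` is the raw (per-dosage) effect size; ``snp_meta`` supplies
    chrom/pos/maf per snp_id. ``factor_two=True`` switches to the full
    additive-genotype variance 2 f (1 - f) beta^2; normalized shares are
    identical either way.
    """
    meta = snp_meta.set_index("snp_id")
    support = predictor.support
    ids = [predictor.feature_ids[j] for j in support]
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise UsageError(f"no metadata for SNPs {missing[:5]}")
    f = meta.loc[ids, "maf"].to_numpy(float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise UsageError("MAF outside (0, 1) in SNP metadata")
    beta = predictor.raw_weights[support]
    var = beta**2 * (1.0 - f) * f
    if factor_two:
        var = 2.0 * var
    tab = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": meta.loc[ids, "chrom"].to_numpy(),
            "pos": meta.loc[ids, "pos"].to_numpy(),
            "beta": beta,
            "maf": f,
            "var_accounted": var,
        }
    ).sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    total = float(tab["var_accounted"].sum())
    tab["cum_share"] = tab["var_accounted"].cumsum() / total if total > 0 else 0.0
    by_chrom = tab.groupby("chrom")["var_accounted"].sum()
    shares = by_chrom / total if total > 0 else by_chrom
    return ArchitectureReport(table=tab, chromosome_shares=shares, n_nonzero=len(support))


def relative_weight_table(ensemble: list[SparseLinearPredictor]) -> pd.DataFrame:
    """Mean weights normalized by the largest magnitude (top entry = +-1).

    The per-feature spread over the ensemble is reported alongside, matching
    the coefficient plots used for disease predictors.
    """
    ids = ensemble[0].feature_ids
    W = np.stack([p.weights for p in ensemble])
    mean_w = W.mean(axis=0)
    scale = np.abs(mean_w).max()
    if scale == 0:
        raise UsageError("all-zero ensemble weights; nothing to normalize")
    tab = pd.DataFrame(
        {
            "feature_id": ids,
            "relative_weight": mean_w / scale,
            "sd": W.std(axis=0, ddof=1) / scale,
        }
    )
    return tab.reindex(tab["relative_weight"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# nonlinearity probe


def quadratic_features(features: pd.DataFrame, top: list[str]) -> pd.DataFrame:
    """Augment with all squares and pairwise products of the top features."""
    out = features.copy()
    for i, a in enumerate(top):
        for b in top[i:]:
            name = f"{a}*{b}" if a != b else f"{a}^2"
            out[name] = features[a] * features[b]
    # re-z-score the new columns so every feature is on the same scale
    new = out.columns[len(features.columns):]
    for c in new:
        v = out[c]
        sd = v.std(ddof=0)
        out[c] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def quadratic_interaction_check(
    features: pd.DataFrame,
    status: pd.Series,
    folds: FoldSplit,
    top_k: int = 7,
    **path_kwargs,
) -> dict:
    """Does adding quadratic interactions of the top biomarkers help?

    Trains a linear ensemble, takes the ``top_k`` features by mean absolute
    weight, augments the design with their k(k+1)/2 squares and pairwise
    products, retrains, and reports evaluation AUC for both.
    """
    linear = train_bmrs(features, status, folds, **path_kwargs)
    W = np.abs(np.stack([p.weights for p in linear])).mean(axis=0)
    order = np.argsort(-W)[:top_k]
    top = [linear[0].feature_ids[j] for j in order]
    augmented_features = quadratic_features(features, top)
    augmented = train_bmrs(augmented_features, status, folds, **path_kwargs)

    ev = folds.evaluation
    y_ev = status.reindex(ev).to_numpy(float)
    auc_lin = [
        _auc(apply_predictor(p, features.loc[ev]), y_ev) for p in linear
    ]
    auc_aug = [
        _auc(apply_predictor(p, augmented_features.loc[ev]), y_ev) for p in augmented
    ]
    return {
        "top_features": top,
        "n_new_columns": len(top) * (len(top) + 1) // 2,
        "linear_auc": auc_lin,
        "augmented_auc": auc_aug,
    }
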