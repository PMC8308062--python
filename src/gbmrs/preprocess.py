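"""Phenotype and genotype preprocessing.

The pipeline's standard order: collapse repeated measurements (mean for
quantitative-trait prediction, first measurement for disease prediction),
z-score men and women separately, remove the linear birth-year trend fitted
to per-year mean values, and optionally residualize on genotype principal
components. All parameters are fitted on training samples only and applied
frozen to held-out data.

Genotype QC removes SNPs below a MAF floor, SNPs and samples with excessive
missingness, and mean-imputes the remaining missing dosages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import GenotypeMatrix, PhenotypeTable
from .errors import PreprocessingError, QCError, UsageError

#: biomarkers excluded from disease-predictor feature panels (too few
#: measurements in the cohort the defaults emulate)
DEFAULT_DROPPED_BIOMARKERS = ("E2", "MA", "RF")


@dataclass
class PreprocessParams:
    """Frozen preprocessing parameters, fitted on a training set.

    z-scoring uses the population-SD convention (divide by sqrt(mean squared
    deviation)); the convention is recorded so serialized parameters are
    unambiguous.
    """

    sex_stats: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    age_lines: dict[str, tuple[float, float]] = field(default_factory=dict)  # slope, intercept vs birth_year
    pc_coefs: dict[str, np.ndarray] = field(default_factory=dict)
    pc_rescale: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_fitted: int = 0
    sd_convention: str = "population"

    def to_json(self) -> str:
        return json.dumps(
            {
                "sex_stats": self.sex_stats,
                "age_lines": self.age_lines,
                "pc_coefs": {k: list(v) for k, v in self.pc_coefs.items()},
                "pc_rescale": self.pc_rescale,
                "n_fitted": self.n_fitted,
                "sd_convention": self.sd_convention,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessParams":
        raw = json.loads(text)
        return cls(
            sex_stats={
                bm: {sex: tuple(ms) for sex, ms in d.items()} for bm, d in raw["sex_stats"].items()
            },
            age_lines={bm: tuple(v) for bm, v in raw["age_lines"].items()},
            pc_coefs={k: np.asarray(v) for k, v in raw.get("pc_coefs", {}).items()},
            pc_rescale={k: tuple(v) for k, v in raw.get("pc_rescale", {}).items()},
            n_fitted=raw["n_fitted"],
            sd_convention=raw["sd_convention"],
        )


# ---------------------------------------------------------------------------
# repeated measurements


def average_repeats(phenotypes: PhenotypeTable, mode: str = "mean") -> pd.DataFrame:
    """Collapse repeated measurements to one value per sample and biomarker.

    mode="mean" averages repeats (stabler, more heritable signal for
    quantitative-trait prediction); mode="first" keeps the first visit
    (closer to a single clinical blood draw, used for disease prediction).
    Returns a wide DataFrame indexed by sample_id with one column per
    biomarker; samples without any measurement get NaN.
    """
    if mode not in ("mean", "first"):
        raise UsageError(f"unknown repeat mode {mode!r}; expected 'mean' or 'first'")
    meas = phenotypes.measurements
    if mode == "mean":
        wide = meas.groupby(["sample_id", "biomarker"])["value"].mean().unstack()
    else:
        first = meas.sort_values("visit").groupby(["sample_id", "biomarker"])["value"].first()
        wide = first.unstack()
    return wide.reindex(phenotypes.sample_ids)


# ---------------------------------------------------------------------------
# sex-stratified z-scoring


def fit_sex_zscore(
    values: pd.DataFrame, samples: pd.DataFrame, training_ids: list[str]
) -> PreprocessParams:
    """Per-sex, per-biomarker mean and population SD on training samples."""
    sex = samples.set_index("sample_id")["sex"]
    train = values.loc[values.index.intersection(training_ids)]
    if train.empty:
        raise PreprocessingError("no training samples with measurements")
    sexes = set(sex.loc[train.index])
    if sexes != {"male", "female"}:
        raise PreprocessingError("both sexes must be present in the training set")
    params = PreprocessParams(n_fitted=len(train))
    for bm in values.columns:
        params.sex_stats[bm] = {}
        for s in ("male", "female"):
            vals = train.loc[sex.loc[train.index] == s, bm].dropna().to_numpy()
            if len(vals) == 0:
                raise PreprocessingError(f"no {s} training values for biomarker {bm!r}")
            mu = float(vals.mean())
            sd = float(np.sqrt(np.mean((vals - mu) ** 2)))
            if sd <= 0:
                raise PreprocessingError(f"zero within-sex variance for biomarker {bm!r} ({s})")
            params.sex_stats[bm][s] = (mu, sd)
    return params


def apply_sex_zscore(
    values: pd.DataFrame, samples: pd.DataFrame, params: PreprocessParams
) -> pd.DataFrame:
    sex = samples.set_index("sample_id")["sex"].reindex(values.index)
    out = values.copy()
    for bm in values.columns:
        if bm not in params.sex_stats:
            raise UsageError(f"no frozen z-score parameters for biomarker {bm!r}")
        for s, (mu, sd) in params.sex_stats[bm].items():
            rows = sex == s
            out.loc[rows, bm] = (values.loc[rows, bm] - mu) / sd
    return out


def invert_sex_zscore(
    values: pd.DataFrame, samples: pd.DataFrame, params: PreprocessParams
) -> pd.DataFrame:
    """Map z-scored values back to the raw scale (round-trip check)."""
    sex = samples.set_index("sample_id")["sex"].reindex(values.index)
    out = values.copy()
    for bm in values.columns:
        for s, (mu, sd) in params.sex_stats[bm].items():
            rows = sex == s
            out.loc[rows, bm] = values.loc[rows, bm] * sd + mu
    return out


# ---------------------------------------------------------------------------
# birth-year (age) correction


def fit_age_correction(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    training_ids: list[str],
    params: PreprocessParams | None = None,
) -> PreprocessParams:
    """Fit a line to (birth year, per-year mean biomarker) on training data.

    The line is fitted to the year-bin means — every birth year contributes
    one point regardless of how many samples were born that year — and its
    prediction is later subtracted per sample.
    """
    params = params or PreprocessParams(n_fitted=len(training_ids))
    year = samples.set_index("sample_id")["birth_year"]
    train = values.loc[values.index.intersection(training_ids)]
    yrs = year.loc[train.index]
    if yrs.nunique() < 2:
        raise PreprocessingError("age correction needs at least two distinct birth years")
    for bm in values.columns:
        by_year = train[bm].groupby(yrs).mean().dropna()
        if len(by_year) < 2:
            raise PreprocessingError(f"biomarker {bm!r}: fewer than two birth-year bins")
        slope, intercept = np.polyfit(by_year.index.to_numpy(float), by_year.to_numpy(), 1)
        params.age_lines[bm] = (float(slope), float(intercept))
    return params


def apply_age_correction(
    values: pd.DataFrame, samples: pd.DataFrame, params: PreprocessParams
) -> pd.DataFrame:
    year = samples.set_index("sample_id")["birth_year"].reindex(values.index).to_numpy(float)
    out = values.copy()
    for bm in values.columns:
        if bm not in params.age_lines:
            raise UsageError(f"no frozen age line for biomarker {bm!r}")
        slope, intercept = params.age_lines[bm]
        out[bm] = values[bm] - (slope * year + intercept)
    return out


# ---------------------------------------------------------------------------
# principal-component adjustment


def genotype_pcs(genotypes: GenotypeMatrix, n_components: int = 20, seed: int = 0) -> pd.DataFrame:
    """Principal components of the (mean-imputed, centered) dosage matrix."""
    X = genotypes.dosages.copy()
    mask = np.isnan(X)
    if mask.any():
        col_mean = np.nanmean(X, axis=0)
        X[mask] = np.take(col_mean, np.where(mask)[1])
    X = X - X.mean(axis=0)
    n_components = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(X)
    cols = {f"PC{i + 1}": scores[:, i] for i in range(n_components)}
    return pd.DataFrame({"sample_id": genotypes.sample_ids, **cols})


def pc_adjust(
    values: pd.DataFrame,
    pcs: pd.DataFrame,
    training_ids: list[str],
    n_components: int = 20,
) -> tuple[pd.DataFrame, PreprocessParams]:
    """Residualize each biomarker on the first PCs, then re-z-score.

    Regression coefficients and the residual re-z-scoring constants are
    fitted on training samples only; the sibling evaluation set must be
    excluded from ``training_ids`` by the caller.
    """
    pc_cols = [f"PC{i + 1}" for i in range(n_components)]
    missing = [c for c in pc_cols if c not in pcs.columns]
    if missing:
        raise UsageError(f"requested {n_components} components but columns missing: {missing}")
    pcs = pcs.set_index("sample_id") if "sample_id" in pcs.columns else pcs
    P = pcs.reindex(values.index)[pc_cols].to_numpy(float)
    design = np.column_stack([np.ones(len(P)), P])
    train_rows = values.index.isin(training_ids)
    params = PreprocessParams(n_fitted=int(train_rows.sum()))
    out = values.copy()
    for bm in values.columns:
        y = values[bm].to_numpy(float)
        ok = train_rows & np.isfinite(y)
        coef, *_ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
        resid = y - design @ coef
        mu = float(resid[ok].mean())
        sd = float(np.sqrt(np.mean((resid[ok] - mu) ** 2)))
        scale = float(np.sqrt(np.mean((y[ok] - y[ok].mean()) ** 2)))
        if sd <= 1e-10 * max(scale, 1.0):
            raise PreprocessingError(
                f"biomarker {bm!r} is an exact linear function of the PCs; "
                "residual has zero variance and cannot be re-z-scored"
            )
        out[bm] = (resid - mu) / sd
        params.pc_coefs[bm] = coef
        params.pc_rescale[bm] = (mu, sd)
    return out, params


# ---------------------------------------------------------------------------
# genotype QC


@dataclass
class QCReport:
    n_snps_maf_removed: int
    n_snps_missing_removed: int
    n_samples_removed: int
    n_imputed: int


def qc_genotypes(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.001,
    snp_missing_max: float = 0.03,
    sample_missing_max: float = 0.03,
) -> tuple[GenotypeMatrix, QCReport]:
    """Quality-control a genotype matrix.

    Removes SNPs with minor allele frequency below ``maf_min`` or with more
    than ``snp_missing_max`` missing calls, removes samples with more than
    ``sample_missing_max`` missing calls, and mean-imputes the remaining
    missing dosages per SNP.
    """
    X = genotypes.dosages
    mask = np.isnan(X)
    snp_missing = mask.mean(axis=0)
    keep_snp_missing = snp_missing <= snp_missing_max
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_snp_maf = maf >= maf_min
    keep_snp = keep_snp_missing & keep_snp_maf
    if not keep_snp.any():
        raise QCError("QC removed every SNP")
    sample_missing = mask[:, keep_snp].mean(axis=1)
    keep_sample = sample_missing <= sample_missing_max

    out = genotypes.subset_snps(np.flatnonzero(keep_snp))
    out = out.subset_samples([s for s, k in zip(out.sample_ids, keep_sample) if k])
    m = np.isnan(out.dosages)
    n_imputed = int(m.sum())
    if n_imputed:
        col_mean = np.nanmean(out.dosages, axis=0)
        rows, cols = np.where(m)
        out.dosages[rows, cols] = col_mean[cols]
    out.snps["maf"] = out.dosages.mean(axis=0) / 2.0
    report = QCReport(
        n_snps_maf_removed=int((~keep_snp_maf).sum()),
        n_snps_missing_removed=int((~keep_snp_missing & keep_snp_maf).sum()),
        n_samples_removed=int((~keep_sample).sum()),
        n_imputed=n_imputed,
    )
    return out, report


# ---------------------------------------------------------------------------
# convenience wrapper


def preprocess_biomarkers(
    phenotypes: PhenotypeTable,
    training_ids: list[str],
    mode: str = "mean",
    drop: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, PreprocessParams]:
    """Repeat-collapse, sex-z-score and age-correct in the standard order.

    Returns the processed wide table (all samples, frozen training-set
    parameters) and the parameters themselves.
    """
    values = average_repeats(phenotypes, mode=mode)
    values = values.drop(columns=[c for c in drop if c in values.columns])
    params = fit_sex_zscore(values, phenotypes.samples, training_ids)
    z = apply_sex_zscore(values, phenotypes.samples, params)
    params = fit_age_correction(z, phenotypes.samples, training_ids, params=params)
    return apply_age_correction(z, phenotypes.samples, params), params
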