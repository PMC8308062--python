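"""Run-directory pipeline stages.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be chained from the command line or called from
Python. Every output carries the resolved-config hash in its header and the
whole chain is deterministic under the master seed.

Stage order: simulate -> preprocess -> train-pgs -> train-bmrs ->
concat-gbmrs -> train-prs -> evaluate -> calibrate -> report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, preprocess
from .calibrate import apply_calibration, calibration_curve, fit_calibration
from .config import PipelineConfig
from .data import GenotypeMatrix, PhenotypeTable
from .errors import UsageError
from .evaluate import auc, correlation, ensemble_stats, or_curve, sibling_call_fraction, sibling_delta_corr
from .predictors import (
    apply_predictor,
    apply_to_genotypes,
    concatenate_gbmrs,
    relative_weight_table,
    snp_variance_accounted,
    train_bmrs,
    train_pgs,
    train_prs,
)
from .sparse_model import FoldSplit, make_splits, ols_fit
from .synthdata import simulate_cohort

logger = logging.getLogger(__name__)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out

        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper

    return deco


class Run:
    """Handle on a run directory; lazily loads shared inputs."""

    def __init__(self, directory: str | Path, config: PipelineConfig | None = None):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        if config is None:
            cfg_path = self.dir / "config.resolved.yaml"
            if not cfg_path.exists():
                raise UsageError(f"no resolved config in run directory {self.dir}")
            config = PipelineConfig.load(cfg_path)
        self.config = config
        self._geno: GenotypeMatrix | None = None
        self._pheno: PhenotypeTable | None = None

    # -- shared inputs ----------------------------------------------------

    @property
    def genotypes(self) -> GenotypeMatrix:
        if self._geno is None:
            self._geno = io.read_genotypes(self.dir / "genotypes.raw")
        return self._geno

    @property
    def phenotypes(self) -> PhenotypeTable:
        if self._pheno is None:
            self._pheno = io.read_phenotypes(self.dir / "phenotypes.tsv")
            truth_dir = self.dir / "truth"
            if truth_dir.exists():
                for f in sorted(truth_dir.glob("*.tsv")):
                    self._pheno.truth[f.stem] = pd.read_csv(f, sep="\t", comment="#")
        return self._pheno

    @property
    def training_ids(self) -> list[str]:
        sib = {s for p in self.phenotypes.sibling_pairs() for s in p}
        return [s for s in self.phenotypes.sample_ids if s not in sib]

    def splits(self, sample_ids: list[str] | None = None, n_validation: int | None = None) -> FoldSplit:
        pheno = self.phenotypes
        ids = pheno.sample_ids if sample_ids is None else sample_ids
        idset = set(ids)
        pairs = [p for p in pheno.sibling_pairs() if p[0] in idset and p[1] in idset]
        return make_splits(
            ids,
            pairs,
            n_folds=self.config.splits.n_folds,
            n_validation=n_validation or self.config.splits.n_validation,
            seed=self.config.seed,
        )

    def processed(self, mode: str) -> pd.DataFrame:
        tab = pd.read_csv(self.dir / f"processed_{mode}.tsv", sep="\t", comment="#", dtype={"sample_id": str})
        return tab.set_index("sample_id")

    def solver_kwargs(self) -> dict:
        s = self.config.solver
        return {
            "n_lambda": s.n_lambda,
            "min_ratio": s.min_ratio,
            "tol": s.tol,
            "max_sweeps": s.max_sweeps,
        }

    def ensemble_dir(self, kind: str, name: str) -> Path:
        d = self.dir / "weights" / f"{kind}_{name}"
        d.mkdir(parents=True, exist_ok=True)
        return d

    def load_ensemble(self, kind: str, name: str):
        d = self.dir / "weights" / f"{kind}_{name}"
        files = sorted(d.glob("fold*.tsv"))
        if not files:
            raise UsageError(f"no trained ensemble {kind}_{name} under {d}")
        return [io.read_weights(f) for f in files]

    def save_ensemble(self, kind: str, name: str, ensemble) -> None:
        d = self.ensemble_dir(kind, name)
        for k, pred in enumerate(ensemble):
            io.write_weights(pred, d / f"fold{k}.tsv", config_hash=self.config.hash)


# ---------------------------------------------------------------------------
# stages


@_stage("simulate")
def simulate(config: PipelineConfig, directory: str | Path) -> Run:
    """Simulate the cohort and write genotypes, phenotypes and truth tables."""
    run = Run(directory, config)
    geno, pheno = simulate_cohort(config.simulation)
    io.write_genotypes(geno, run.dir / "genotypes.raw", config_hash=config.hash)
    io.write_phenotypes(pheno, run.dir / "phenotypes.tsv", config_hash=config.hash)
    truth_dir = run.dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, tab in pheno.truth.items():
        tab.to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    config.dump(run.dir / "config.resolved.yaml")
    run._geno, run._pheno = geno, pheno
    return run


@_stage("preprocess")
def preprocess_stage(run: Run) -> None:
    """QC genotypes and build the two preprocessed biomarker tables.

    ``processed_mean`` (repeat-averaged; quantitative-trait features) and
    ``processed_first`` (first measurement, configured biomarkers dropped;
    disease-predictor features), both sex-z-scored and age-corrected with
    parameters frozen on the non-sibling training set.
    """
    cfg = run.config
    geno, report = preprocess.qc_genotypes(
        run.genotypes,
        maf_min=cfg.qc.maf_min,
        snp_missing_max=cfg.qc.snp_missing_max,
        sample_missing_max=cfg.qc.sample_missing_max,
    )
    (run.dir / "qc_report.json").write_text(json.dumps(report.__dict__, indent=1))
    if report.n_snps_maf_removed or report.n_snps_missing_removed or report.n_samples_removed:
        io.write_genotypes(geno, run.dir / "genotypes.qc.raw", config_hash=cfg.hash)
        run._geno = geno
    train_ids = run.training_ids
    for mode, drop in (("mean", ()), ("first", tuple(cfg.predictors.dropped_biomarkers))):
        values, params = preprocess.preprocess_biomarkers(
            run.phenotypes, train_ids, mode=mode, drop=drop
        )
        with open(run.dir / f"processed_{mode}.tsv", "w") as fh:
            fh.write(f"# config_hash={cfg.hash}\n")
            values.to_csv(fh, sep="\t", float_format="%.10g")
        (run.dir / f"preprocess_params_{mode}.json").write_text(params.to_json())


def _eval_ids(run: Run) -> list[str]:
    return [s for p in run.phenotypes.sibling_pairs() for s in p]


@_stage("train-pgs")
def train_pgs_stage(run: Run, biomarkers: list[str] | None = None) -> list[dict]:
    """Train the PGS ensemble per biomarker; report evaluation correlations."""
    cfg = run.config
    values = run.processed("mean")
    targets = biomarkers or cfg.predictors.biomarkers or list(values.columns)
    folds = run.splits()
    rows = []
    eval_ids = _eval_ids(run)
    geno = run.genotypes
    eval_geno = geno.subset_samples(eval_ids)
    for bm in targets:
        ens = train_pgs(geno, values[bm], folds, **run.solver_kwargs())
        run.save_ensemble("pgs", bm, ens)
        y_ev = values.loc[eval_ids, bm].to_numpy(float)
        corrs = [correlation(apply_to_genotypes(p, eval_geno), y_ev) for p in ens]
        stats = ensemble_stats(corrs, metric="pgs_correlation", cohort="siblings")
        for k, v in enumerate(corrs):
            rows.append({"metric": "pgs_correlation", "cohort": "siblings", "target": bm, "fold": k, "value": v})
        arch = snp_variance_accounted(ens[0], geno.snps)
        arch.table.to_csv(
            run.ensemble_dir("pgs", bm) / "architecture.tsv", sep="\t", index=False, float_format="%.10g"
        )
        logger.info("PGS %s: corr %.3f +- %.3f, support %d", bm, stats.mean, stats.sd, ens[0].n_nonzero)
    io.write_report(rows, run.dir / "report_pgs.tsv", config_hash=cfg.hash)
    return rows


def _sex_ids(run: Run, sex: str, ids: list[str]) -> list[str]:
    tab = run.phenotypes.samples.set_index("sample_id")["sex"]
    return [s for s in ids if tab[s] == sex]


@_stage("train-bmrs")
def train_bmrs_stage(run: Run, conditions: list[str] | None = None) -> list[dict]:
    """Sex-stratified BMRS ensembles per condition; report evaluation AUCs."""
    cfg = run.config
    features = run.processed("first")
    pheno = run.phenotypes
    targets = conditions or cfg.predictors.conditions or pheno.conditions
    strata = ["male", "female"] if cfg.predictors.sex_stratified_bmrs else ["all"]
    rows = []
    for cond in targets:
        status = pheno.status(cond)
        for sex in strata:
            ids = pheno.sample_ids if sex == "all" else _sex_ids(run, sex, pheno.sample_ids)
            folds = run.splits(ids)
            ens = train_bmrs(features.loc[ids], status, folds, **run.solver_kwargs())
            run.save_ensemble("bmrs", f"{cond}_{sex}", ens)
            ev = folds.evaluation
            y_ev = status.reindex(ev).to_numpy(float)
            aucs = [auc(apply_predictor(p, features.loc[ev]), y_ev) for p in ens]
            for k, v in enumerate(aucs):
                rows.append({"metric": "bmrs_auc", "cohort": f"siblings_{sex}", "target": cond, "fold": k, "value": v})
            relative_weight_table(ens).to_csv(
                run.ensemble_dir("bmrs", f"{cond}_{sex}") / "relative_weights.tsv",
                sep="\t", index=False, float_format="%.10g",
            )
    io.write_report(rows, run.dir / "report_bmrs.tsv", config_hash=cfg.hash)
    return rows


@_stage("train-prs")
def train_prs_stage(run: Run, conditions: list[str] | None = None) -> list[dict]:
    """Direct SNP-to-status ensembles (both sexes pooled)."""
    cfg = run.config
    pheno = run.phenotypes
    targets = conditions or cfg.predictors.conditions or pheno.conditions
    folds = run.splits()
    geno = run.genotypes
    rows = []
    eval_geno = geno.subset_samples(folds.evaluation)
    for cond in targets:
        status = pheno.status(cond)
        ens = train_prs(geno, status, folds, **run.solver_kwargs())
        run.save_ensemble("prs", cond, ens)
        y_ev = status.reindex(folds.evaluation).to_numpy(float)
        aucs = [auc(apply_to_genotypes(p, eval_geno), y_ev) for p in ens]
        for k, v in enumerate(aucs):
            rows.append({"metric": "prs_auc", "cohort": "siblings", "target": cond, "fold": k, "value": v})
    io.write_report(rows, run.dir / "report_prs.tsv", config_hash=cfg.hash)
    return rows


@_stage("concat-gbmrs")
def concat_gbmrs_stage(run: Run, conditions: list[str] | None = None) -> list[dict]:
    """Concatenate trained PGS through trained BMRS; evaluate on siblings."""
    cfg = run.config
    pheno = run.phenotypes
    features = run.processed("first")
    targets = conditions or cfg.predictors.conditions or pheno.conditions
    strata = ["male", "female"] if cfg.predictors.sex_stratified_bmrs else ["all"]
    pgs = {}
    for bm in features.columns:
        try:
            pgs[bm] = run.load_ensemble("pgs", bm)
        except UsageError:
            logger.warning("no PGS ensemble for %s; it will contribute zero to gBMRS", bm)
    geno = run.genotypes
    train_geno = geno.subset_samples(run.training_ids)
    rows = []
    for cond in targets:
        status = pheno.status(cond)
        for sex in strata:
            bmrs = run.load_ensemble("bmrs", f"{cond}_{sex}")
            ev = _eval_ids(run) if sex == "all" else _sex_ids(run, sex, _eval_ids(run))
            eval_geno = geno.subset_samples(ev)
            scores = concatenate_gbmrs(pgs, bmrs, eval_geno, train_geno)
            y_ev = status.reindex(ev).to_numpy(float)
            aucs = [auc(s, y_ev) for s in scores]
            for k, v in enumerate(aucs):
                rows.append({"metric": "gbmrs_auc", "cohort": f"siblings_{sex}", "target": cond, "fold": k, "value": v})
    io.write_report(rows, run.dir / "report_gbmrs.tsv", config_hash=cfg.hash)
    return rows


@_stage("evaluate")
def evaluate_stage(run: Run) -> list[dict]:
    """Sibling tests and odds-ratio curves for the trained predictors."""
    cfg = run.config
    pheno = run.phenotypes
    values = run.processed("mean")
    features = run.processed("first")
    pairs = pheno.sibling_pairs()
    eval_ids = _eval_ids(run)
    geno = run.genotypes
    eval_geno = geno.subset_samples(eval_ids)
    rows = []

    pgs_names = sorted(d.name.removeprefix("pgs_") for d in (run.dir / "weights").glob("pgs_*"))
    for bm in pgs_names:
        ens = run.load_ensemble("pgs", bm)
        pred = ens[0]
        scores = dict(zip(eval_ids, apply_to_genotypes(pred, eval_geno)))
        phen = values.loc[eval_ids, bm].to_dict()
        tab = sibling_delta_corr(scores, phen, pairs, thresholds=tuple(cfg.evaluation.sibling_thresholds), seed=cfg.seed)
        for _, r in tab.iterrows():
            rows.append({"metric": "sibling_delta_corr", "cohort": r["group"], "target": bm, "fold": 0, "value": r["correlation"], "n_pairs": r["n_pairs"]})

    bmrs_names = sorted(d.name.removeprefix("bmrs_") for d in (run.dir / "weights").glob("bmrs_*"))
    sex_of = pheno.samples.set_index("sample_id")["sex"]
    conds = sorted({n.rsplit("_", 1)[0] for n in bmrs_names})
    for cond in conds:
        status = pheno.status(cond)
        # score each sibling with the predictor of their own sex (fold 0)
        scores = {}
        ensemble_scores = []
        for sex in ("male", "female", "all"):
            name = f"{cond}_{sex}"
            if name not in bmrs_names:
                continue
            ens = run.load_ensemble("bmrs", name)
            ids = eval_ids if sex == "all" else [s for s in eval_ids if sex_of[s] == sex]
            if not ids:
                continue
            member_scores = [apply_predictor(p, features.loc[ids]) for p in ens]
            scores.update(dict(zip(ids, member_scores[0])))
            y = status.reindex(ids).to_numpy(float)
            if len(np.unique(y)) == 2:
                oc = or_curve(member_scores, y, percentiles=tuple(cfg.evaluation.percentiles))
                oc.insert(0, "sex", sex)
                oc.to_csv(run.dir / f"or_curve_{cond}_{sex}.tsv", sep="\t", index=False, float_format="%.10g")
        stat_map = {s: int(status[s]) for s in scores}
        try:
            frac = sibling_call_fraction(scores, stat_map, [p for p in pairs if p[0] in scores and p[1] in scores], seed=cfg.seed)
            for _, r in frac.iterrows():
                rows.append({"metric": "sibling_call_fraction", "cohort": r["group"], "target": cond, "fold": 0, "value": r["fraction_correct"], "n_pairs": r["n_pairs"]})
        except Exception as exc:  # no discordant pairs in tiny demos
            logger.warning("sibling call fraction skipped for %s: %s", cond, exc)
    io.write_report(rows, run.dir / "report_evaluate.tsv", config_hash=cfg.hash)
    return rows


@_stage("calibrate")
def calibrate_stage(run: Run, condition: str | None = None) -> pd.DataFrame:
    """Dense risk score -> absolute-risk map -> calibration curve."""
    cfg = run.config
    pheno = run.phenotypes
    features = run.processed("first")
    conds = cfg.predictors.conditions or pheno.conditions
    cond = condition or conds[0]
    status = pheno.status(cond)
    train_ids = run.training_ids
    eval_ids = _eval_ids(run)
    fit = ols_fit(
        features.loc[train_ids].to_numpy(float),
        status.reindex(train_ids).to_numpy(float),
        feature_ids=list(features.columns),
    )
    cal = fit_calibration(
        fit.predict(features.loc[train_ids].to_numpy(float)),
        status.reindex(train_ids).to_numpy(float),
        n_bins=cfg.calibration.n_bins,
        window=cfg.calibration.window,
    )
    (run.dir / f"calibration_{cond}.json").write_text(cal.to_json())
    risks = apply_calibration(cal, fit.predict(features.loc[eval_ids].to_numpy(float)))
    curve = calibration_curve(
        risks,
        status.reindex(eval_ids).to_numpy(float),
        n_bins=cfg.calibration.curve_bins,
        n_boot=cfg.evaluation.n_boot,
        seed=cfg.seed,
    )
    curve.to_csv(run.dir / f"calibration_curve_{cond}.tsv", sep="\t", index=False, float_format="%.10g")
    return curve


@_stage("report")
def report_stage(run: Run) -> pd.DataFrame:
    """Collect every per-fold metric into one summary (mean +- SD)."""
    frames = []
    for f in sorted(run.dir.glob("report_*.tsv")):
        frames.append(io.read_report(f))
    if not frames:
        raise UsageError("no stage reports found; run the pipeline first")
    tab = pd.concat(frames, ignore_index=True)
    summary = (
        tab.groupby(["metric", "cohort", "target"], dropna=False)["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    io.write_report(summary.to_dict("records"), run.dir / "summary.tsv", config_hash=run.config.hash)
    return summary
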