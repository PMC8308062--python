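"""Delimited-text formats for genotypes, phenotypes, weights and reports.

Genotypes travel as an additive-coding text matrix (header: ``sample_id``
then one ``<snp_id>_<effect_allele>`` column per SNP; dosages 0/1/2, NA for
a missing call) with a SNP metadata sidecar TSV
(snp_id, chrom, pos, effect_allele, maf). Phenotypes are one wide TSV with
covariate/status columns and ``<biomarker>_v<k>`` repeat-measurement
columns, empty fields meaning "no measurement". All tables are
tab-delimited UTF-8 with '.' decimals; every written file starts with a
``# config_hash=`` comment when a hash is supplied.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SNP_META_COLUMNS, GenotypeMatrix, PhenotypeTable
from .errors import ParseError
from .sparse_model import SparseLinearPredictor

MAX_REPEATS = 3
_RESERVED = ("sample_id", "sex", "birth_year", "sibling_pair")


def _header_comment(config_hash: str | None) -> str:
    return f"# config_hash={config_hash}\n" if config_hash else ""


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path, config_hash: str | None = None) -> None:
    path = Path(path)
    cols = [
        f"{sid}_{ea}"
        for sid, ea in zip(genotypes.snps["snp_id"], genotypes.snps["effect_allele"])
    ]
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write("\t".join(["sample_id", *cols]) + "\n")
        for sid, row in zip(genotypes.sample_ids, genotypes.dosages):
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write("\t".join([sid, *vals]) + "\n")
    sidecar = path.with_suffix(path.suffix + ".snps.tsv")
    with open(sidecar, "w") as fh:
        fh.write(_header_comment(config_hash))
        genotypes.snps[SNP_META_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read an additive-coded genotype matrix plus its SNP sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".snps.tsv")
    if not sidecar.exists():
        raise ParseError(f"SNP metadata sidecar not found: {sidecar}")
    snps = pd.read_csv(sidecar, sep="\t", comment="#")
    header = None
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            ids.append(parts[0])
            vals = np.empty(len(parts) - 1)
            for j, tok in enumerate(parts[1:]):
                if tok == "NA":
                    vals[j] = np.nan
                elif tok in ("0", "1", "2"):
                    vals[j] = float(tok)
                else:
                    raise ParseError(f"{path}:{lineno}: invalid dosage {tok!r}")
            rows.append(vals)
    if header is None:
        raise ParseError(f"{path}: empty genotype file")
    if len(header) - 1 != len(snps):
        raise ParseError(f"{path}: {len(header) - 1} dosage columns but {len(snps)} sidecar SNPs")
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return GenotypeMatrix(np.vstack(rows), snps, ids)


# ---------------------------------------------------------------------------
# phenotypes


def write_phenotypes(pheno: PhenotypeTable, path: str | Path, config_hash: str | None = None) -> None:
    wide = pheno.samples.set_index("sample_id").copy()
    meas = pheno.measurements
    for (bm, visit), grp in meas.groupby(["biomarker", "visit"], sort=True):
        wide[f"{bm}_v{visit}"] = grp.set_index("sample_id")["value"]
    wide = wide.reset_index()
    # deterministic column order: covariates, statuses, PCs, then measurements
    fixed = [c for c in _RESERVED if c in wide.columns]
    status = sorted(c for c in wide.columns if c.startswith("status_"))
    pcs = sorted((c for c in wide.columns if c.startswith("PC")), key=lambda c: int(c[2:]))
    meas_cols = sorted(c for c in wide.columns if "_v" in c and c not in fixed + status + pcs)
    other = sorted(c for c in wide.columns if c not in fixed + status + pcs + meas_cols)
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        wide[fixed + status + pcs + other + meas_cols].to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    wide = _read_table(path)
    if "sample_id" not in wide.columns:
        raise ParseError(f"{path}: missing sample_id column")
    meas_cols = [c for c in wide.columns if "_v" in c and c.rsplit("_v", 1)[1].isdigit()]
    rows = {"sample_id": [], "biomarker": [], "visit": [], "value": []}
    for c in meas_cols:
        bm, visit = c.rsplit("_v", 1)
        sub = wide[["sample_id", c]].dropna()
        rows["sample_id"] += list(sub["sample_id"])
        rows["biomarker"] += [bm] * len(sub)
        rows["visit"] += [int(visit)] * len(sub)
        rows["value"] += list(sub[c].astype(float))
    samples = wide.drop(columns=meas_cols)
    for c in samples.columns:
        if c.startswith("status_"):
            bad = set(samples[c].dropna().unique()) - {0, 1}
            if bad:
                raise ParseError(f"{path}: status column {c} has values outside {{0,1}}: {bad}")
    if "sibling_pair" in samples.columns:
        samples["sibling_pair"] = samples["sibling_pair"].fillna("").astype(str)
    meas = pd.DataFrame(rows).sort_values(["biomarker", "visit", "sample_id"], ignore_index=True)
    return PhenotypeTable(samples, meas)


# ---------------------------------------------------------------------------
# predictor weights


def write_weights(pred: SparseLinearPredictor, path: str | Path, config_hash: str | None = None) -> None:
    """Weight table (support features only) plus a JSON metadata sidecar."""
    path = Path(path)
    support = pred.support
    tab = pd.DataFrame(
        {
            "feature_id": [pred.feature_ids[j] for j in support],
            "beta_standardized": pred.weights[support],
            "beta_raw": pred.raw_weights[support],
            "feature_mean": pred.feature_means[support],
            "feature_sd": pred.feature_sds[support],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        tab.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    meta = {
        "namespace": pred.namespace,
        "intercept": pred.intercept,
        "lambda": pred.lam,
        "fold": pred.fold,
        "n_features_total": len(pred.feature_ids),
        "metadata": {k: v for k, v in pred.metadata.items() if isinstance(v, (int, float, str))},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_weights(path: str | Path) -> SparseLinearPredictor:
    """Rebuild a predictor from its weight table; zero-weight features are
    not round-tripped (scores are unchanged)."""
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", comment="#")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SparseLinearPredictor(
        namespace=meta["namespace"],
        feature_ids=list(tab["feature_id"].astype(str)),
        weights=tab["beta_standardized"].to_numpy(float),
        intercept=float(meta["intercept"]),
        lam=float(meta["lambda"]),
        feature_means=tab["feature_mean"].to_numpy(float),
        feature_sds=tab["feature_sd"].to_numpy(float),
        fold=int(meta["fold"]),
        metadata=meta.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# tidy reports


def write_report(rows: list[dict], path: str | Path, config_hash: str | None = None) -> None:
    """Tidy metric table: one row per (metric, cohort, fold, value, ...)."""
    tab = pd.DataFrame(rows)
    lead = [c for c in ("metric", "cohort", "fold", "value") if c in tab.columns]
    tab = tab[lead + [c for c in tab.columns if c not in lead]]
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        tab.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
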