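"""Core in-memory containers shared across the pipeline.

A cohort is represented by a :class:`GenotypeMatrix` (samples x SNPs additive
dosages plus per-SNP metadata) and a :class:`PhenotypeTable` (per-sample
covariates, disease statuses and a long table of repeated biomarker
measurements). Simulated cohorts additionally carry truth tables (latent
genetic values, liabilities, causal effects) used by oracle evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: columns of the SNP metadata sidecar, in canonical order
SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "maf"]


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes for a cohort.

    Attributes
    ----------
    dosages:
        float array of shape (n_samples, n_snps) with values in {0, 1, 2}
        or NaN for a missing call. Missingness is carried by NaN plus the
        ``missing_mask`` property, never by a magic dosage value.
    snps:
        DataFrame with columns ``snp_id, chrom, pos, effect_allele, maf``;
        ``maf`` is the realized alternate-allele frequency in this cohort.
    sample_ids:
        unique string identifiers, aligned with dosage rows.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snps) != p:
            raise ValueError("SNP metadata rows do not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP metadata missing columns: {missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a call is missing."""
        return np.isnan(self.dosages)

    def realized_mafs(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(self.dosages[rows], self.snps.copy(), list(ids))

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.dosages[:, keep],
            self.snps.iloc[keep].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class PhenotypeTable:
    """Per-sample covariates, statuses and repeated biomarker measurements.

    ``samples`` has one row per sample: ``sample_id``, ``sex`` ("male" /
    "female"), ``birth_year``, optional ``sibling_pair`` (pair label, empty
    for singletons), optional ``status_<condition>`` binary columns, optional
    ``PC1..PCk`` columns and an optional external risk-score column.

    ``measurements`` is long format: ``sample_id, biomarker, visit, value``
    with ``visit`` counting repeats from 1.
    """

    samples: pd.DataFrame
    measurements: pd.DataFrame
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "sample_id" not in self.samples.columns:
            raise ValueError("samples table needs a sample_id column")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        need = {"sample_id", "biomarker", "visit", "value"}
        if not need.issubset(self.measurements.columns):
            raise ValueError(f"measurements table needs columns {sorted(need)}")
        bad = set(self.samples["sex"].dropna()) - {"male", "female"}
        if bad:
            raise ValueError(f"sex values outside {{male, female}}: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def biomarkers(self) -> list[str]:
        return sorted(self.measurements["biomarker"].unique())

    @property
    def conditions(self) -> list[str]:
        return [c.removeprefix("status_") for c in self.samples.columns if c.startswith("status_")]

    def status(self, condition: str) -> pd.Series:
        col = f"status_{condition}"
        if col not in self.samples.columns:
            raise KeyError(f"no status column for condition {condition!r}")
        return self.samples.set_index("sample_id")[col]

    def sibling_pairs(self) -> list[tuple[str, str]]:
        """(member_a, member_b) per pair, in a fixed member order."""
        if "sibling_pair" not in self.samples.columns:
            return []
        tab = self.samples[["sample_id", "sibling_pair"]].dropna()
        tab = tab[tab["sibling_pair"] != ""]
        pairs = []
        for _, grp in tab.groupby("sibling_pair", sort=True):
            ids = sorted(grp["sample_id"])
            if len(ids) == 2:
                pairs.append((ids[0], ids[1]))
        return pairs

    def subset(self, ids: list[str]) -> "PhenotypeTable":
        ids = list(ids)
        samp = self.samples[self.samples["sample_id"].isin(ids)]
        samp = samp.set_index("sample_id").loc[ids].reset_index()
        meas = self.measurements[self.measurements["sample_id"].isin(ids)]
        truth = {
            k: v[v["sample_id"].isin(ids)].reset_index(drop=True) if "sample_id" in v.columns else v
            for k, v in self.truth.items()
        }
        return PhenotypeTable(samp.reset_index(drop=True), meas.reset_index(drop=True), truth)

    def copy(self) -> "PhenotypeTable":
        return replace(
            self,
            samples=self.samples.copy(),
            measurements=self.measurements.copy(),
            truth={k: v.copy() for k, v in self.truth.items()},
        )
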