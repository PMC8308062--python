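"""Synthetic cohort generator.

Produces biobank-like cohorts with the statistical structure the downstream
analysis assumes: Hardy-Weinberg, linkage-equilibrium SNPs with a configurable
MAF spectrum; Mendelian sibling pairs; sparse additive genetic architectures
per biomarker; sex offsets, linear age trends, shared sibling environment and
repeat-measurement noise; liability-threshold disease statuses driven by a
weighted subset of biomarkers plus a direct genetic term; and Balding-Nichols
allele-frequency divergence for ancestry-shifted evaluation cohorts.

Everything is deterministic under the master seed: each component draws from a
named child stream, so adding a component never perturbs the others. True
latent quantities (genetic values, liabilities, causal effects) are retained
in ``PhenotypeTable.truth`` for oracle tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeTable
from .errors import ConfigurationError, SimulationError

#: reference calendar year used to convert age to birth year
REFERENCE_YEAR = 2018
AGE_MIN, AGE_MAX = 40, 70


@dataclass
class DiseaseSpec:
    """Liability-threshold disease definition.

    liability = sum_b weight_b * latent biomarker_b
              + direct_genetic_weight * direct genetic score
              + Normal(0, noise_var)

    Status is 1 for the top round(n*K) liabilities, so the realized
    prevalence equals the target K up to rounding.
    """

    name: str
    biomarker_weights: dict[str, float]
    direct_genetic_weight: float = 0.0
    noise_var: float = 1.0
    prevalence: float = 0.1

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError(f"prevalence of {self.name!r} must be in (0, 1)")
        if self.noise_var < 0:
            raise ConfigurationError(f"noise_var of {self.name!r} must be >= 0")


@dataclass
class SimulationConfig:
    n_samples: int = 2000
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_per_biomarker: int = 20
    heritability_h2: float = 0.5
    n_biomarkers: int = 5
    sex_offset: float = 0.3
    age_slope: float = 0.01
    repeat_noise_sd: float = 0.3
    n_sibling_pairs: int = 100
    shared_env_var: float = 0.1
    disease_specs: list[DiseaseSpec] = field(default_factory=list)
    fst_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_snps <= 0 or self.n_biomarkers <= 0:
            raise ConfigurationError("n_samples, n_snps and n_biomarkers must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.heritability_h2 <= 1.0:
            raise ConfigurationError("heritability_h2 must be in [0, 1]")
        if self.shared_env_var < 0 or self.heritability_h2 + self.shared_env_var > 1.0:
            raise ConfigurationError("heritability_h2 + shared_env_var must be <= 1")
        if self.n_causal_per_biomarker < 0 or self.n_causal_per_biomarker > self.n_snps:
            raise ConfigurationError("n_causal_per_biomarker must be in [0, n_snps]")
        if self.n_sibling_pairs < 0:
            raise ConfigurationError("n_sibling_pairs must be >= 0")
        if not 0.0 <= self.fst_divergence < 1.0:
            raise ConfigurationError("fst_divergence must be in [0, 1)")
        for spec in self.disease_specs:
            spec.validate()

    def rng(self, component: str) -> np.random.Generator:
        """Named child stream of the master seed."""
        key = zlib.crc32(component.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    @property
    def biomarker_names(self) -> list[str]:
        return [f"bm{i + 1:02d}" for i in range(self.n_biomarkers)]


# ---------------------------------------------------------------------------
# genotype layer


def _snp_metadata(config: SimulationConfig, mafs: np.ndarray) -> pd.DataFrame:
    p = config.n_snps
    chroms = (np.arange(p) % 22) + 1  # round-robin over autosomes
    pos = np.zeros(p, dtype=int)
    for c in range(1, 23):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = 10_000 * (np.arange(len(idx)) + 1)  # increasing within chromosome
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:05d}" for i in range(p)],
            "chrom": chroms,
            "pos": pos,
            "effect_allele": np.where(np.arange(p) % 2 == 0, "A", "G"),
            "maf": mafs,
        }
    )


def base_allele_frequencies(config: SimulationConfig) -> np.ndarray:
    """Per-SNP population allele frequencies, drawn once per master seed."""
    rng = config.rng("mafs")
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int | None = None,
    prefix: str = "ind",
    stream: str = "genotypes",
    freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw unrelated Hardy-Weinberg genotypes at the base allele frequencies.

    Each dosage is the sum of two Bernoulli(f_i) allele draws, so a SNP with
    frequency f has mean 2f and variance 2f(1-f).
    """
    n = config.n_samples if n_samples is None else n_samples
    if n <= 0:
        raise ConfigurationError("number of samples must be positive")
    f = base_allele_frequencies(config) if freqs is None else np.asarray(freqs, float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ConfigurationError("allele frequencies must lie strictly in (0, 1)")
    rng = config.rng(stream)
    dosages = rng.binomial(2, f[None, :], size=(n, config.n_snps)).astype(float)
    meta = _snp_metadata(config, dosages.mean(axis=0) / 2.0)
    ids = [f"{prefix}{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, meta, ids)


def simulate_sibling_pairs(
    config: SimulationConfig, freqs: np.ndarray | None = None
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Draw sibling pairs by Mendelian transmission from simulated parents.

    For each pair, two parental genotypes are drawn at the base frequencies;
    each sibling independently inherits one allele per parent per SNP. Across
    many SNPs this yields the expected genotypic correlation of 1/2.
    """
    k = config.n_sibling_pairs
    if k < 1:
        raise ConfigurationError("n_sibling_pairs must be >= 1")
    f = base_allele_frequencies(config) if freqs is None else np.asarray(freqs, float)
    rng = config.rng("siblings")
    p = config.n_snps
    # parental haplotypes: (pairs, parent, allele_copy, snp)
    haplo = rng.random((k, 2, 2, p)) < f[None, None, None, :]
    dosages = np.empty((2 * k, p))
    for s in range(2):  # two siblings per pair, independent transmissions
        pick = rng.integers(0, 2, size=(k, 2, p))
        transmitted = np.take_along_axis(haplo, pick[:, :, None, :], axis=2)[:, :, 0, :]
        dosages[s::2] = transmitted.sum(axis=1).astype(float)
    meta = _snp_metadata(config, dosages.mean(axis=0) / 2.0)
    # rows 2j, 2j+1 hold pair j (written by the strided assignment above)
    ids = []
    pairs = []
    for j in range(k):
        a, b = f"sib{j + 1:05d}a", f"sib{j + 1:05d}b"
        ids += [a, b]
        pairs.append((a, b))
    return GenotypeMatrix(dosages, meta, ids), pairs


def simulate_diverged_cohort(
    config: SimulationConfig,
    base_freqs: np.ndarray,
    fst: float | None = None,
    n_samples: int | None = None,
    prefix: str = "div",
) -> GenotypeMatrix:
    """Cohort at Balding-Nichols diverged allele frequencies.

    Diverged frequencies are Beta with mean f and variance Fst*f*(1-f); the
    causal effects of the base population are unchanged, so predictor
    performance in the diverged cohort probes ancestry transferability.
    """
    fst = config.fst_divergence if fst is None else fst
    if not 0.0 <= fst < 1.0:
        raise ConfigurationError("fst must be in [0, 1)")
    f = np.asarray(base_freqs, float)
    if fst == 0.0:
        freqs = f.copy()
    else:
        rng = config.rng(f"diverged_freqs_{fst}")
        scale = (1.0 - fst) / fst
        freqs = rng.beta(scale * f, scale * (1.0 - f))
        freqs = np.clip(freqs, 1e-6, 1.0 - 1e-6)
    return simulate_genotypes(
        config, n_samples=n_samples, prefix=prefix, stream=f"diverged_{fst}", freqs=freqs
    )


# ---------------------------------------------------------------------------
# phenotype layer


@dataclass
class Architecture:
    """Causal SNP sets and effect sizes per biomarker, fixed per master seed."""

    causal_idx: dict[str, np.ndarray]
    effects: dict[str, np.ndarray]  # per-dosage effects, h2-scaled

    def effects_table(self, snp_ids: list[str]) -> pd.DataFrame:
        rows = []
        for bm, idx in self.causal_idx.items():
            for j, b in zip(idx, self.effects[bm]):
                rows.append({"biomarker": bm, "snp_id": snp_ids[j], "snp_index": j, "beta": b})
        return pd.DataFrame(rows, columns=["biomarker", "snp_id", "snp_index", "beta"])


def draw_architecture(config: SimulationConfig, freqs: np.ndarray) -> Architecture:
    """Draw causal SNPs and effects; scale so the genetic variance is h2.

    Effects are Gaussian and the scale is set from the theoretical dosage
    variance 2f(1-f) at the base frequencies, so the same effects transfer to
    sibling and diverged cohorts while realized variance matches h2 up to
    Monte-Carlo error.
    """
    causal_idx: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    s = config.n_causal_per_biomarker
    for bm in config.biomarker_names:
        rng = config.rng(f"architecture_{bm}")
        idx = np.sort(rng.choice(config.n_snps, size=s, replace=False))
        beta = rng.standard_normal(s)
        if config.heritability_h2 > 0:
            var_g = float(np.sum(beta**2 * 2.0 * freqs[idx] * (1.0 - freqs[idx])))
            if var_g <= 0:
                raise SimulationError(f"zero causal variance for {bm}: cannot scale to h2")
            beta = beta * np.sqrt(config.heritability_h2 / var_g)
        else:
            beta = np.zeros_like(beta)
        causal_idx[bm] = idx
        effects[bm] = beta
    return Architecture(causal_idx, effects)


def single_locus_architecture(config: SimulationConfig, freqs: np.ndarray) -> Architecture:
    """One causal SNP per biomarker — an LpA-like, maximally localized trait."""
    causal_idx: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    for i, bm in enumerate(config.biomarker_names):
        rng = config.rng(f"architecture_{bm}")
        j = int(rng.integers(0, config.n_snps))
        f = freqs[j]
        beta = np.sqrt(config.heritability_h2 / (2.0 * f * (1.0 - f)))
        causal_idx[bm] = np.array([j])
        effects[bm] = np.array([beta])
    return Architecture(causal_idx, effects)


def simulate_biomarkers(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    pairs: list[tuple[str, str]] | None = None,
    architecture: Architecture | None = None,
) -> PhenotypeTable:
    """Generate sex, birth year and repeated biomarker measurements.

    A sample's latent biomarker value (standardized scale) is
    genetic + shared environment + person noise, with component variances
    h2, shared_env_var and 1 - h2 - shared_env_var. On top of the latent
    value sit the sex offset (added to males), a linear age trend, and per
    measurement an independent repeat-noise draw. Each sample receives one
    to three measurements per biomarker.
    """
    if architecture is None:
        architecture = draw_architecture(config, base_allele_frequencies(config))
    pairs = pairs or []
    ids = genotypes.sample_ids
    n = len(ids)
    rng = config.rng("phenotypes")

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = rng.integers(AGE_MIN, AGE_MAX + 1, size=n)
    birth_year = REFERENCE_YEAR - age
    mean_age = (AGE_MIN + AGE_MAX) / 2.0

    pair_label = {s: f"pair{j + 1:05d}" for j, (a, b) in enumerate(pairs) for s in (a, b)}
    pos = {s: i for i, s in enumerate(ids)}

    resid_var = 1.0 - config.heritability_h2 - config.shared_env_var
    genetic = {}
    latent = {}
    meas_rows: dict[str, list] = {"sample_id": [], "biomarker": [], "visit": [], "value": []}
    n_repeats = rng.integers(1, 4, size=n)

    for bm in config.biomarker_names:
        idx = architecture.causal_idx[bm]
        beta = architecture.effects[bm]
        g = genotypes.dosages[:, idx] @ beta
        g = g - g.mean()
        if config.heritability_h2 > 0 and np.allclose(g, 0.0):
            raise SimulationError(f"zero causal variance realized for {bm}")
        env = rng.normal(0.0, np.sqrt(config.shared_env_var), size=n) if config.shared_env_var > 0 else np.zeros(n)
        # sibling pair members share one environment draw
        for a, b in pairs:
            if a in pos and b in pos:
                env[pos[b]] = env[pos[a]]
        noise = rng.normal(0.0, np.sqrt(resid_var), size=n) if resid_var > 0 else np.zeros(n)
        lat = g + env + noise
        observed_base = (
            lat
            + np.where(sex == "male", config.sex_offset, 0.0)
            + config.age_slope * (age - mean_age)
        )
        genetic[bm] = g
        latent[bm] = lat
        for i, sid in enumerate(ids):
            for v in range(int(n_repeats[i])):
                val = observed_base[i] + rng.normal(0.0, config.repeat_noise_sd)
                meas_rows["sample_id"].append(sid)
                meas_rows["biomarker"].append(bm)
                meas_rows["visit"].append(v + 1)
                meas_rows["value"].append(val)

    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "sex": sex,
            "birth_year": birth_year,
            "sibling_pair": [pair_label.get(s, "") for s in ids],
        }
    )
    truth = {
        "genetic": pd.DataFrame({"sample_id": ids, **genetic}),
        "latent": pd.DataFrame({"sample_id": ids, **latent}),
        "effects": architecture.effects_table(genotypes.snp_ids),
    }
    return PhenotypeTable(samples, pd.DataFrame(meas_rows), truth)


def simulate_disease(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
) -> PhenotypeTable:
    """Assign liability-threshold statuses for every configured disease.

    Liability combines the latent (repeat-noise-free) biomarker values with
    the spec's weights, an optional direct genetic score from its own causal
    SNPs, and Gaussian noise. The threshold is the empirical (1-K) quantile,
    so in-sample prevalence equals K up to rounding of n*K.
    """
    out = phenotypes.copy()
    n = len(out.samples)
    if n < 10:
        raise SimulationError("too few samples to define a prevalence quantile")
    latent = out.truth["latent"].set_index("sample_id").loc[out.sample_ids]
    liab_table = {"sample_id": out.sample_ids}
    freqs = base_allele_frequencies(config)
    for spec in config.disease_specs:
        unknown = set(spec.biomarker_weights) - set(latent.columns)
        if unknown:
            raise ConfigurationError(f"disease {spec.name!r} references unknown biomarkers {sorted(unknown)}")
        rng = config.rng(f"disease_{spec.name}")
        liability = np.zeros(n)
        for bm, w in spec.biomarker_weights.items():
            liability += w * latent[bm].to_numpy()
        if spec.direct_genetic_weight != 0.0:
            s = max(config.n_causal_per_biomarker, 1)
            idx = np.sort(rng.choice(config.n_snps, size=min(s, config.n_snps), replace=False))
            beta = rng.standard_normal(len(idx))
            var_g = float(np.sum(beta**2 * 2.0 * freqs[idx] * (1.0 - freqs[idx])))
            beta /= np.sqrt(var_g)
            direct = genotypes.dosages[:, idx] @ beta
            liability += spec.direct_genetic_weight * (direct - direct.mean())
        if spec.noise_var > 0:
            liability += rng.normal(0.0, np.sqrt(spec.noise_var), size=n)
        n_cases = int(round(n * spec.prevalence))
        if n_cases < 1 or n_cases >= n:
            raise SimulationError(f"prevalence {spec.prevalence} yields no cases or no controls at n={n}")
        order = np.argsort(liability)
        status = np.zeros(n, dtype=int)
        status[order[-n_cases:]] = 1
        out.samples[f"status_{spec.name}"] = status
        liab_table[spec.name] = liability
    out.truth["liability"] = pd.DataFrame(liab_table)
    return out


def simulate_cohort(
    config: SimulationConfig,
    architecture: Architecture | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Full cohort: unrelated samples plus sibling pairs, biomarkers, statuses.

    The returned genotype matrix stacks ``n_samples`` unrelated individuals
    and ``2 * n_sibling_pairs`` siblings; the phenotype table carries the
    sibling pairing and one status column per configured disease.
    """
    freqs = base_allele_frequencies(config)
    geno = simulate_genotypes(config, freqs=freqs)
    pairs: list[tuple[str, str]] = []
    if config.n_sibling_pairs > 0:
        sib_geno, pairs = simulate_sibling_pairs(config, freqs=freqs)
        dosages = np.vstack([geno.dosages, sib_geno.dosages])
        ids = geno.sample_ids + sib_geno.sample_ids
        meta = _snp_metadata(config, dosages.mean(axis=0) / 2.0)
        geno = GenotypeMatrix(dosages, meta, ids)
    pheno = simulate_biomarkers(geno, config, pairs=pairs, architecture=architecture)
    if config.disease_specs:
        pheno = simulate_disease(pheno, geno, config)
    return geno, pheno
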