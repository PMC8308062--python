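# Methods

This note records the models behind `gbmrs`, the defaults and why they were
chosen, and what the synthetic cohorts do and do not establish about real
data.

## Simulation model

**Genotypes.** SNPs are in Hardy–Weinberg and linkage equilibrium: dosage
at SNP *i* is Binomial(2, fᵢ) with fᵢ drawn once per master seed, uniform
over `maf_range` (default 0.05–0.5). SNPs are assigned round-robin to
chromosomes 1–22 with increasing positions. No LD blocks are simulated:
none of the pipeline stages require LD to be exercised, and LD-aware
methods are out of scope; this is the main structural simplification and
the first extension point. Sibling pairs are generated by drawing two
parents at the base frequencies and transmitting one allele per parent per
SNP independently to each sibling, which yields the expected genotypic
correlation of ½ (on population-standardized dosages). Ancestry-diverged
cohorts draw per-SNP frequencies from the Balding–Nichols Beta with mean f
and variance Fst·f(1−f), keeping causal effects fixed.

**Biomarkers.** Each biomarker has `n_causal_per_biomarker` causal SNPs
with Gaussian effects, scaled so the genetic variance equals h² using the
theoretical dosage variance 2f(1−f) at the base frequencies. Scaling from
theoretical rather than realized variance keeps the causal effects
identical across the training, sibling and diverged cohorts, at the cost
of h² holding only up to Monte-Carlo error (the tests verify ~2% at
n ≥ 10⁴). On the standardized scale a sample's latent value is

    latent = genetic (h²) + shared environment (c²) + person noise (1−h²−c²),

where the shared-environment draw is identical for the two members of a
sibling pair. The observed value adds a sex offset (to males), a linear
trend in age (age uniform over 40–70, anchored to birth year at reference
year 2018 — a biobank-like window; the exact distribution is immaterial to
any tested contract), and per measurement an independent repeat-noise draw;
each sample gets 1–3 visits.

**Disease.** Liability = Σ_b w_b · latent_b + w_g · (direct genetic score)
+ Gaussian noise. "Latent" here means the repeat-noise-free standardized
biomarker value *including* its person noise and *excluding* sex/age fixed
effects: this is the quantity that preprocessing reconstructs from
measurements, so a biomarker-driven disease is in principle learnable from
preprocessed features, while sex/age effects — which the pipeline removes —
do not leak into the liability. Status is 1 for the top round(n·K)
liabilities, so in-sample prevalence equals the target K exactly up to
rounding. A consequence worth remembering when reading oracle comparisons:
the AUC of the true liability against its own thresholding is exactly 1,
so "oracle gap" numbers bundle everything the features cannot see (the
liability noise term, the direct genetic term, repeat noise).

**Seeding.** One master seed spawns named child streams
(`SeedSequence(seed, spawn_key=(crc32(name),))`), so adding a component
never perturbs the draws of existing ones, and identical config + seed
reproduces cohorts byte-identically.

## Preprocessing

Measurements are collapsed to one value per sample either by averaging
repeats (quantitative-trait features: the average is the stabler, more
heritable level) or by taking the first visit (disease features: one
clinical blood draw). Averaging precedes z-scoring. Values are then
z-scored per sex (population-SD convention; at biobank n the sample/
population distinction is irrelevant, and the convention is recorded in
the serialized parameters) and corrected by subtracting a line fitted to
per-birth-year mean values — every birth year contributes one point
regardless of its sample count. All parameters are fitted on training
samples only and applied frozen elsewhere; applying frozen parameters to
the training set reproduces the fit-time transform bit-identically.

Optional PC adjustment regresses each biomarker on the leading genotype
principal components (default 20, computed with scikit-learn on the
mean-imputed centered dosage matrix), takes residuals and re-z-scores
them. Genotype QC removes SNPs with MAF < 0.001 or more than 3%
missingness, samples with more than 3% missingness, and mean-imputes the
rest; missing calls are carried as NaN plus a mask, never as a sentinel
dosage.

## The sparse solver

The L1 objective `(1/2n)‖y − Xβ − b‖² + λ‖β‖₁` is minimized by cyclic
coordinate descent on column-standardized features with a centered
response; the single-coordinate update is the soft threshold
S(ρ, λ) = sign(ρ)·max(|ρ|−λ, 0). The λ grid has 100 points, geometric from
λ_max = max_j |x_jᵀy|/n down to 10⁻³ λ_max; at λ ≥ λ_max the zero solution
is returned exactly. Warm starts carry the solution down the grid; after
each full sweep the active set is iterated to convergence before the next
full sweep. Convergence is declared when a full sweep moves no coefficient
by more than 10⁻⁷; because that update-size rule can understate coefficient
error on ill-conditioned designs, every solution is then verified against
the KKT stationarity conditions (tolerance 10⁻⁸ on the residual
correlations) and re-polished at a tighter tolerance if needed. The test
suite checks the solver against an independent convex-programming oracle
(bound-constrained quasi-Newton on the split positive/negative
formulation, with an exact KKT-system polish) to 10⁻⁶ per coefficient.

Coordinate order is cyclic, not random, for determinism. The inner kernel
is JIT-compiled with numba. Binary case/control responses are fitted by
the same penalized least squares on 0/1 labels — a linear probability
model; λ is then selected by AUC. This mirrors the analysis design the
package implements; logistic LASSO is a non-goal.

**Splits.** All sibling-pair members form the evaluation set and never
enter training or validation. The remaining samples supply five disjoint
validation draws (default 1000 samples each); fold k trains on everything
except draw k, so the five retained predictors see slightly different
training sets and their spread (sample SD, n−1) is the reported
uncertainty. Quantitative-trait and case/control predictors both use this
machinery, differing only in validation size and metric defaults.

## Predictors

**gBMRS.** A trained BMRS is applied, as is, to PGS outputs: each
biomarker column is replaced by its PGS score, z-scored against the
frozen training-population PGS distribution, and the BMRS weights and
intercept are applied directly (no re-standardization, no retraining). In
the perfect-PGS limit — outputs equal to the true biomarker values, with
reference constants from the BMRS training set — the concatenated score is
an exact affine image of the BMRS score; the tests assert Spearman ρ = 1.
With five PGS members per biomarker and five BMRS members, all 5×5
combinations are computed and summarized as mean ± SD. Biomarkers without
a PGS contribute their training-mean (zero) and are logged. Score
combination is the sum of the two z-scored scores over the evaluated
cohort.

**Architecture.** Variance accounted for by SNP *i* is βᵢ²(1−fᵢ)fᵢ with βᵢ
the raw-scale (per-dosage) weight. The conventional additive-genotype
variance carries a factor 2; the unscaled form is the default here because
the factor cancels in the normalized per-chromosome shares that the
reports are built from, and a `factor_two` flag exposes the full variance.

**Quadratic probe.** Nonlinearity is probed by augmenting the feature set
with all squares and pairwise products of the top-k (default 7, hence 28
new columns) features by mean absolute weight, re-z-scoring the new
columns, retraining and comparing evaluation AUCs.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), computed from ranks. The
percentile odds-ratio curve puts everyone whose percentile rank is at or
above the cut (ties at the cut value included) in the high group and the
complement in the reference; empty cells get the Haldane–Anscombe +0.5
correction and a flag. The reported SEM combines the delta-method binomial
error of the log-OR with the spread over ensemble members. Note the curve
of a strongly informative score need not be monotone at low cuts — moving
the cut down strips cases out of the reference group too — so the
monotonicity property is asserted only in the ≥70th-percentile tail.

Sibling Δ-correlation compares corr(Δphen, ΔPGS) between sibling pairs and
an equal number of seeded random pairs, with differences taken in a fixed
member order, plus filtered variants requiring |Δphen| above 0.5/1.0/1.5
phenotype SDs. Why siblings score *lower* than random pairs here even
though their shared environment cancels in the difference: within-pair
differencing halves the genetic variance (sibling genotype correlation ½)
while person and visit noise keep their full variance, so the
noise-to-signal ratio of Δphen roughly doubles whenever the non-shared
noise exceeds the shared-environment variance. The ratio of sibling to
random correlation is √((h²+c²+σ²)/(h²+2σ²)), bounded below by 1/√2 — a
maximum drop of ~29%. The validation experiments use a modestly heritable,
labile biomarker (h² = 0.3, shared environment 0.2, day-to-day SD 0.7,
single-visit phenotype), giving a ~20% drop. The discordant-pair call
fraction counts one-case/one-control pairs where the case scores strictly
higher (ties ½) against a random case/control-pair baseline.

The PCA comparison reports the RMS difference, the mean percent difference
(m − m_PCA)/m_PCA, and the per-key relative differences between matched
metric sets trained with and without PC residualization.

## Calibration

Training risk scores are cut into equal-count bins (default 40; massive
ties merge bins, logged); per-bin prevalence is smoothed by a centered,
count-weighted rolling average (default window 5, truncated at the edges)
and linearly interpolated between within-bin mean-score knots, clamping
outside the range. Bin scheme, count and window are recorded in the
serialized map. No monotonicity is enforced by default — the smoothed
prevalences are reported as estimated — with an isotonic variant behind a
flag. Calibration curves bin held-out predicted risks, compare with
realized prevalence and attach 100-fold bootstrap 95% percentile intervals
(resampling individuals within bins, seeded); bins under 50 samples are
flagged. Because the intervals are honest 95% CIs, the fraction of bins
covering the truth fluctuates binomially around 0.95 on any single curve;
the coverage check therefore pools bins over ten replicate cohorts. The
external clinical risk estimator consumed by the combination analyses is a
pluggable column; a synthetic logistic stand-in ships for end-to-end tests
and implements no published clinical equation.

## Problem sizes in the validation battery

The validation experiments run at sizes chosen to make their Monte-Carlo
error small relative to the asserted margins while staying desk-scale:
solver oracles at p ≤ 12 over 200 instances; architecture recovery at
n = 4000, p = 2000, 20 causal SNPs, 10 seeds; the disease battery at
n = 20,000 with 30 biomarkers of which 5 drive a K = 0.1 liability disease
with a ~10% unexplainable-noise share (a "biomarker-driven" regime — with
larger liability noise the oracle gap measures the noise, not the
machinery); sibling experiments with 1500 pairs per seed over 10 seeds;
calibration at n = 50,000. The acceptance script reuses these designs with
fewer replicates.

## Known limitations

No LD, imputation error, X chromosome, admixture, batch effects,
medication adjustment, or time-to-event structure; disease status is
lifetime-style, not prospective. Passing tests establish that the
machinery is correct under the generator's assumptions (independent SNPs,
additive effects, Gaussian noise, exchangeable samples); they do not
establish real-data performance, where LD, stratification, genetic
nurture, assay drift and selection effects all bite. The PCA-neutrality
result in particular is a property of structure-free simulation, not
evidence that PC adjustment is unnecessary on real cohorts.
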