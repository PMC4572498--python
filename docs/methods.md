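# Methods

This note documents the models and procedures implemented in `methscore`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Synthetic cohorts

The generator (`simulate.py`) emulates the structure of an adult
whole-blood methylation cohort, not any particular dataset.

**Probes.** CpG probes live on one synthetic chromosome in blocks of
`probes_per_block` (default 5) whose positions span at most `block_size_bp`
(default 500 bp); block starts are spaced ten windows apart so distinct
blocks never fall in one pruning window. Within a block, latent probe
values share a single Gaussian factor, giving exact equicorrelation
`within_block_r` (default 0.5) on the latent (logit) scale; richer
distance-decay LD is deliberately out of scope. Each probe gets a baseline
level μⱼ ~ N(0, 1.5²), and betas are the inverse-logit of μⱼ + latent (+
batch shifts), so all betas lie strictly in (0, 1) and the logit transform
recovers the latent scale exactly.

**Genotypes.** Per-SNP MAF ~ Uniform(0.05, 0.5); founders are drawn in
Hardy–Weinberg proportions, `binomial(2, p)`. Family structure: `trios` and
`sib_pairs` transmit one allele per parent per locus (Mendelian
transmission, unlinked loci), `mz_pairs` duplicates genotype rows. Because
loci are unlinked, realized sib relatedness concentrates tightly around 0.5
— tighter than with real linked genomes, which is sufficient for testing
GRM/REML machinery but not for IBD-segment methods.

**Phenotype.** On the covariate-adjusted scale, y is a sum of a genetic
component (weights N(0,1) on centered causal-SNP dosages), a methylation
component (weights N(0,1) on causal-probe latents, one causal probe per
block by default so pruning keeps one representative per signal), and
Gaussian noise. Each component is rescaled so its *sample* variance equals
its configured fraction exactly (defaults 0.08 genetic, 0.07 methylation);
the realized fractions recorded in `SyntheticTruth` then deviate from the
targets only through the small cross-covariances between components. The
trait is mapped to its natural scale (BMI kg/m² or height cm) with additive
sex and age effects, so `adjust_phenotype` has real work to do.

**Nuisance structure.** Samples are laid out on 96-well plates and 12-sample
arrays; per-(plate, probe) shifts ~ N(0, `batch_effect_sd`) and
per-(array, probe) shifts at half that SD are added to the latent scale
*after* the phenotype is formed, so batch noise is technical, not
biological. Five cell counts are Gaussian with hematology-scale means,
loaded on y by `cellcount_confounding` and clipped at zero — enough to
create confounding structure, with no attempt at compositional realism.
An optional `meqtl_effect` adds SNP→probe effects for interaction
experiments; by default methylation and genotype are independent, since the
joint (meQTL) distribution is not otherwise constrained by the design.

**What passing tests do not show.** The generator has no probe-type
chemistry, no age-related drift, no longitudinal sampling, no population
stratification, and equicorrelated rather than distance-decaying blocks.
Recovery of variance fractions here demonstrates correctness of the
estimators under the stated model, not robustness to real-data artifacts.

## Preprocessing

Pipeline order is fixed: probe filter → logit → residualize →
inverse-normal. Non-autosomal probes and probes with a SNP at the target
CpG are dropped first (annotation flags, logged count). Betas equal to 0 or
1 are clamped to ε = 1e−6 before the logit (logged count) to avoid infinite
M-values. Technical covariates are one-hot encoded dropping one level;
array position is treated as unordered categorical. Because each array sits
on exactly one plate, the full technical design is rank-deficient; the
pipeline drops aliased columns with a warning (the residual projection is
unchanged), while direct calls to `residualize` raise by default, naming
the collinear columns. The inverse-normal transform uses Blom's offset,
Φ⁻¹((r − 3/8)/(n + 1/4)) with average ranks for ties — the common default
for this class of analysis; constant columns are rejected since their ranks
are undefined. Cell-count adjustment is a sensitivity path
(`include_cell_counts=True`), off by default.

Degrees-of-freedom cost: residualizing on k design columns removes a
fraction ≈ k/n of every probe's variance, signal included. With 12-sample
arrays this is ~10% at any n, and it is the reason recovery experiments
that simulate *no* batch structure adjust only for sex and age — adjusting
a batch-free cohort for ~n/12 array dummies attenuates every variance
fraction by that share while removing nothing real.

## Association scan and inflation

The scan is simple per-probe OLS (the probes are already
covariate-residualized), two-sided p from t at n−2 df, with p floored at
1e−300. λ is defined as the **mean** 1-df χ² statistic across probes —
obtained from p through the χ² quantile, which keeps the definition exact
at small n — not the conventional median-based λ (available via
`method="median"` for comparison). The permutation null shuffles only the
phenotype vector (covariate structure is already removed from both sides);
the default is 100 permutations with a mandatory seed. The effective number
of independent probes is M = 2/sd(λ)², from Var(mean χ²) = 2/M for M
independent 1-df χ² variables.

## Selection and scoring

Candidates pass p < α/P (or an explicit override, e.g. 1e−3 when the strict
threshold yields too few probes). Pruning sweeps candidates in ascending p
(ties broken by chromosome, position, probe id, making the output invariant
to input order) and keeps a candidate iff no kept probe on the same
chromosome within `prune_window_bp` (pairwise distance, ≤, 1-based
coordinates; a tile mode exists behind `window_mode="tile"`) has
|Pearson r| > `prune_r` on the analysis-scale values. Absolute correlation
on the residualized/INT scale is the defensible reading of an unsigned
correlation threshold. A cross-cohort mode (`weights_from_candidates`)
takes an external probe list and pulls weights from a supplied scan,
supporting select-in-A / weight-in-B designs.

Methylation scores are computed on the residualized/INT scale — the scale
the weights were estimated on; passing the raw `MethylationDataset` gives a
beta-scale sensitivity variant. Genetic scores count effect alleles after
harmonization: a weight whose effect allele matches the dataset's other
allele contributes 2 − dosage; unmatchable alleles drop the SNP with a
logged count; missing dosages are mean-imputed per SNP (standard polygenic
scoring convention). Scores are not internally standardized — adjusted R²
is invariant to affine rescaling, and raw sums are more transparent.

## Variance partition

Four nested OLS fits (statsmodels), adjusted R² = 1 − (1−R²)(n−1)/(n−k−1)
reported as-is, including negative values. Marginal significance of each
score inside the additive model is its coefficient t-test. The interaction
is tested by the F-statistic of model 4 against model 3. Scores with
|r| > 0.9999 are rejected as collinear. Raw-R² monotonicity across the
nesting is asserted on every fit as an internal invariant.

## GRM, REML and family correction

The GRM is GCTA-style, A = ZZ'/m with zⱼ = (xⱼ − 2pⱼ)/√(2pⱼ(1−pⱼ)),
monomorphic SNPs skipped and missing dosages mean-imputed. Off-diagonals
strictly below 0.05 are zeroed before model fitting so distant relatedness
cannot absorb phenotypic variance; thresholding can leave the matrix
non-PSD, in which case negative eigenvalues are clipped at zero with a
warning. Near-duplicate pairs (off-diagonal > 0.95; MZ twins or sample
duplicates) can be reduced to one member per pair up front
(`mz_duplicate_filter`); note the cutoff presumes enough SNPs that the
duplicate entries concentrate near 1 (per-entry SD scales as 1/√m).

REML for y = μ + g + e, g ~ N(0, σ²g·K), is exact for one GRM: one
eigendecomposition plus Brent search on log(σ²g/σ²e) over [−12, 12], with
σ²e profiled out. The SE of ĥ² comes from the numerical curvature of the
profiled restricted likelihood in the h² parametrization (undefined at the
boundary). With K = I the ratio is unidentifiable; the output of the
correction then reduces to the standardized input, which is the documented
degenerate behavior.

**Choice of corrected phenotype.** The classical mixed-model residual
y − BLUP(g) leaves relatives *negatively* correlated — Cov(ê) = σ⁴e V⁻¹,
about −σ²g·relatedness for a pair on the standardized scale (≈ −0.25 for
sib pairs at h² = 0.5) — because each member's BLUP borrows the other's
phenotype. Since the purpose of the correction is to hand downstream OLS a
phenotype free of family correlation, the canonical corrected phenotype
here is the GLS-decorrelated residual V^(−1/2)(y − μ̂) at the REML
estimates, which leaves exactly zero correlation between relatives and
reduces to the input for unrelated samples; the BLUP-residual variant
remains available via `method="blup"`.

## Meta-analysis

Fixed-effect inverse-variance pooling over common probes: w = 1/se²,
β = Σwβ/Σw, se = (Σw)^(−1/2), two-sided normal p. Inverse-variance
weighting is the standard fixed-effect estimator when only "fixed-effect"
is specified. Probe ids are canonical array identifiers, so no
strand/allele harmonization applies. Cochran's Q is available behind
`heterogeneity=True` but not computed by default.

## Numerical conventions

Coordinates are 1-based, fully closed, everywhere — including the BED-like
annotation file, which is documented as such. All randomness flows through
`numpy.random.default_rng` with explicit seeds; identical configs produce
bit-identical cohorts. p-values are floored at 1e−300. Writers emit plain
TSV with Python's shortest-roundtrip float formatting, so write→read is
exact.

## Problem sizes used in tests

The suite exercises the null-lambda calibration at 500 samples × 20,000
probes × 100 permutations; additive-recovery at n = 1,500 over 100
replicates (targets 0.07/0.08/0.15, judged within 3 Monte-Carlo SE);
interaction-test calibration over 500 null replicates at n = 200 (KS test,
α = 0.01); REML recovery on 300 sib pairs at h² = 0.5 with 1,000 SNPs; and
pruning against an exhaustive pairwise oracle on 200 random 20-candidate
instances. These sizes were chosen so each check has the statistical power
it needs while the whole suite stays desk-scale.

## Known limitations

Single-GRM REML only (no multi-component decomposition); no robust-SE or
mixed-model MWAS variants; no inflation *correction* (the λ machinery is
diagnostic); two-study meta-analysis only; text formats only (no IDAT,
PLINK .bed, or compressed VCF). The generator's realism limits are listed
above.
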