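# Methods

## Models

Let `y` be an n-vector of one milk trait (fat %, protein %, or a fatty acid
as wt/wt % of total fat) over n cows. Fixed effects are collected in
`X = [1 | herd contrasts | parity contrast | DIM | e^(−0.05·DIM)]`,
treatment-coded with the first level as reference; the last two columns are
the Wilmink lactation-curve adjustment with the conventional rate constant
−0.05 per day held fixed. The design is rejected at construction if rank
deficient (e.g. constant DIM, or an empty factor level after filtering).

Variance partitioning uses two single-kernel animal models fitted
separately:

* genomic:   `y = Xβ + g + e`, `g ~ N(0, G σ²_g)`, `e ~ N(0, I σ²_e)`
* microbial: `y = Xβ + m + e`, `m ~ N(0, M σ²_m)`

with ratios `h²_g = σ²_g/(σ²_g+σ²_e)` and `h²_B = σ²_m/(σ²_m+σ²_e)`
(microbiability). Each ratio's denominator deliberately excludes the other
random component, matching the separate-model definitions; a joint G+M fit
is available through the generic multi-kernel interface but is not used for
the headline ratios, because at a few hundred animals the two components
are poorly separable and the joint fit is fragile.

### Kernels

* `G` (VanRaden method 1): counted-allele frequencies `p_j` are observed
  frequencies over non-missing calls; missing codes are mean-imputed to
  `2p_j` (standard for this estimator; the alternative of dropping pairs
  complicates the cross-product without changing results at ~1% missingness);
  `Z = codes − 2p_j`, `G = ZZᵀ / (2 Σ p_j(1−p_j))`.
* `M = BBᵀ/c`, where `B` is the OTU count matrix centered and scaled
  columnwise with the sample (n−1) SD — hence `trace(M) = n−1` exactly —
  and `c` the number of OTUs. Zero-variance columns are dropped and logged.
* Interaction: the Hadamard (elementwise) product `M ∘ G`, PSD by the Schur
  product theorem. It is not rescaled, so its diagonal is not ≈ 1; variance
  components attached to it are interpreted on that scale.
* Any kernel failing the PSD tolerance (smallest eigenvalue < −1e−8) gets
  the smallest jitter from {1e−8, 1e−6, 1e−4}·I that passes, recorded in
  `psd_adjustment`.

Kernels are computed once on the full animal set and subset per
cross-validation fold; per-fold recomputation would change `p_j` and the
column standardization by fractions of a percent at these sizes while
multiplying cost.

### REML

`reml_fit` maximizes the restricted log-likelihood
`ℓ_R = −½(log|V| + log|XᵀV⁻¹X| + yᵀPy)` over the per-kernel variances and
`σ²_e`, each bounded below at 1e−9 (keeps `V` invertible; near-zero
estimates in real data print as ~1e−7, i.e. effectively at this boundary).
Updates are average-information Newton steps `δ = AI⁻¹ s` with

* `s_k = −½(tr(PK_k) − yᵀPK_kPy)`, `AI_{kl} = ½ (K_k Py)ᵀ P (K_l Py)`,
* traces computed as elementwise sums `Σ_ij P_ij (K_k)_ij`, so one Cholesky
  of `V` dominates each iteration,
* an active-set reduction: components pinned at the bound with negative
  score are held fixed, since including them makes the clipped AI direction
  a descent direction for the free components,
* proposals projected onto the feasible region, step-halved up to 10 times
  if the likelihood would decrease, and replaced by an EM-REML step
  (`σ²ₖ ← σ²ₖ + σ⁴ₖ(yᵀPK_kPy − tr(PK_k))/n`) when halving fails — so the
  restricted likelihood never decreases across accepted iterations.

Convergence: maximum relative parameter change < 1e−8 (denominator floored
at 1e−6 of the total variance so a bound-pinned component's sub-noise
wiggles cannot block convergence), at most 200 iterations; non-convergence
returns the fit flagged with a warning. A component is flagged *boundary*
when it is ≤ max(1e−8, 1e−6 × total variance), covering both exact bound
hits and near-zero estimates. A near-singular AI matrix at the optimum
(condition number > 1e10) triggers a non-identifiability warning — the
behaviour seen when a kernel is proportional to the identity.

Ratio standard errors use the delta method with the inverse AI matrix as
the asymptotic covariance of the variance estimates:
`se² = ∇hᵀ AI⁻¹ ∇h`, `∇h = (σ²_e, −σ²_c)/(σ²_c+σ²_e)²` on the relevant
coordinates. This is an asymptotic approximation; at boundary estimates it
is indicative only.

`profile_reml_oracle` is an independent check used by the tests: for a
single kernel it profiles β and the scale out of the restricted likelihood
and searches the ratio λ = σ²_k/σ²_e on a log grid (default 10⁻⁴…10⁴, 161
points) refined by bounded golden-section search. It shares no code path
with the AI iteration beyond the kernel itself.

## Cross-validation

Step one fits the fixed effects by OLS on all animals and keeps residuals
ỹ (the two-step GFBLUP convention; this leaks a little information from
validation animals into the adjustment, accepted for comparability —
`adjust_phenotypes` can equally be applied within training folds by the
caller). Step two, per replicate: a validation set of `n_val` animals
(default 50 of 292) is drawn uniformly without replacement; variance
components are re-estimated on the training fold under a mean-only design
for each model M4 (G), M5 (M), M6 (G+M), M7 (G+M+M∘G); validation
phenotypes are predicted by the conditional expectation

`ŷ_val = μ̂ + Σ_k σ̂²_k K_(val,train) V⁻¹_train (ỹ_train − 1μ̂)`,

with `μ̂` the GLS mean. Predictive ability is the Pearson correlation
between `ŷ` and `ỹ` in the validation set; RMSE is per replicate, averaged
over the (default 10) replicates. Splits are a deterministic function of
the seed and the animal-id list, so all models and traits in a run share
identical folds — required for the paired model contrasts. Predictions
whose variance is at the numerical bound scale are treated as constant and
their PA recorded as 0 with a warning (an undefined correlation would
otherwise propagate noise); negative PAs are reported as-is.

Model contrasts are one-sided Welch (unequal-variance) t tests on the
replicate-level PAs, with the richer model as the "greater" arm: M6 > M4
(microbiome adds information), M6 > M5 (genetics adds), M7 > M6
(interaction adds). Significance uses the strict inequality
`p < 0.05 / (number of traits × 3)` — with 19 traits, 57 comparisons. The
replicate PAs of two models on shared splits are positively correlated, so
Welch's test is conservative here; it is retained as the conventional
choice for this comparison.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any
particular farm:

* **Genotypes**: per-SNP counted-allele frequency uniform in `maf_range`
  (default 0.05–0.5), genotypes as two Hardy–Weinberg Bernoulli draws,
  missing entries MCAR (default 1%). Animals are therefore *unrelated*;
  the resulting G is a noisy identity whose off-diagonal dispersion scales
  as √(n/m). Real cattle cohorts carry pedigree relatedness that many
  more markers cannot dilute — to emulate a comparable amount of kernel
  structure the experiments use marker counts of the same order as n
  (e.g. 500 SNPs at n = 300) rather than tens of thousands. With m ≫ n the
  ratio σ²_g : σ²_e becomes weakly identified and estimates spread widely;
  this is a property of unrelated populations, not of the estimator.
* **OTU counts**: Dirichlet–multinomial. Compositions are Dirichlet with
  concentration `α_j = 100·s·q_j`, `q_j ∝ j^(−1/s)` (s = `dominance_shape`,
  default 1): a fixed Zipf-like rank-abundance base pattern shared by all
  animals. The default puts ~10–15% of reads on the top OTU, >50% on the
  top 5% of OTUs, and a between-animal CV of ~25–30% for dominant taxa —
  the Prevotella/Bacteroidales-dominated profile typical of rumen
  communities. Library sizes are uniform in 60,000–150,000 reads. Chosen
  over a log-normal–Poisson model as the simplest form reproducing
  dominance plus overdispersion; it does not emulate taxonomic correlation
  structure, diet shifts, or sequencing batch effects, so passing tests
  demonstrate correctness of the estimators under the assumed model, not
  robustness to those real-data features.
* **Phenotypes**: `y = μ + herd + parity + b₁·DIM + b₂·e^(−0.05·DIM) +
  g + m + g×m + e` with effects drawn from the same G, M, M∘G kernels the
  analysis later estimates. Component variances come from the per-model
  ratio definitions, `σ²_g = h²_g/(1−h²_g)·σ²_e`, so targets are exact in
  distribution. Herd (3 levels), parity (2) and DIM (3–398 days) are
  uniform per animal; defaults `μ = 4`, herd effects (0, 0.25, −0.25),
  parity (0, 0.2), `b₁ = −0.0025`/day, `b₂ = 2` give a mild early-lactation
  excursion on a fat-%-like scale. One master seed drives deterministic
  child streams for genotypes, OTUs, covariates and per-trait effects, so
  identical configs are bit-identical and sub-tables are independently
  reproducible.

## Preprocessing conventions

Sample-depth filtering (≥ 50,000 reads) precedes the OTU total-count filter
(≥ 10), both with strict "less than" removal. The depth filter is applied
to OTU-table row totals — an approximation to filtering on post-QC read
counts, which are upstream of this package's inputs. Filters are idempotent
provided thresholds are small relative to library sizes (removing
sub-10-count OTUs cannot push an animal below 50,000 reads in any realistic
table). Genotype QC drops individuals (< 80% call rate) before loci
(< 95% call rate or MAF < 1%, recomputed on retained animals); the order is
fixed and documented since the two orders differ on edge cases. Animal
records must match across rumen, milk and genotype id sets, with DIM ≤ 400.
Descriptive statistics report mean, sample SD and CV% = 100·SD/mean from
unrounded values — recomputing a CV from rounded means/SDs can differ in
the second decimal. Cow clustering uses the Pearson distance (1 − r between
rows of B) and complete-linkage agglomeration, the default of the usual
hclust routine.

## Problem sizes in tests and the acceptance script

Experiments are sized to be informative yet quick: oracle-equivalence fits
use n = 30 with a rank-12 kernel (the kernel null space pins the residual,
keeping the ratio interior); recovery runs 50 herds of n = 300 with 500
SNPs / 600 OTUs; cross-validation behaviour and the end-to-end determinism
check run at full study scale (292 cows, 5,000 SNPs, 3,055 OTUs). For a
null variance component, REML's estimate is asymptotically a half-mixture
with probability ½ exactly at zero, so roughly half of null replicates are
flagged boundary and the rest give small positive values — the recovery
checks assert that band rather than universal flagging.

## Known limitations

* Unrelated simulated animals make genomic prediction across folds weak by
  construction (no families to carry information); genomic PAs at large
  marker counts hover near zero even for heritable traits. Microbial
  prediction does not suffer this because community composition itself
  provides the between-animal covariance.
* SEs from the AI matrix and the delta method are asymptotic; with ~300
  animals they are indicative (the motivating application reports SEs of
  0.05–0.2 at similar size).
* Single records per animal; no repeated measures, no multi-trait REML, no
  dominance/epistatic genomic kernels, and bacteria only (no archaea,
  fungi or protozoa kernels).
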