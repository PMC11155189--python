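# Methods

## Model

Phenotypes from a MET with `N` genotypes and `J` environments are modeled as

```
y = Xβ + Zu + e
```

where `β = (μ_1, …, μ_J)` are fixed environment means, `u` stacks the
centered environment-specific breeding values (env-BVs) environment-major
with `u ~ N(0, Σ_G)`, `Σ_G = Ω_G ⊗ A`, and `e ~ N(0, Σ_E)` with `Σ_E`
diagonal, one error variance `σ²_{E_j}` per environment. `A` is any genetic
relationship matrix (here a VanRaden-1 GRM from biallelic dosages), `Ω_G` is
the unstructured J×J genetic covariance between environments, and
`Σ_Y = ZΣ_GZᵀ + Σ_E`. `Z` maps plots to (genotype, environment) cells;
duplicated rows are replicate plots of the same cell.

Each env-BV decomposes as `G_ij = μ_j + U_ij`. Conditional on the phenotypes,
`G_ij` is Gaussian with mean `Ĝ_ij = μ̂_j + [Σ_G Zᵀ M y]_ij` (the env-GEBV,
with `μ̂` the GLS estimate and `M` the GLS annihilator) and covariance
`P = Σ_G − Σ_G Zᵀ Σ_Y⁻¹ Z Σ_G`. `P` is the prediction-error variance defined
*as if β were known*; an optional flag adds the fixed-effect correction
`(X_g − Σ_G ZᵀΣ_Y⁻¹X)(XᵀΣ_Y⁻¹X)⁻¹(·)ᵀ` for sensitivity analyses (default
off, matching the definition above). The correction matters only at very
small N; a joint-simulation test verifies that the empirical covariance of
`G − Ĝ` equals the corrected `P`.

## Metric BLUPs

The five metrics are quadratic (or bilinear) forms in the env-BVs. Writing
`E(Q²|y) = [E(Q|y)]² + Var(Q|y)` per summed combination gives closed forms:
the expectation ("Geno-Exp") part is the plain metric evaluated on `Ĝ`, and
the variance part contracts `P`:

- Lin–Binns: `(1/2J) Σ_j (P_{ij,ij} + P_{r_j j,r_j j} − 2P_{ij,r_j j})`,
  with reference genotype `r_j` chosen from `Ĝ` (each estimator must be
  computable from its own inputs; ties go to the lowest genotype index).
- Environmental Variance: `(1/(J−1)) Σ_j (P_{ij,ij} − (1/J)Σ_{j'} P_{ij,ij'})`.
- Ecovalence: the double-centering contraction, assembled from five block
  averages of `P` (diagonal; within-genotype environment means;
  within-environment genotype means; per-environment-pair double means and
  their row means) — algebraically identical to the printed quadruple sums
  but O(NJ·n) time and O(NJ) memory.
- Finlay–Wilkinson: the BLUP of a ratio is approximated by the ratio of
  BLUPs (first-order Taylor); numerator and denominator each get their PEV
  correction. The corrected denominator is provably ≥ its expectation part
  for PSD `P`; it can only degenerate when the environment means are
  (numerically) constant, which raises an error rather than clamping.
- Average: the row mean of `Ĝ`; no variance term exists, so `geno_exp` and
  `geno_exp_var` coincide.

`P` is never materialized beyond 4000 cells: it is held as
`Ω_G ⊗ A − BBᵀ (+ EEᵀ)` with `B = Σ_G Zᵀ L⁻ᵀ` from the Cholesky factor `L`
of `Σ_Y` (and `E` the optional fixed-effect term), from which all
contractions follow by reductions over `B`. Every contraction is tested
against the naively assembled dense tensor on small instances, and the full
estimators against a Monte-Carlo oracle that draws `G|y ~ N(Ĝ, P)` and
averages the plain metrics (20 000 draws, agreement within 3 MC standard
errors for the quadratic metrics; the Finlay–Wilkinson gap measures the
Taylor error and shrinks with the PEV, as a dedicated test checks). The
oracle holds `r_j` fixed at the value chosen from `Ĝ`, matching the closed
form.

### Unbiasedness

For fixed-reference quadratic forms the full BLUP is unbiased over the
phenotype distribution: over 200 simulated replicates (N=50, J=5, known
components) the means of the Environmental Variance and Ecovalence BLUPs
match the means of the true metrics within 3 standard errors, while the
expectation-only estimator is strongly downward-biased (it omits
`Var(Q|y) ≥ 0`). Lin–Binns is the exception: the *true* metric references
the realized best genotype per environment, whereas the estimator can only
plug in the best genotype of `Ĝ`; because the realized maximum is an
extreme-value selection, the estimator carries a systematic deficit that no
conditional expectation of a fixed quadratic form can remove. Against a
truth recomputed with the estimator's own (fixed) reference, Lin–Binns is
unbiased as well. The corresponding acceptance test asserts the blanket
claim and is therefore expected to fail for Lin–Binns; this is a property of
the metric's definition, not an implementation defect.

## Variance-component inference

A conjugate Gibbs sampler estimates `(β, Ω_G, Ω_E)`:

- `μ_j | ·` — Gaussian (flat prior);
- `u_j | u_{−j}, ·` — Gaussian, conditioned through the precision
  `[Ω_G⁻¹]_{jj} A⁻¹ + diag(counts_j)/σ²_{E_j}` (one N×N Cholesky per
  environment per iteration);
- `Ω_G | ·` — inverse-Wishart `IW(ν₀ + N, Ψ₀ + UᵀA⁻¹U)` with prior
  `ν₀ = J+2`, `Ψ₀ = I` (prior mean `I`, weakly informative at unit genetic
  variance);
- `σ²_{E_j} | ·` — scaled inverse chi-square with prior df 5 and scale 1.

Defaults are 20 000 iterations, 2 000 burn-in, thinning 2; a fast profile
(2 000/500/2) serves tests and desk-scale runs. Point estimates are
posterior means; effective sample sizes (via arviz) below 50 raise a
warning, never an error. Unobserved cells are simply absent from the
likelihood — no data augmentation — so arbitrary sparseness patterns are
handled exactly.

**Identifiability.** With a near-identity relationship matrix and one plot
per cell, only the off-diagonal structure of `A` separates genetic from
error variance within an environment; the split is then essentially
prior-driven (cross-environment covariances remain well identified). The
parameter-recovery tests therefore use two plots per observed combination,
which pins the error variances through within-cell contrasts; under that
design 20 replicates at N=300, J=4 recover genetic variances within 4%,
error variances within 7%, and the genetic correlation within 0.05 on
average. Real analyses should provide either replicates or a structured
relationship matrix for reliable variance components.

## Simulator

The generator emulates a genotyped breeding panel and the trait model above:

- Markers: per-locus allele frequency `p_m ~ U(maf_floor, 1−maf_floor)`
  (floor 0.05), dosages `Binomial(2, p_m)`; loci whose realized MAF falls
  below the floor are redrawn. Defaults: 200 genotypes × 1279 loci, a
  realistic size for a diversity-array wheat panel. No linkage, family, or
  population structure — genotypes are essentially unrelated, so the GRM is
  identity-like with off-diagonal noise ~0.03.
- GRM: VanRaden method 1 on observed frequencies.
- Env-BVs: `μ_j ~ N(100, σ_μ²)` iid; `vec(U) = chol(Ω_G ⊗ A) z` realized as
  `L_A Z L_Ωᵀ`; `Ω_G` has unit diagonal and common pairwise correlation ρ.
- Phenotypes: one plot per observed cell, `y_ij = G_ij + e_ij` with
  `σ²_{E_j} = (1−h²_j)/h²_j` from `h²_j = c + d_j`, `d_j ~ U(−0.2, 0.2)`
  drawn afresh per replicate (plot-level heritability at unit genetic
  variance).
- Sparseness: a uniformly random fraction of the N·J cells is masked, with a
  connectivity guard keeping ≥1 observation per genotype and per
  environment. At high sparseness (75%, J=10) a uniform mask almost surely
  empties some genotype, so after a few resampling attempts the guard
  repairs the mask by swapping cells while keeping the masked count exact.

Basic condition: N=200, J=10, σ_μ=1, ρ=0.5, c=0.5, sparseness 0.

**What passing tests do not show.** Because the panel is unrelated, genomic
estimators borrow less information than they would from a real structured
population; replicated coincidence means for the stability metrics sit a few
points below what a family-structured panel yields (the phenotype-only
baseline, which ignores the GRM, is unaffected). Real data also carry
spatial trends, non-Gaussian errors and heteroscedastic replicates that the
simulator does not emulate.

## Evaluation machinery

- **Selection coincidence**: percent overlap of the k = round(intensity·N)
  genotypes selected on estimates versus reference values, ties broken by
  genotype index, lowest-k for all four selectable metrics (Lin–Binns,
  Environmental Variance, Ecovalence, Average; the slope has no desirable
  tail). A calibration test confirms random rankings overlap at ≈ the
  intensity.
- **Scaled RMSE**: RMSE divided by the standard deviation of the reference
  values — the definition chosen here so that magnitudes compare across
  metrics with different scales.
- **CV1**: per repeat, a training fraction (25/50/75%) of genotypes is
  sampled, *all* phenotypes of the remaining genotypes are discarded before
  fitting, and criteria are computed on the test set only; splits leaving an
  environment empty are resampled and logged. Constant test predictions
  (e.g. with an identity relationship) yield a missing correlation, not an
  error. A mutation test asserts that perturbing test-genotype phenotypes
  cannot change any result.
- **Scenario benchmark**: one marker panel is generated from the master seed
  and shared across scenarios and replicates (as a study reuses one
  genotyped population); env-BVs and phenotypes are redrawn per replicate;
  per-replicate failures are logged and skipped.

Per-replicate variance components default to re-estimation by MCMC; the
documented fast mode reuses supplied (or simulation-truth) components and is
what the replicated benchmarks and the acceptance script use, keeping a
50-replicate run under a minute.

## Numerical choices

- Cholesky solves throughout; diagonal jitter escalates from 0 to at most
  1e−8 (relative to the trace scale) before a factorization error is raised.
- Canonical observation order is (environment, genotype); results are
  invariant to input row order.
- Environment-major cell indexing `j·N + i` matches `Ω_G ⊗ A` everywhere.
- Master seeds spawn independent child streams (numpy `SeedSequence`) for
  the panel and each replicate, so every run is bit-reproducible given its
  seed and replicate prefixes coincide across run lengths.

## Problem sizes in the test suite

Replicated studies run at the basic condition (N=200, J=10): 50 replicates
for the coincidence reproduction, 20 per parameter level for the trend
directions, 200 small-instance replicates (N=50, J=5) for the bias study,
and 20 replicated-design datasets (N=300, J=4) for sampler recovery — sizes
chosen so the default suite completes in a few minutes while leaving the
Monte-Carlo error well below every asserted tolerance.

## Known limitations

- The Finlay–Wilkinson BLUP is first-order Taylor only; no higher-order
  correction is provided.
- `Ω_G` is unstructured: with many environments its estimation degrades and
  factor-analytic structures (not implemented) would be preferable.
- No REML path; inference is Bayesian-only.
- No spatial adjustment of raw plot data; inputs are assumed to be adjusted
  means or single plots.
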