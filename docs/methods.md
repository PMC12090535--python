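# Methods

## The model

`mkgp` fits Bayesian multi-kernel mixed models for genomic prediction in a
multi-environment trial. For a vector of phenotype observations `y` (one
record per line × environment × replicate),

    y = X·mu + Σ_r u_r + e,        e ~ N(0, sigma_e^2 I)

where `X` is the intercept design — a single column of ones, or one
indicator column per environment whenever the data span more than one
environment — and each random effect `u_r` is a zero-mean Gaussian vector
with covariance `sigma_r^2 K_r`. The kernels `K_r` carry all structure:

| kernel | construction | captures |
|---|---|---|
| `G` | VanRaden linear kernel `W Wᵀ / (2 Σ p_k (1−p_k))`, `W = X − 2p` | additive genetic effects; mean diagonal = 1 + f |
| `G#G` (`EPI`) | Hadamard square `G ∘ G` | pairwise epistasis (PSD by the Schur product theorem) |
| `A` | cross-product of the centred homozygosity indicator (1 = AA/BB, 0 = AB), rescaled to mean diagonal 1 | dominance |
| `T` | per-gene standardised abundances, cross-product / gene count | transcriptome; built at observation level when expression is profiled per environment, so it absorbs E and G×E signal |
| `GAUSS` | `exp(−d²_ij / h)` over centred marker rows | additive plus cryptic non-additive effects in one term (RKHS) |
| `GxE` | `(Z_g G Z_gᵀ) ∘ (Z_E Z_Eᵀ)` | environment-specific genetic deviations (block-diagonal over environments) |

Line-level kernels are expanded to observations through 0/1 incidence
matrices. Thirteen model scenarios combine these terms (see
`mkgp.scenarios`); the nine GBLUP scenarios use the linear kernels with
separate non-additive terms, the four RKHS scenarios replace the genomic
terms with the single Gaussian kernel.

Every variance component has a scaled inverse-χ² prior — the conjugate
choice giving closed-form Gibbs updates. Defaults follow the rule
popularised by Bayesian genomic-regression software: df = 5, scale chosen so
the prior mode equals an equal share of the phenotypic variance (half to the
residual, half split across terms, each divided by the kernel's mean
diagonal). Realised values are logged in `PosteriorSamples.realised_priors`.
The intercept prior is flat.

## The sampler

Each observation-level kernel is eigendecomposed once, `K = U Λ Uᵀ`
(eigenvalues below `1e-10·λ_max` truncated, retained rank recorded). With
`u = U s`, `s ~ N(0, sigma² Λ)`, the full conditional of `s` factorises over
coordinates because `U` has orthonormal columns, so one sweep costs two thin
matrix products per term instead of a dense solve. Variance components are
drawn from their scaled inverse-χ² conditionals; sampled variances are
floored at 1e-10 to avoid degenerate χ² draws. A covariance-form sampler
(`gibbs_fit_dense`) implements the identical model without the
transformation and is used to validate the transformed sampler: posterior
means of all variance components agree within 3 Monte-Carlo standard errors
on a 30-line instance.

Chain defaults are 12 000 iterations, 2 000 burn-in, thinning 5; the
effective sample size of each variance chain is estimated by the
initial-positive-sequence method and a coded warning is emitted below 100.
Test and cross-validation chains in this repository are much shorter
(600–3 000 iterations) — the problem sizes used there (30–200 lines) mix
quickly, and the validation suite checks the chains against closed-form and
dense-sampler oracles at exactly these lengths.

The Gaussian bandwidth `h` is fixed per fit, defaulting to the median of the
nonzero pairwise squared distances (logged); it is a hyperparameter of the
kernel, not a sampled quantity. An optional flag divides squared distances
by the marker count for dimension-free bandwidths.

## Prediction and cross-validation

Prediction uses whole-kernel conditioning: kernels are built over all lines,
held-out phenotypes are passed as NaN and treated as missing data — imputed
from the current model state each sweep (proper data augmentation), so the
masked values never influence the chain. A leakage test asserts that
corrupting held-out phenotypes leaves the held-out predictions bitwise
unchanged.

Cross-validation partitions *lines* (never observations) into five
near-equal folds, so a genotype never sits in train and test simultaneously
across environments. Accuracy is the Pearson correlation between observed
and predicted phenotypes computed *within* each environment, averaged over
environments to a fold score (stratified scoring); the report gives the mean
and standard deviation across the five fold scores, with the pooled
correlation emitted alongside for diagnostics. Cells with undefined
correlation (zero variance) are excluded with a coded warning. Repeated
trait measurements (`name_1`, `name_2`, …) can be analysed independently and
averaged (`--replicate-analyses`).

GEBVs are the per-line posterior means of the genetic terms (`G`, `EPI`,
`A`, `GAUSS`); transcriptome and G×E terms are excluded by definition of a
breeding value.

## The synthetic panel

The generator emulates a structured, largely inbred small-grain diversity
panel observed in two contrasting environments:

- **Genotypes.** Per marker, a panel-level allele frequency p ~ U(0.05, 0.5).
  Lines belong to `n_subpops = 20` families whose frequencies drift around p
  under the Balding–Nichols model with `fst = 0.35`; within a family,
  genotype classes follow inbreeding-adjusted Hardy–Weinberg proportions
  with `f = 0.95`. The family structure is essential, not cosmetic: genomic
  prediction of untested lines operates entirely through kinship between
  training and test lines, and an i.i.d. panel (obtainable with
  `n_subpops = 1`, used for the Hardy–Weinberg and GRM-scaling checks) has
  a prediction ceiling near zero regardless of heritability.
- **Transcriptome.** Per gene and environment: a sparse linear read-out of
  ~10 marker dosages (variance share `transcriptome_h2 = 0.4`), an
  environment main shift and an environment-specific marker read-out
  (together `transcriptome_env_frac = 0.3`, split evenly), plus Gaussian
  noise. Abundances are emitted directly on a normalised continuous scale;
  no count layer is modelled, since downstream analysis consumes normalised
  expression.
- **Phenotypes.** Each random effect is drawn from N(0, sigma²·K) with the
  same kernels the models fit, expanded through incidence matrices, plus iid
  noise — so `true_effects` reconstructs every phenotype exactly. The G×E
  effect generalises the block kernel with a cross-environment correlation
  `gxe_env_corr` (covariance `sigma² (Σ_ρ ⊗ G)`): ρ = 0 reproduces
  independent per-environment deviations; negative ρ produces crossover
  interaction, where line rankings flip between contrasting environments.
  Independent deviations contain an implicit line main effect (variance
  σ²/2 with two environments) that a G-only model absorbs; contrasting
  day-length or site regimes realistically produce crossover, so the default
  flowering trait uses ρ = −0.5.
- **Default traits.** Flowering time: intercept 100 (days), additive 0.5,
  epistatic 0.1, G×E 1.5 with ρ = −0.5, residual 0.5, environment offset
  8 days. Height: intercept 90 (cm), additive 1.5, epistatic 0.1, G×E 0.1,
  residual 0.5, offset 2 cm. These make flowering strongly G×E-mediated and
  height mostly additive.

Randomness: one `numpy.random.Generator` per stage, seeded by
`SeedSequence(seed, spawn_key=(stage,))` so regenerating one stage never
shifts another; identical configs give bitwise-identical panels.

What the generator does **not** emulate: linkage disequilibrium and genetic
maps, pedigree descent, selection, read-level expression noise, or shared
causal architecture between the simulated transcriptome and the trait
beyond their common dependence on markers and environment. Passing tests
therefore demonstrate correctness of the estimators and the qualitative
behaviour of the model scenarios under kinship-driven prediction, not
performance magnitudes on any real panel.

## Study sizes used by the validation suite

Chosen so every check exercises the full pipeline at sizes where the
Monte-Carlo tolerances are meaningful: GRM scaling on 500 lines × 2 000
markers; sampler-vs-BLUP oracle on 50 lines with variances fixed at truth;
eigen-trick equivalence on 30 lines × 2 environments × 2 replicates;
variance recovery on 200 lines × 2 environments × 2 replicates over 20
seeds (replication identifies the residual: with a single replicate the
identity-like part of the kernels is confounded with noise and the
partition between them is prior-driven); scenario comparisons on 150 lines
× 1 000 markers × 500 genes with a nearly pure crossover G×E trait
(additive 0.05, G×E 2.0 with ρ = −0.8, residual 0.3); null calibration on
100 lines against a 50-draw permutation null.

## Numerical choices

- Kernel PSD floor: `λ_min ≥ −1e-8·λ_max`; eigenvalues in the float-noise
  band are clipped to zero by `KernelMatrix.repaired()` with a warning,
  anything lower is an error.
- Monomorphic markers are dropped (warning) before centring; missing
  genotype codes are mean-imputed to `2 p_k`; the `{−1,0,1}` dialect is
  auto-shifted and matrices whose values are all in `{0,1}` are rejected as
  ambiguous.
- Dominance on a fully inbred panel is an error from `dominance_kernel`
  (the design is constant); the scenario catalog instead drops the term
  with a warning so one degenerate term cannot abort a 13-scenario run.
- Pearson correlation is undefined under zero variance and reported as
  missing, never as 0.

## Known limitations

- Variance partitions from unreplicated single-observation designs are
  weakly identified (see above); interpret them with the reported posterior
  spread, not as point estimates.
- The RKHS G×E block uses the Gaussian kernel inside the block structure —
  the natural reading of a Gaussian-kernel environment interaction — though
  a linear-G variant would also be defensible.
- CV1/CV2-style designs (predicting into unobserved environments) are out
  of scope; the fold design always observes every environment in training.
- Multi-trait models, marker-effect parameterisations (BayesA/B/Cπ) and
  alternative samplers are not implemented.
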