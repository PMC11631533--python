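# Methods

## Model

All evaluation routes assume the additive animal model. For one trait,

    y = Xb + Za + e,  a ~ N(0, A σa²),  e ~ N(0, I σe²),

with `A` the additive relationship matrix over every pedigree member
(phenotyped or not) and `Z` the incidence of observations on pedigree
members. For m traits the random effects stack with covariances `G0 ⊗ A`
(genetic) and `R0 ⊗ I` (residual, homoscedastic across individuals,
correlated within an individual). Phenotypes are assumed pre-adjusted for
trial design and spatial effects, so the default fixed-effect design is an
intercept; arbitrary covariate matrices are accepted through `ModelDesign`.

## Pedigree algebra

Pedigrees are topologically sorted trios with opaque string ids; parents
referenced but never declared are auto-promoted to founders, matching common
pedigree-file practice. `A` is built by the tabular recursion
`a_ij = ½(a_j,sire(i) + a_j,dam(i))`, `a_ii = 1 + ½ a_sire(i),dam(i)`.
Inbreeding coefficients come from the tabular diagonal for pedigrees up to
2,000 members and from the Meuwissen–Luo ancestor-tracing algorithm above
that (the two agree to 1e-12 on overlapping sizes). The sparse inverse of
`A` is assembled directly by Henderson's rules with Mendelian-sampling
variances `d_i = ½ − ¼(F_sire + F_dam)` (¾ − ¼F with one known parent, 1
with none); a flag disables the inbreeding adjustment, since some
established implementations are ambiguous about it — the default is on,
which makes `A⁻¹ A = I` exact.

## PCA and imputation

`fit_svd_pca` is plain SVD-PCA on the (centered, optionally scaled)
complete matrix: eigenvalues are the score variances with denominator n−1,
loadings are orthonormal, and the model stores center and scale so the
back-transformation is exact. Centering defaults on and scaling off, the
usual default of standard PCA implementations; the scale vector is recorded
in the model either way. Signs are fixed deterministically by making the
largest-magnitude loading of each column positive (ties broken by trait
order), so repeated runs are bitwise identical.

Missing data are handled before the transformation. `filter_missing` drops
traits with more than 40% missing cells first, then individuals with more
than 25% missing over the remaining traits (both thresholds configurable;
the order matters and is fixed). `impute_mean` is the baseline.
`fit_bpca` implements a variational Bayesian PCA: `y = Wx + μ + ε` with
isotropic residual precision τ and an automatic-relevance prior on the
columns of W. Each iteration (i) regresses factor scores on the observed
coordinates of each row (rows are processed grouped by missingness pattern,
so the E-step is vectorised), (ii) predicts missing cells as `W_miss x`,
(iii) updates W, μ, τ and the relevance weights. Convergence is monitored
on the imputed matrix itself — relative Frobenius change of the completed
matrix and of W below the threshold (defaults: 10,000 max steps, 1e-6) —
because the imputed values are the quantity downstream code consumes.
Observed cells are never modified. Non-convergence returns a flagged
result with a warning, never silently.

Loading diagnostics: per-trait contributions to component k are `100 Λ_jk²`
(summing to 100 by orthonormality); trait clustering uses Ward linkage on
Euclidean distances between loading rows; two ordinations are compared by a
Mantel test (Pearson statistic, one-sided "greater", 999 permutations by
default) on their loading-distance matrices. Note that with all components
kept the loading rows form an orthogonal matrix and their distances are
nearly constant; Mantel comparisons are meaningful on the leading axes.

## REML and BLUP

BLUP at fixed variances solves Henderson's mixed-model equations with the
sparse `A⁻¹`; near-singular coefficient matrices receive a logged ridge of
`1e-8 · trace/dim` and the solve continues, mirroring the "continue on
singularity" behaviour breeders expect from production software. The MME
route is what extends predictions to non-phenotyped pedigree members
(mid-parent EBVs fall out of the equations).

Univariate REML runs in the eigenbasis of `H = Z A Z'`: after one
eigendecomposition per design, the marginal covariance is diagonal
(`σa² s_r + σe²`), and each iteration costs O(n p²). EM is the reference
algorithm — its complete-data formulation over the rotated genetic values
gives closed-form updates whose restricted log-likelihood is provably
non-decreasing, which the tests assert at every iteration. AI (average
information) is the accelerator: Newton-like steps on the score with the AI
matrix, falling back to an EM step whenever a proposed update leaves the
parameter space or decreases the likelihood. Convergence requires relative
parameter change < 1e-8 *and* likelihood change < 1e-6 within 1,000
iterations (defaults chosen strict; the full trace is always returned).
Estimates are clamped at `1e-8 · var(y)` with a boundary flag rather than
going negative. Component SDs come from the inverse AI matrix at
convergence; the SD of h² = σa²/(σa²+σe²) uses the first-order Taylor
approximation for a ratio, `SD(A/B) = (A/B)·sqrt((SD A/A)² + (SD B/B)²)`,
treating numerator and total as uncorrelated.

Multitrait REML has two paths. With complete data the same spectral
rotation block-diagonalises the problem into n independent m×m rows
(`Σ_r = s_r G0 + R0`), and EM updates for `G0` and `R0` (with the
fixed-effect-uncertainty corrections that make it REML rather than ML) are
computed batched over rows. With per-trait missingness the model is fitted
through the stacked Henderson equations with `R⁻¹` assembled per individual
over its observed traits and `G⁻¹ = G0⁻¹ ⊗ A⁻¹`; the EM E-step needs dense
blocks of the inverse coefficient matrix, so this path is intended for
small problems (it is also the cross-check for the spectral path, and the
two agree on complete data). Identical responses passed as a trait pair are
rejected up front: the residual covariance would be singular.

The staged many-trait workflow is: (a) univariate REML per trait,
(b) pairwise bivariate REML for all m(m−1)/2 combinations started at the
univariate estimates, (c) assembly of `G0`/`R0` (diagonals from stage a,
covariances from stage b) and a single multitrait BLUP with those matrices
fixed. Assembled matrices that are not PSD are repaired by clipping
eigenvalues at 1e-6 of the largest ("bending"), logged and flagged. At
small n the pairwise estimates are mutually inconsistent often enough that
bending fires on most runs; staged and jointly-fitted EBVs then agree to
r ≈ 0.98 rather than exactly.

## Per-PC evaluation, back-transformation, selection

`evaluate_pcs` fits one univariate animal model per component score column
(sharing `A` and `A⁻¹` across fits); a zero-variance column is skipped with
a warning and a zeroed EBV column. Component EBVs map back to the trait
scale as `G_orig = G_ebv Λ' diag(s) + μ`, exact when p = m. When `G0` and
`R0` are proportional (`G0 = γP0`, `R0 = (1−γ)P0`) the trait-covariance
eigenbasis diagonalises both, the multitrait BLUP decouples exactly into
the per-PC univariate BLUPs, and the package reproduces this identity to
machine precision; with variances *estimated* per PC the agreement is
limited by REML sampling noise.

Selection indices are signed, name-resolved weighted sums of trait-scale
EBVs with |weights| normalised to 1. By default each EBV column is centered
and scaled to unit variance before weighting, because traits are usually on
incommensurate scales; a raw mode is provided and the choice is recorded in
the result. Ranks are descending with ties broken by id. Rankings are
compared by Pearson r over all candidates, Kendall τ-b over the *reference
method's* top-k candidates' ranks in both full lists (membership defined by
the reference), and top-k set overlap. τ-b uses exact enumeration for
n ≤ 10 without ties and the tie-adjusted normal approximation otherwise;
p-values are reported but never drive decisions.

## Simulator

`simulate_pedigree` builds discrete generations of random sire×dam
full-sib families from the previous generation. `simulate_traits` draws
breeding values recursively down the pedigree — founders ~ MVN(0, G0),
offspring get the parent average plus a Mendelian-sampling deviation with
covariance `½(1 − ½(F_s + F_d)) G0` — rather than one global Cholesky of
`G0 ⊗ A`, which scales as O(n m²) and is testable against the A-matrix
moments (mid-parent regression slope 1, founder covariance G0). Residuals
are MVN(0, R0) and `Y = μ + a + e`. Missingness is MCAR only, applied
cell-wise with a seed; a draw that empties a trait is redrawn once and then
errors.

Presets mirror two forest-tree designs scaled to ≤ 600 individuals:
`scots-small` (15 traits, complete), `scots-large` (10 traits, 13.3%
missing) and `loblolly` (26 traits, 32 founders, 10% missing). Each keeps
the published per-trait narrow-sense heritabilities on unit phenotypic
variance (σa² = h², σe² = 1 − h², h² ranging 0.04–0.65) and imposes a
block correlation structure (production / quality / disease trait groups,
within-block genetic correlation 0.5–0.6, between-block 0.1) — a
deliberate simplification: real trait covariances are not block-compound
and real missingness is not MCAR, so passing tests show correctness of the
machinery under the stated generative model, not robustness to informative
missingness or covariance misspecification.

Test and validation problem sizes are kept modest by design: pedigrees of
200–600 for model fits, 400 individuals × 6 traits for the end-to-end
concordance runs (40 founders plus 45 full-sib families of 8, the family
ratio of a typical progeny trial), and 500 × 10 for the timing comparison.
At these sizes the per-PC heritability SEs are ≈ 0.08–0.10, which bounds
how closely the REML-estimated PCA route can track the multivariate
reference (index correlations ≈ 0.93–0.99 under proportional covariances,
0.65–0.98 under adversarial general covariances).

## Known limitations

- The per-PC route treats components as genetically independent; when the
  true `G0` is far from proportional to the phenotypic covariance, genetic
  correlations between components are ignored and EBV accuracy is lost
  (visible in the general-covariance concordance distribution).
- The missing-data multitrait REML path inverts the coefficient matrix
  densely and is only suitable for small problems; the spectral path
  requires complete data.
- BPCA assumes an isotropic residual and linear structure; heavily
  non-Gaussian traits (counts, binary scores) are imputed on the linear
  scale.
- Only MCAR missingness is modelled or simulated.
- No genomic (marker-based) relationships, genetic groups, maternal or
  permanent-environment effects, or heterogeneous residual variances.
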