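# pcablup — fast multitrait genetic evaluation through phenotype PCA

`pcablup` is a Python library for pedigree-based genetic evaluation of many
correlated traits, written for tree- and animal-breeding analysts who need
breeding values and selection rankings for 5–30 traits without waiting for a
full multivariate REML analysis to (not) converge.

## The idea

The multitrait animal model for *n* individuals and *m* traits is

    y = Xb + Za + e,    a ~ N(0, G0 ⊗ A),    e ~ N(0, R0 ⊗ I),

where `A` is the additive (numerator) relationship matrix from the pedigree
and `G0`, `R0` are the m×m genetic and residual covariance matrices. Fitting
this model jointly is slow and fragile: the classical workflow needs
univariate fits for starting values, all m(m−1)/2 pairwise bivariate REML
fits to fill `G0`/`R0` (325 fits for 26 traits), and a final multitrait
solve that often runs for thousands of iterations.

`pcablup` instead transforms the phenotype matrix to orthogonal principal
components, fits an **independent univariate animal model to each
component** (REML variance components + BLUP breeding values, each
converging in a few iterations), and maps the component breeding values back
to the trait scale:

    G_orig = G_ebv Λ' + μ,

which is exact when all components are kept. Missing phenotypes are handled
*before* the transformation, either by trait means or by a variational
Bayesian PCA (BPCA) that predicts missing cells from the principal-axis
model (`y_miss = W_miss x`). Selection indices built on the back-transformed
breeding values are then compared against the multivariate reference with
Pearson correlation, top-k Kendall τ and top-k overlap.

The package also implements the classical staged multitrait workflow
(univariate → pairwise bivariate → fixed-covariance multitrait BLUP, with
eigenvalue "bending" of non-PSD assembled matrices) so the two routes can be
compared on the same data, plus a simulator that generates multi-generation
pedigrees and correlated traits under the exact generative model above.

## Worked example

`examples/04_pca_evaluation_pipeline.py` simulates 400 individuals × 6
traits with mean heritability 0.3 and a general (non-proportional) genetic
covariance, runs both routes, and prints:

```
simulated 400 individuals x 6 traits (mean h2 = 0.3)
PC variance explained: [32.2 23.6 17.7 10.7 10.1  5.8] %
per-PC h2: [0.11, 0.25, 0.31, 0.43, 0.66, 0.69]
index concordance: Pearson r = 0.935 over 400 candidates
top-50 agreement: Kendall tau = 0.482 (p = 7.7e-07), overlap = 38/50
```

Reading the numbers: the six orthogonal components each get their own
heritability estimate; an equal-weight selection index computed from the
back-transformed per-PC breeding values correlates at r = 0.935 with the
index from a full multivariate BLUP, and 38 of the top-50 candidates are
shared — similar selection decisions at a small fraction of the cost
(`examples/05_staged_multitrait.py` times the two routes on 500×10:
roughly 0.4 s vs 12 s).

The other examples cover pedigree algebra (`01`), filtering + BPCA
imputation + loading diagnostics (`02`), and a single-trait REML/BLUP run
with standard errors (`03`). A thin CLI wraps the same pipeline:

```bash
pcablup simulate --preset scots-large --seed 1 --out-dir sim/
pcablup evaluate --pedigree sim/pedigree.csv --phenotypes sim/phenotypes.csv \
    --method bpca --q 5 --weights trait_1=0.5,trait_2=0.5 --out-dir run/
pcablup compare --reference run/index.csv --candidate other/index.csv
```

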