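"""The staged multitrait evaluation and its cost relative to the PCA route.

Runs the classical many-trait workflow on a simulated 500 x 10 dataset:
(a) univariate REML per trait for starting values, (b) all 45 pairwise
bivariate REML fits to fill G0/R0, (c) one multitrait BLUP with the
assembled covariances fixed — then times the per-PC univariate route on the
same data.
"""

import time
import warnings

import numpy as np

from pcablup import (
    SimulationConfig,
    back_transform,
    evaluate_pcs,
    fit_svd_pca,
    simulate_pedigree,
    simulate_traits,
    staged_multitrait_evaluation,
)
from pcablup.simulate import random_psd_covariance

warnings.simplefilter("ignore")

m = 10
h2 = np.linspace(0.1, 0.6, m)
cfg = SimulationConfig(
    founders=40, generations=2, families_per_generation=46,
    offspring_per_family=10, trait_means=np.zeros(m),
    G0=random_psd_covariance(m, h2, seed=61),
    R0=random_psd_covariance(m, 1 - h2, seed=62), seed=63,
)
ped = simulate_pedigree(cfg)
tm, _ = simulate_traits(ped, cfg)

t0 = time.perf_counter()
fit, report = staged_multitrait_evaluation(tm, ped, algorithm="ai",
                                           bivariate_max_iter=200)
t_staged = time.perf_counter() - t0
print(f"staged evaluation: {report.n_bivariate} bivariate fits, "
      f"bending applied: {report.bending_applied}")
print(f"stage-b iterations: min {min(report.bivariate_iterations)}, "
      f"max {max(report.bivariate_iterations)}")
print(f"wall clock: {t_staged:.1f} s")

t0 = time.perf_counter()
model = fit_svd_pca(tm)
ebv, _, _ = evaluate_pcs(model, ped, algorithm="ai")
back_transform(ebv, model)
t_pca = time.perf_counter() - t0
print(f"per-PC univariate route on the same data: {t_pca:.1f} s "
      f"({t_staged / t_pca:.0f}x faster than staged)")
print(
    "The staged route spends almost all its time in the m(m-1)/2 bivariate\n"
    "REML fits; the PCA route replaces them with m independent univariate\n"
    "fits that converge in a few iterations each."
)
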