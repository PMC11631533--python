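"""The full PCA evaluation pipeline versus multivariate BLUP.

Simulates six correlated traits, runs the fast route (PCA -> independent
per-PC univariate REML/BLUP -> back-transformation -> selection index) and
compares its ranking against a full multivariate BLUP at the true
covariances.
"""

import warnings

import numpy as np

from pcablup import (
    SimulationConfig,
    back_transform,
    compare_rankings,
    evaluate_pcs,
    fit_multitrait,
    fit_svd_pca,
    selection_index,
    simulate_pedigree,
    simulate_traits,
)
from pcablup.simulate import random_psd_covariance

warnings.simplefilter("ignore")

m = 6
h2 = np.full(m, 0.3)
G0 = random_psd_covariance(m, h2, seed=201)
R0 = random_psd_covariance(m, 1 - h2, seed=301)
cfg = SimulationConfig(
    founders=40, generations=2, families_per_generation=45,
    offspring_per_family=8, trait_means=np.zeros(m), G0=G0, R0=R0, seed=1,
)
ped = simulate_pedigree(cfg)
tm, _ = simulate_traits(ped, cfg)
print(f"simulated {len(ped)} individuals x {m} traits (mean h2 = 0.3)")

# fast route: PCA + independent univariate evaluations
model = fit_svd_pca(tm)
print("PC variance explained:", np.round(model.explained * 100, 1), "%")
ebv_pc, comps, _ = evaluate_pcs(model, ped, algorithm="ai")
print("per-PC h2:", [round(c.h2, 2) for c in comps])
g_pca = back_transform(ebv_pc, model)

# reference route: multivariate BLUP with the true covariances
mv = fit_multitrait(tm, ped, G0, R0)

weights = {t: 1 / m for t in tm.trait_names}
idx_pca = selection_index(g_pca, list(ped.ids), tm.trait_names, weights)
idx_mv = selection_index(mv.ebv, list(ped.ids), tm.trait_names, weights)
cmp_ = compare_rankings(idx_mv, idx_pca, k=50)
print(f"index concordance: Pearson r = {cmp_.pearson_r:.3f} over {len(ped)} "
      f"candidates")
print(f"top-50 agreement: Kendall tau = {cmp_.tau:.3f} "
      f"(p = {cmp_.tau_pvalue:.2g}), overlap = {cmp_.overlap}/50")
print(
    "The per-PC route treats each component as an independent trait; the\n"
    "high index correlation shows selection decisions carry over from the\n"
    "expensive multivariate analysis to the fast PCA route."
)
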