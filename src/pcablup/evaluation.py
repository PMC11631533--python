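"""Per-component genetic evaluation, back-transformation and selection.

Principal-component scores are evaluated as independent univariate animal
models; the resulting component breeding values G_ebv (one column per PC)
are mapped back to the original trait scale by

    G_orig = G_ebv @ loadings' * scale + center,

which is exact (no information loss) when as many components as traits are
kept.  Selection indices are signed weighted sums of (optionally
standardized) trait-scale breeding values, and candidate rankings are
compared by Kendall's tau-b over the reference top-k, Pearson correlation
over all candidates, and top-k set overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import (
    AnimalModelFit,
    ConvergenceWarning,
    ModelDesign,
    VarianceComponents,
    reml_univariate,
)
from .pca import PCAModel
from .pedigree import Pedigree, additive_relationship, relationship_inverse


def evaluate_pcs(
    model: PCAModel,
    ped: Pedigree,
    algorithm: str = "ai",
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, list[VarianceComponents | None], list[AnimalModelFit | None]]:
    """Independent univariate REML+BLUP for every principal component.

    Returns the n_ped x p matrix of component EBVs (all pedigree members),
    the per-component variance components (heritability with Taylor SD),
    and the per-component fits.  A zero-variance score column is skipped
    with a warning and its EBV column zeroed.
    """
    scores = model.scores
    n_pc = scores.shape[1]
    A = additive_relationship(ped).values
    Ainv = relationship_inverse(ped)
    ebv = np.zeros((len(ped), n_pc))
    comps: list[VarianceComponents | None] = []
    fits: list[AnimalModelFit | None] = []
    for k in range(n_pc):
        col = scores[:, k]
        if np.var(col) < 1e-14:
            warnings.warn(
                f"PC {k + 1} has zero variance; skipping its evaluation",
                RuntimeWarning,
            )
            comps.append(None)
            fits.append(None)
            continue
        design = ModelDesign.from_phenotypes(model.ids, col, ped)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            vc, fit = reml_univariate(
                design, ped, algorithm=algorithm, max_iter=max_iter, tol=tol,
                A=A, Ainv=Ainv,
            )
        ebv[:, k] = fit.ebv
        comps.append(vc)
        fits.append(fit)
    return ebv, comps, fits


def back_transform(g_ebv: np.ndarray, model: PCAModel) -> np.ndarray:
    """Map component breeding values back to the original trait scale.

    G_orig = G_ebv @ loadings' * scale + center.  With p = m the round trip
    through :meth:`PCAModel.transform` is exact.
    """
    g_ebv = np.atleast_2d(np.asarray(g_ebv, float))
    p = model.n_components
    if g_ebv.shape[1] != p:
        raise ValueError(
            f"G_ebv has {g_ebv.shape[1]} columns but the model has {p} components"
        )
    return g_ebv @ model.loadings.T * model.scale + model.center


@dataclass(frozen=True)
class SelectionIndex:
    """Weighted ranking of selection candidates."""

    ids: tuple[str, ...]
    trait_names: tuple[str, ...]
    weights: np.ndarray  # aligned with trait_names, |weights| sums to 1
    values: np.ndarray
    ranks: np.ndarray  # 1 = best; permutation of 1..n
    standardized: bool

    def top(self, k: int) -> tuple[str, ...]:
        order = np.argsort(self.ranks)
        return tuple(np.asarray(self.ids, dtype=object)[order][:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.ids), "index": self.values, "rank": self.ranks}
        )


def selection_index(
    g_orig: np.ndarray,
    ids: Sequence[str],
    trait_names: Sequence[str],
    weights: Mapping[str, float],
    standardize: bool = True,
) -> SelectionIndex:
    """Signed weighted combination of trait-scale breeding values.

    Weights are given by trait name (unknown names error); their absolute
    values are normalized to sum to 1.  With ``standardize`` each trait
    column is mean-centered and scaled to unit variance before weighting
    (traits are usually on incommensurate scales); ``standardize=False``
    uses the raw columns.  Ranks are descending in index value with ties
    broken by id for determinism.
    """
    g = np.atleast_2d(np.asarray(g_orig, float))
    names = list(trait_names)
    unknown = [t for t in weights if t not in names]
    if unknown:
        raise KeyError(f"unknown trait names in weights: {unknown}")
    w = np.array([float(weights.get(t, 0.0)) for t in names])
    total = np.abs(w).sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    w = w / total
    cols = g.copy()
    if standardize:
        mu = cols.mean(axis=0)
        sd = cols.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        cols = (cols - mu) / sd
    vals = cols @ w
    order = sorted(range(len(ids)), key=lambda i: (-vals[i], str(ids[i])))
    ranks = np.empty(len(ids), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return SelectionIndex(
        ids=tuple(str(i) for i in ids),
        trait_names=tuple(names),
        weights=w,
        values=vals,
        ranks=ranks,
        standardized=standardize,
    )


def pc_index_contribution(
    model: PCAModel,
    ebv_variances: Sequence[float],
    weights: Mapping[str, float] | np.ndarray,
) -> np.ndarray:
    """Share of the selection-index variance attributable to each PC.

    Treating the per-PC EBVs as uncorrelated, the index variance splits as
    share_k proportional to (w' lambda_k)^2 * Var(g_k); shares are >= 0 and
    sum to 1.
    """
    p = model.n_components
    v = np.asarray(list(ebv_variances), float)
    if v.size != p:
        raise ValueError("need one EBV variance per component")
    if isinstance(weights, Mapping):
        w = np.array([float(weights.get(t, 0.0)) for t in model.trait_names])
    else:
        w = np.asarray(weights, float)
    raw = (w @ model.loadings) ** 2 * v
    total = raw.sum()
    if total <= 0:
        raise ValueError("all component contributions are zero")
    return raw / total


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided p-value.

    The p-value uses exact enumeration for n <= 10 without ties and the
    tie-adjusted normal approximation otherwise (null: true tau = 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Kendall tau is undefined for a constant vector")
    ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    method = "exact" if (x.size <= 10 and not ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RankComparison:
    tau: float
    tau_pvalue: float
    pearson_r: float
    r_pvalue: float
    overlap: int
    k: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": self.tau,
                "tau_pvalue": self.tau_pvalue,
                "pearson_r": self.pearson_r,
                "r_pvalue": self.r_pvalue,
                "overlap": self.overlap,
                "k": self.k,
            }
        )


def compare_rankings(
    reference: SelectionIndex, candidate: SelectionIndex, k: int = 50
) -> RankComparison:
    """Concordance between a reference and a candidate candidate ranking.

    Pearson r is computed over all individuals' index values; Kendall tau-b
    over the *reference* top-k individuals' ranks in both full lists
    (membership defined by the reference method); overlap is the size of the
    intersection of the two top-k sets.
    """
    if set(reference.ids) != set(candidate.ids):
        raise ValueError("reference and candidate must rank the same individuals")
    n = len(reference.ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    cand_pos = {i: j for j, i in enumerate(candidate.ids)}
    perm = [cand_pos[i] for i in reference.ids]
    r, r_p = stats.pearsonr(reference.values, candidate.values[perm])
    top_ref = reference.top(k)
    ref_rank = {i: reference.ranks[j] for j, i in enumerate(reference.ids)}
    cand_rank = {i: candidate.ranks[cand_pos[i]] for i in reference.ids}
    tau, tau_p = kendall_tau(
        [ref_rank[i] for i in top_ref], [cand_rank[i] for i in top_ref]
    )
    overlap = len(set(top_ref) & set(candidate.top(k)))
    return RankComparison(
        tau=tau, tau_pvalue=tau_p, pearson_r=float(r), r_pvalue=float(r_p),
        overlap=overlap, k=k,
    )


def write_index(index: SelectionIndex, path: str | Path) -> None:
    index.to_frame().to_csv(path, index=False)


def read_index(path: str | Path) -> SelectionIndex:
    df = pd.read_csv(path, dtype={"id": str})
    vals = df["index"].to_numpy(float)
    ranks = df["rank"].to_numpy(int)
    return SelectionIndex(
        ids=tuple(df["id"]),
        trait_names=(),
        weights=np.array([]),
        values=vals,
        ranks=ranks,
        standardized=False,
    )
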