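"""Trait-matrix handling, SVD-based PCA and Bayesian model-based PCA.

The phenotype container is an n individuals x m traits matrix with an
explicit missingness mask.  Two imputation routes are provided: trait-mean
baseline and a variational Bayesian PCA (BPCA) in which the principal-axis
matrix is split into observed and missing coordinate blocks, factor scores
are regressed on the observed coordinates and missing cells are predicted
as ``y_miss = W_miss x``.  The SVD route gives exact loadings, eigenvalues
and scores for complete data, plus the loading diagnostics used downstream
(per-trait contributions, Ward/Euclidean clustering, Mantel comparison of
loading-distance matrices).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel


class TraitMatrixError(ValueError):
    pass


@dataclass(frozen=True)
class TraitMatrix:
    """Phenotype matrix with NaN-encoded missing cells."""

    values: np.ndarray  # n x m, float, NaN = missing
    ids: tuple[str, ...]
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "trait_names", tuple(str(t) for t in self.trait_names))
        if v.ndim != 2 or v.shape != (len(self.ids), len(self.trait_names)):
            raise TraitMatrixError("values shape does not match ids/trait_names")
        if len(set(self.ids)) != len(self.ids):
            raise TraitMatrixError("duplicate individual ids")
        if v.shape[0] < 2 or v.shape[1] < 1:
            raise TraitMatrixError("need at least 2 individuals and 1 trait")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(self.mask.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.trait_names))


def read_traits(path: str | Path) -> TraitMatrix:
    """Read a delimited phenotype table: first column ``id``, one column per
    trait; empty cells or "NA" are missing."""
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA", ""])
    if df.columns[0].strip().lower() != "id":
        raise TraitMatrixError("first column of a phenotype file must be 'id'")
    ids = df.iloc[:, 0].astype(str).tolist()
    traits = [c.strip() for c in df.columns[1:]]
    return TraitMatrix(df.iloc[:, 1:].to_numpy(dtype=float), tuple(ids), tuple(traits))


def write_traits(tm: TraitMatrix, path: str | Path) -> None:
    df = tm.to_frame()
    df.insert(0, "id", list(tm.ids))
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# filtering and baseline imputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterReport:
    removed_traits: tuple[tuple[str, float], ...]
    removed_individuals: tuple[tuple[str, float], ...]


def filter_missing(
    tm: TraitMatrix,
    trait_threshold: float = 0.40,
    individual_threshold: float = 0.25,
) -> tuple[TraitMatrix, FilterReport]:
    """Drop traits, then individuals, that are too incomplete.

    Traits whose missing fraction is strictly above ``trait_threshold`` are
    removed first; individuals whose missing fraction over the *remaining*
    traits is strictly above ``individual_threshold`` are removed second.
    """
    for thr in (trait_threshold, individual_threshold):
        if not (0.0 < thr <= 1.0):
            raise ValueError("thresholds must lie in (0, 1]")
    mask = tm.mask
    trait_frac = mask.mean(axis=0)
    keep_t = trait_frac <= trait_threshold
    removed_traits = tuple(
        (tm.trait_names[j], float(trait_frac[j])) for j in np.where(~keep_t)[0]
    )
    if not keep_t.any():
        raise TraitMatrixError("all traits removed by the trait filter")
    vals = tm.values[:, keep_t]
    ind_frac = np.isnan(vals).mean(axis=1)
    keep_i = ind_frac <= individual_threshold
    removed_inds = tuple(
        (tm.ids[i], float(ind_frac[i])) for i in np.where(~keep_i)[0]
    )
    if keep_i.sum() < 2:
        raise TraitMatrixError("fewer than 2 individuals left after filtering")
    out = TraitMatrix(
        vals[keep_i],
        tuple(np.asarray(tm.ids, dtype=object)[keep_i]),
        tuple(np.asarray(tm.trait_names, dtype=object)[keep_t]),
    )
    return out, FilterReport(removed_traits, removed_inds)


def impute_mean(tm: TraitMatrix) -> TraitMatrix:
    """Replace every missing cell by its trait's observed mean."""
    vals = tm.values.copy()
    mask = np.isnan(vals)
    if mask.all(axis=0).any():
        j = int(np.where(mask.all(axis=0))[0][0])
        raise TraitMatrixError(
            f"trait {tm.trait_names[j]!r} has no observed values; filter it first"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(vals, axis=0)
    vals[mask] = np.broadcast_to(means, vals.shape)[mask]
    return TraitMatrix(vals, tm.ids, tm.trait_names)


# ---------------------------------------------------------------------------
# SVD PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAModel:
    """Principal components of a complete trait matrix.

    ``loadings`` (m x p) has orthonormal columns; ``eigenvalues`` are sample
    variances of the scores (denominator n-1), non-increasing; ``center``
    and ``scale`` record the transformation so that back-transformation to
    the trait scale is exact.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    scores: np.ndarray
    explained: np.ndarray
    ids: tuple[str, ...]
    trait_names: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, float) - self.center) / self.scale @ self.loadings

    def save(self, path: str | Path) -> None:
        payload = {
            "trait_names": list(self.trait_names),
            "ids": list(self.ids),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "scores": self.scores.tolist(),
            "explained": self.explained.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            loadings=np.array(d["loadings"]),
            eigenvalues=np.array(d["eigenvalues"]),
            center=np.array(d["center"]),
            scale=np.array(d["scale"]),
            scores=np.array(d["scores"]),
            explained=np.array(d["explained"]),
            ids=tuple(d["ids"]),
            trait_names=tuple(d["trait_names"]),
        )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: make the largest-magnitude loading in
    each column positive; ties broken by the earliest trait."""
    out = loadings.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        j = int(np.argmax(np.abs(col)))  # argmax takes the first maximum
        if col[j] < 0:
            out[:, k] = -col
    return out


def fit_svd_pca(
    tm: TraitMatrix,
    center: bool = True,
    scale: bool = False,
    p: int | None = None,
) -> PCAModel:
    """SVD-based PCA of a complete trait matrix.

    Eigenvalues are the sample variances of the scores (denominator n-1);
    with ``p = m`` the reconstruction ``scores @ loadings' * scale + center``
    is exact.  Centering defaults on, scaling off.
    """
    Y = tm.values
    if np.isnan(Y).any():
        raise TraitMatrixError("fit_svd_pca requires a complete matrix; impute first")
    n, m = Y.shape
    mu = Y.mean(axis=0) if center else np.zeros(m)
    if scale:
        s = Y.std(axis=0, ddof=1)
        if np.any(s == 0):
            j = int(np.where(s == 0)[0][0])
            raise TraitMatrixError(
                f"trait {tm.trait_names[j]!r} has zero variance; cannot scale"
            )
    else:
        s = np.ones(m)
    Z = (Y - mu) / s
    U, sv, Vt = np.linalg.svd(Z, full_matrices=False)
    p_eff = min(n, m) if p is None else int(p)
    if not (1 <= p_eff <= min(n, m)):
        raise ValueError(f"p must be in [1, {min(n, m)}]")
    lam_all = sv**2 / (n - 1)
    total_var = Z.var(axis=0, ddof=1).sum()
    loadings = _fix_signs(Vt.T[:, :p_eff])
    scores = Z @ loadings
    lam = lam_all[:p_eff]
    explained = lam / total_var if total_var > 0 else np.zeros_like(lam)
    return PCAModel(
        loadings=loadings,
        eigenvalues=lam,
        center=mu,
        scale=s,
        scores=scores,
        explained=explained,
        ids=tm.ids,
        trait_names=tm.trait_names,
    )


# ---------------------------------------------------------------------------
# Bayesian model-based PCA with missing-cell prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BPCAFit:
    """Variational BPCA fit: principal axes, factor scores, imputed matrix."""

    W: np.ndarray  # m x q principal axes (scaled, not orthonormal)
    X: np.ndarray  # n x q posterior-mean factor scores
    mu: np.ndarray
    residual_variance: float
    imputed: TraitMatrix
    iterations: int
    converged: bool


def fit_bpca(
    tm: TraitMatrix,
    q: int,
    max_steps: int = 10_000,
    threshold: float = 1e-6,
    seed: int | None = None,
) -> BPCAFit:
    """Fit Bayesian model-based PCA and impute missing cells.

    The model is ``y_i = W x_i + mu + eps`` with isotropic residual
    precision tau and an automatic-relevance prior on the columns of W.
    Each step (i) regresses factor scores on the observed coordinates of
    each row using the observed block of W, (ii) predicts the missing
    cells as ``W_miss x_i``, and (iii) updates axes, mean and variances.
    Convergence is declared when the relative change of the imputed matrix
    (Frobenius norm), together with the relative change of W, drops below
    ``threshold``.  Observed cells are never modified.
    """
    Y = tm.values
    n, m = Y.shape
    if not (1 <= q < min(n, m)):
        raise ValueError(f"q must satisfy 1 <= q < min(n, m) = {min(n, m)}")
    mask = np.isnan(Y)
    if mask.all(axis=0).any() or mask.all(axis=1).any():
        raise TraitMatrixError(
            "every individual and every trait must have at least one observation"
        )
    del seed  # algorithm is deterministic; kept for interface stability

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(Y, axis=0)
    Yfill = np.where(mask, mu, Y)

    # spectral initialisation on the mean-imputed covariance
    C = np.cov(Yfill, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    W = evecs[:, :q] * np.sqrt(np.maximum(evals[:q], 1e-12))
    resid = evals[q:].sum() / max(m - q, 1)
    tau = 1.0 / max(resid, 1e-12)
    tau = min(tau, 1e10)
    alpha = np.ones(q)

    # group rows by missingness pattern so E-steps vectorise
    pattern_keys = [tuple(np.where(row)[0]) for row in mask]
    groups: dict[tuple[int, ...], list[int]] = {}
    for i, key in enumerate(pattern_keys):
        groups.setdefault(key, []).append(i)

    Ximp = Yfill.copy()
    X = np.zeros((n, q))
    converged = False
    it = 0
    for it in range(1, max_steps + 1):
        W_old = W
        Ximp_old = Ximp.copy()
        A = np.zeros((m, q))  # sum E[(y_i - mu) x_i']
        B = np.zeros((q, q))  # sum E[x_i x_i']
        sse = 0.0
        for miss_idx, rows in groups.items():
            rows_a = np.array(rows)
            miss = np.array(miss_idx, dtype=int)
            obs = np.setdiff1d(np.arange(m), miss)
            Wo = W[obs]
            Ci = np.linalg.inv(np.eye(q) + tau * (Wo.T @ Wo))
            dyo = Y[np.ix_(rows_a, obs)] - mu[obs]
            Xg = tau * dyo @ Wo @ Ci  # r x q scores
            X[rows_a] = Xg
            if miss.size:
                pred = Xg @ W[miss].T + mu[miss]
                Ximp[np.ix_(rows_a, miss)] = pred
            r = len(rows)
            B += r * Ci + Xg.T @ Xg
            dy_full = Ximp[rows_a] - mu
            A += dy_full.T @ Xg
            if miss.size:
                # E[(y_miss - mu) x'] carries the posterior-score covariance
                A[miss] += r * (W[miss] @ Ci)
            res_o = dyo - Xg @ Wo.T
            sse += float((res_o**2).sum()) + r * float(
                np.trace(Wo @ Ci @ Wo.T)
            )
            if miss.size:
                Wm = W[miss]
                sse += r * (miss.size / tau + float(np.trace(Wm @ Ci @ Wm.T)))
        W = A @ np.linalg.inv(B + np.diag(alpha) / tau)
        mu = (Ximp - X @ W.T).mean(axis=0)
        tau = min((n * m) / max(sse, 1e-300), 1e10)
        alpha = np.minimum(m / (np.sum(W**2, axis=0) + 1e-12), 1e10)

        denom = max(float(np.linalg.norm(Ximp_old)), 1e-12)
        d_imp = float(np.linalg.norm(Ximp - Ximp_old)) / denom
        d_w = float(np.linalg.norm(W - W_old)) / max(float(np.linalg.norm(W_old)), 1e-12)
        if max(d_imp, d_w) < threshold:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"BPCA did not converge within {max_steps} steps "
            f"(last relative change {max(d_imp, d_w):.2e})",
            RuntimeWarning,
        )

    imputed_vals = np.where(mask, Ximp, Y)  # observed cells exactly preserved
    return BPCAFit(
        W=W,
        X=X,
        mu=mu,
        residual_variance=1.0 / tau,
        imputed=TraitMatrix(imputed_vals, tm.ids, tm.trait_names),
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# loading diagnostics
# ---------------------------------------------------------------------------


def trait_contributions(model: PCAModel, k: int) -> np.ndarray:
    """Percent contribution of each trait to component k (1-based):
    100 * loading^2, summing to 100 by orthonormality."""
    if not (1 <= k <= model.n_components):
        raise ValueError(f"component k must be in [1, {model.n_components}]")
    col = model.loadings[:, k - 1]
    return 100.0 * col**2


@dataclass(frozen=True)
class LoadingClusters:
    linkage: np.ndarray  # scipy hierarchical merge tree over traits
    labels: tuple[int, ...]  # flat cluster label per trait at the requested k
    trait_names: tuple[str, ...]


def cluster_loadings(
    model: PCAModel, components_used: int | None = None, k_clusters: int = 2
) -> LoadingClusters:
    """Ward/Euclidean agglomerative clustering of the trait loading rows."""
    p = model.n_components if components_used is None else int(components_used)
    if p > model.n_components:
        raise ValueError("components_used exceeds the number of components")
    rows = model.loadings[:, :p]
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 traits to cluster")
    Z = sch.linkage(rows, method="ward", metric="euclidean")
    labels = sch.fcluster(Z, t=k_clusters, criterion="maxclust")
    return LoadingClusters(Z, tuple(int(v) for v in labels), model.trait_names)


def mantel_loadings(
    model_a: PCAModel,
    model_b: PCAModel,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test between the trait-distance structures of two PCA models.

    Euclidean distances between loading rows are computed for each model and
    compared by the Pearson-correlation Mantel statistic; the p-value is
    one-sided (greater) from permutation of the trait labels of one matrix.
    """
    if model_a.trait_names != model_b.trait_names:
        raise ValueError("models must share the same trait set and order")
    da = squareform(pdist(model_a.loadings))
    db = squareform(pdist(model_b.loadings))
    names = list(model_a.trait_names)
    if seed is not None:
        np.random.seed(seed % (2**32))
    r, p, _ = _skbio_mantel(
        DistanceMatrix(da, names),
        DistanceMatrix(db, names),
        method="pearson",
        permutations=permutations,
        alternative="greater",
    )
    return float(r), float(p)
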