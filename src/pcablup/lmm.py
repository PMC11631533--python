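"""Pedigree animal models: Henderson's MME, REML variance components, BLUP.

The univariate animal model is  y = Xb + Za + e  with a ~ N(0, A sigma_a^2)
over pedigree members and e ~ N(0, I sigma_e^2).  Restricted maximum
likelihood runs in the eigenspace of H = Z A Z': after rotating the data by
the eigenvectors of H the marginal covariance is diagonal, so each EM or
average-information (AI) iteration costs O(n p^2) instead of a sparse solve.
EM is the reference algorithm (its restricted log-likelihood is monotone by
construction); AI is the accelerator, falling back to EM steps whenever a
proposed update leaves the parameter space or decreases the likelihood.

The multitrait model stacks m traits with covariances G0 (x) A (genetic) and
R0 (x) I (residual).  Two REML paths are provided: a fast spectral path for
complete data (rows decouple into m x m blocks in the eigenbasis of H) and a
Henderson-MME path with dense information blocks for data with per-trait
missingness (small problems).  The staged evaluation mirrors common breeding
practice for many traits: univariate fits for starting values, pairwise
bivariate fits to fill G0/R0, then one multitrait BLUP with the assembled
covariances held fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pca import TraitMatrix
from .pedigree import Pedigree, additive_relationship, relationship_inverse

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-10


class ConvergenceWarning(RuntimeWarning):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelDesign:
    """Response, fixed-effects design, and observation-to-pedigree mapping."""

    y: np.ndarray  # n_obs
    X: np.ndarray  # n_obs x p, full column rank
    obs_to_ped: np.ndarray  # n_obs indices into the pedigree
    n_ped: int

    def __post_init__(self) -> None:
        y = np.asarray(self.y, float).ravel()
        X = np.atleast_2d(np.asarray(self.X, float))
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of observations")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effects design X is rank deficient")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "obs_to_ped", np.asarray(self.obs_to_ped, np.int64))

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def Z(self) -> sp.csr_matrix:
        n = self.n_obs
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.obs_to_ped)), shape=(n, self.n_ped)
        )

    @classmethod
    def from_phenotypes(
        cls,
        ids: Sequence[str],
        values: Sequence[float],
        ped: Pedigree,
        X: np.ndarray | None = None,
    ) -> "ModelDesign":
        """Build an intercept-only design from (id, value) records, dropping
        missing values and mapping ids into the pedigree."""
        vals = np.asarray(values, float)
        keep = ~np.isnan(vals)
        kept_ids = [str(i) for i, k in zip(ids, keep) if k]
        missing = [i for i in kept_ids if i not in ped.index]
        if missing:
            raise ValueError(f"phenotyped ids not in pedigree: {missing[:5]}")
        idx = np.array([ped.index[i] for i in kept_ids], dtype=np.int64)
        y = vals[keep]
        if X is None:
            X = np.ones((y.size, 1))
        else:
            X = np.atleast_2d(np.asarray(X, float))[keep]
        return cls(y=y, X=X, obs_to_ped=idx, n_ped=len(ped))


@dataclass(frozen=True)
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    sd_a2: float
    sd_e2: float
    sd_total: float  # SD of sigma_a2 + sigma_e2
    h2: float
    h2_sd: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma_a2": self.sigma_a2,
            "sigma_e2": self.sigma_e2,
            "sd_a2": self.sd_a2,
            "sd_e2": self.sd_e2,
            "sd_total": self.sd_total,
            "h2": self.h2,
            "h2_sd": self.h2_sd,
        }


@dataclass(frozen=True)
class AnimalModelFit:
    fixed_effects: np.ndarray
    ebv: np.ndarray  # one entry per pedigree member (phenotyped or not)
    loglik: float
    trace: tuple[tuple[float, float, float], ...]  # (sigma_a2, sigma_e2, logLR)
    converged: bool
    boundary: bool = False
    ids: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class MultiTraitFit:
    G0: np.ndarray
    R0: np.ndarray
    ebv: np.ndarray  # n_ped x m
    fixed_effects: np.ndarray  # p x m
    loglik: float | None
    iterations: int
    converged: bool
    ids: tuple[str, ...] = field(default=())
    trait_names: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class StageReport:
    univariate_iterations: tuple[int, ...]
    univariate_converged: tuple[bool, ...]
    bivariate_pairs: tuple[tuple[int, int], ...]
    bivariate_iterations: tuple[int, ...]
    bivariate_converged: tuple[bool, ...]
    bending_applied: bool

    @property
    def n_bivariate(self) -> int:
        return len(self.bivariate_pairs)


# ---------------------------------------------------------------------------
# Henderson mixed-model equations (BLUP at fixed variances)
# ---------------------------------------------------------------------------


def _solve_possibly_singular(M: sp.spmatrix, rhs: np.ndarray) -> np.ndarray:
    """Sparse solve; on singularity add a logged ridge and continue."""
    M = sp.csc_matrix(M)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            lu = spla.splu(M)
            sol = lu.solve(rhs)
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("non-finite MME solution")
        return sol
    except (RuntimeError, Warning):
        ridge = 1e-8 * float(M.diagonal().sum()) / M.shape[0]
        logger.warning("near-singular coefficient matrix: adding ridge %.3e", ridge)
        M2 = M + ridge * sp.identity(M.shape[0], format="csc")
        return spla.splu(M2).solve(rhs)


def solve_mme(
    design: ModelDesign,
    Ainv: sp.spmatrix,
    sigma_a2: float,
    sigma_e2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """BLUE/BLUP solutions of Henderson's mixed-model equations.

    Coefficient matrix [[X'X, X'Z], [Z'X, Z'Z + alpha A^-1]] with
    alpha = sigma_e2 / sigma_a2.  Returns (b_hat, a_hat) where a_hat covers
    every pedigree member, phenotyped or not.
    """
    if sigma_a2 <= 0:
        raise ValueError(
            "sigma_a2 must be positive; for sigma_a2 -> 0 the model reduces "
            "to ordinary least squares on X"
        )
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    alpha = sigma_e2 / sigma_a2
    X, Z, y = sp.csr_matrix(design.X), design.Z, design.y
    top = sp.hstack([X.T @ X, X.T @ Z])
    bottom = sp.hstack([Z.T @ X, Z.T @ Z + alpha * sp.csr_matrix(Ainv)])
    M = sp.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = _solve_possibly_singular(M, rhs)
    p = design.X.shape[1]
    return sol[:p], sol[p:]


# ---------------------------------------------------------------------------
# univariate REML in the eigenspace of H = Z A Z'
# ---------------------------------------------------------------------------


class _Spectral:
    """Rotated data for a single-trait animal model."""

    def __init__(self, design: ModelDesign, A: np.ndarray):
        Z = design.Z.toarray()
        H = Z @ A @ Z.T
        s, U = np.linalg.eigh((H + H.T) / 2)
        self.s = np.clip(s, 0.0, None)
        self.yt = U.T @ design.y
        self.Xt = U.T @ design.X
        self.n = design.n_obs
        self.p = design.X.shape[1]

    def _weights(self, sa: float, se: float) -> np.ndarray:
        return sa * self.s + se

    def gls(self, sa: float, se: float):
        w = self._weights(sa, se)
        Xw = self.Xt / w[:, None]
        info = self.Xt.T @ Xw
        omega = np.linalg.inv(info)
        beta = omega @ (Xw.T @ self.yt)
        resid = self.yt - self.Xt @ beta
        return w, omega, beta, resid, info

    def loglik(self, sa: float, se: float) -> float:
        w, omega, beta, resid, info = self.gls(sa, se)
        ypy = float(resid @ (resid / w))
        sign, logdet_info = np.linalg.slogdet(info)
        return -0.5 * (float(np.log(w).sum()) + logdet_info + ypy)

    def applyP(self, v: np.ndarray, w: np.ndarray, omega: np.ndarray) -> np.ndarray:
        vw = v / w
        return vw - (self.Xt / w[:, None]) @ (omega @ (self.Xt.T @ vw))

    def em_step(self, sa: float, se: float) -> tuple[float, float]:
        w, omega, beta, resid, _ = self.gls(sa, se)
        gamma = sa * self.s / w
        xox = np.einsum("rp,pq,rq->r", self.Xt, omega, self.Xt)
        ghat = gamma * resid
        pos = self.s > _EIG_FLOOR
        e_g2 = ghat**2 + sa * self.s * (1 - gamma) + gamma**2 * xox
        sa_new = float((e_g2[pos] / self.s[pos]).mean()) if pos.any() else sa
        ehat = (se / w) * resid
        e_e2 = ehat**2 + sa * self.s * se / w + (se / w) ** 2 * xox
        se_new = float(e_e2.mean())
        return sa_new, se_new

    def score_and_ai(self, sa: float, se: float):
        w, omega, beta, resid, _ = self.gls(sa, se)
        Py = resid / w  # P y in the eigenbasis
        XtW = self.Xt / w[:, None]
        corr_s = np.einsum("rp,pq,rq->", XtW * self.s[:, None], omega, XtW)
        corr_i = np.einsum("rp,pq,rq->", XtW, omega, XtW)
        trPH = float((self.s / w).sum()) - corr_s
        trP = float((1.0 / w).sum()) - corr_i
        yPHPy = float(Py @ (self.s * Py))
        yPPy = float(Py @ Py)
        score = np.array([-0.5 * (trPH - yPHPy), -0.5 * (trP - yPPy)])
        va, ve = self.s * Py, Py
        Pva = self.applyP(va, w, omega)
        Pve = self.applyP(ve, w, omega)
        ai = 0.5 * np.array(
            [[va @ Pva, va @ Pve], [ve @ Pva, ve @ Pve]]
        )
        return score, ai


def reml_univariate(
    design: ModelDesign,
    ped: Pedigree,
    algorithm: str = "em",
    start: tuple[float, float] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    loglik_tol: float = 1e-6,
    A: np.ndarray | None = None,
    Ainv: sp.spmatrix | None = None,
) -> tuple[VarianceComponents, AnimalModelFit]:
    """Univariate animal-model REML plus BLUP of all pedigree members.

    ``algorithm`` is "em" (reference; restricted log-likelihood non-decreasing
    at every step) or "ai" (average information with EM fallback).  Variance
    estimates are clamped at 1e-8 * var(y) and the boundary is flagged.
    Standard deviations of the components come from the inverse average-
    information matrix at convergence; heritability uses the Taylor-series
    ratio approximation (:func:`heritability_se`).
    """
    if design.n_obs <= design.X.shape[1] + 1:
        raise ValueError("too few observations for REML")
    if algorithm not in {"em", "ai"}:
        raise ValueError("algorithm must be 'em' or 'ai'")
    if A is None:
        A = additive_relationship(ped).values
    spec = _Spectral(design, A)
    vy = float(np.var(design.y, ddof=1))
    floor = 1e-8 * vy
    sa, se = start if start is not None else (vy / 2, vy / 2)
    sa, se = max(sa, floor), max(se, floor)
    trace: list[tuple[float, float, float]] = []
    ll = spec.loglik(sa, se)
    trace.append((sa, se, ll))
    converged = False
    for _ in range(max_iter):
        if algorithm == "ai" and len(trace) > 3:
            score, ai = spec.score_and_ai(sa, se)
            try:
                step = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                step = None
            if step is not None:
                cand = np.array([sa, se]) + step
                if np.all(cand > floor):
                    ll_cand = spec.loglik(*cand)
                    if ll_cand >= ll - 1e-10:
                        sa_new, se_new = float(cand[0]), float(cand[1])
                        ll_new = ll_cand
                    else:
                        sa_new, se_new = spec.em_step(sa, se)
                        ll_new = None
                else:
                    sa_new, se_new = spec.em_step(sa, se)
                    ll_new = None
            else:
                sa_new, se_new = spec.em_step(sa, se)
                ll_new = None
        else:
            sa_new, se_new = spec.em_step(sa, se)
            ll_new = None
        sa_new, se_new = max(sa_new, floor), max(se_new, floor)
        if ll_new is None:
            ll_new = spec.loglik(sa_new, se_new)
        rel = max(abs(sa_new - sa) / max(sa, floor), abs(se_new - se) / max(se, floor))
        dll = abs(ll_new - ll)
        sa, se, ll = sa_new, se_new, ll_new
        trace.append((sa, se, ll))
        if rel < tol and dll < loglik_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations "
            f"(last relative change {rel:.2e})",
            ConvergenceWarning,
        )
    boundary = bool(sa <= floor * (1 + 1e-6) or se <= floor * (1 + 1e-6))

    _, ai = spec.score_and_ai(sa, se)
    try:
        cov = np.linalg.inv(ai)
        sd_a = float(np.sqrt(max(cov[0, 0], 0.0)))
        sd_e = float(np.sqrt(max(cov[1, 1], 0.0)))
        sd_t = float(np.sqrt(max(cov.sum(), 0.0)))
    except np.linalg.LinAlgError:
        sd_a = sd_e = sd_t = float("nan")
    h2, h2_sd = heritability_se(sa, se, sd_a, sd_t)
    vc = VarianceComponents(sa, se, sd_a, sd_e, sd_t, h2, h2_sd)

    if Ainv is None:
        Ainv = relationship_inverse(ped)
    b_hat, a_hat = solve_mme(design, Ainv, sa, se)
    fit = AnimalModelFit(
        fixed_effects=b_hat,
        ebv=a_hat,
        loglik=ll,
        trace=tuple(trace),
        converged=converged,
        boundary=boundary,
        ids=ped.ids,
    )
    return vc, fit


def heritability_se(
    sigma_a2: float,
    sigma_e2: float,
    sd_a2: float,
    sd_total: float,
) -> tuple[float, float]:
    """Narrow-sense heritability and its first-order Taylor-series SD.

    For the ratio C = A/B with A = sigma_a2 and B = sigma_a2 + sigma_e2, and
    assuming no covariation between A and B,

        SD(C) = (A/B) * sqrt( (SD(A)/A)^2 + (SD(B)/B)^2 ).
    """
    total = sigma_a2 + sigma_e2
    if sigma_a2 <= 0 or total <= 0:
        raise ValueError("variance components must be positive")
    h2 = sigma_a2 / total
    h2_sd = h2 * float(np.sqrt((sd_a2 / sigma_a2) ** 2 + (sd_total / total) ** 2))
    return h2, h2_sd


# ---------------------------------------------------------------------------
# multitrait REML: spectral path (complete data)
# ---------------------------------------------------------------------------


def _multitrait_em_complete(
    Y: np.ndarray,
    X: np.ndarray,
    A_obs: np.ndarray,
    G0: np.ndarray,
    R0: np.ndarray,
    max_iter: int,
    tol: float,
    loglik_tol: float,
):
    """EM-REML for m complete traits in the eigenbasis of H = A_obs."""
    n, m = Y.shape
    p = X.shape[1]
    s, U = np.linalg.eigh((A_obs + A_obs.T) / 2)
    s = np.clip(s, 0.0, None)
    Yt, Xt = U.T @ Y, U.T @ X
    pos = s > _EIG_FLOOR
    n_pos = int(pos.sum())
    eye_m = np.eye(m)

    def iterate(G0, R0):
        Sig = s[:, None, None] * G0 + R0  # (n, m, m)
        Sinv = np.linalg.inv(Sig)
        info = np.einsum("rjk,rp,rq->jpkq", Sinv, Xt, Xt).reshape(m * p, m * p)
        omega = np.linalg.inv(info)
        rhs = np.einsum("rjk,rk,rp->jp", Sinv, Yt, Xt).reshape(m * p)
        beta = (omega @ rhs).reshape(m, p)  # beta[j] = coefs for trait j
        B = beta.T  # p x m
        resid = Yt - Xt @ B
        sign, logdet_info = np.linalg.slogdet(info)
        ypy = float(np.einsum("rj,rjk,rk->", resid, Sinv, resid))
        ll = -0.5 * (
            float(np.linalg.slogdet(Sig)[1].sum()) + logdet_info + ypy
        )
        # E-step moments
        omega_t = omega.reshape(m, p, m, p)
        Mr = np.einsum("jpkq,rp,rq->rjk", omega_t, Xt, Xt)  # Var from beta-hat
        K = s[:, None, None] * np.einsum("jk,rkl->rjl", G0, Sinv)
        ghat = np.einsum("rjk,rk->rj", K, resid)
        condv = s[:, None, None] * G0 - np.einsum("rjk,kl->rjl", K, G0) * s[
            :, None, None
        ]
        KM = np.einsum("rjk,rkl,rml->rjm", K, Mr, K)
        Egg = np.einsum("rj,rk->rjk", ghat, ghat) + condv + KM
        G0_new = (Egg[pos] / s[pos, None, None]).mean(axis=0) if n_pos else G0
        RS = np.einsum("jk,rkl->rjl", R0, Sinv)
        ehat = np.einsum("rjk,rk->rj", RS, resid)
        RM = np.einsum("rjk,rkl,rml->rjm", RS, Mr, RS)
        Eee = (
            np.einsum("rj,rk->rjk", ehat, ehat)
            + (R0[None] - np.einsum("rjk,kl->rjl", RS, R0))
            + RM
        )
        R0_new = Eee.mean(axis=0)
        G0_new = (G0_new + G0_new.T) / 2
        R0_new = (R0_new + R0_new.T) / 2
        return G0_new, R0_new, ll, B, ghat

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        G0_new, R0_new, ll, B, ghat = iterate(G0, R0)
        rel = max(
            float(np.max(np.abs(G0_new - G0)) / max(np.max(np.abs(G0)), 1e-12)),
            float(np.max(np.abs(R0_new - R0)) / max(np.max(np.abs(R0)), 1e-12)),
        )
        G0, R0 = G0_new, R0_new
        if rel < tol and abs(ll - ll_prev) < loglik_tol and it > 1:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    # final GLS / EBVs on the observed block (caller extends to full pedigree)
    _, _, ll, B, ghat = iterate(G0, R0)
    ghat_obs = U @ ghat  # back to the observation basis
    return G0, R0, ll, B, ghat_obs, it, converged


# ---------------------------------------------------------------------------
# multitrait REML: MME path (per-trait missingness, small n)
# ---------------------------------------------------------------------------


def _stack_design(
    Y: np.ndarray,
    X: np.ndarray,
    obs_to_ped: np.ndarray,
    n_ped: int,
):
    """Row-index bookkeeping for the stacked multitrait data vector."""
    n, m = Y.shape
    p = X.shape[1]
    entries = []  # (individual row, trait)
    for i in range(n):
        for j in range(m):
            if not np.isnan(Y[i, j]):
                entries.append((i, j))
    return entries, n, m, p


def _multitrait_em_missing(
    Y: np.ndarray,
    X: np.ndarray,
    obs_to_ped: np.ndarray,
    A: np.ndarray,
    Ainv_dense: np.ndarray,
    G0: np.ndarray,
    R0: np.ndarray,
    max_iter: int,
    tol: float,
    loglik_tol: float,
):
    """EM-REML via Henderson MME with dense inverse blocks.

    Handles arbitrary per-trait missingness; intended for small problems
    (the coefficient matrix is inverted densely each iteration).
    """
    n, m = Y.shape
    p = X.shape[1]
    q = A.shape[0]
    dim = m * p + m * q
    obs_sets = [np.where(~np.isnan(Y[i]))[0] for i in range(n)]
    sign_A, logdet_A = np.linalg.slogdet(A)

    def build_and_invert(G0, R0):
        G0inv = np.linalg.inv(G0)
        C = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        ypy_dir = 0.0
        logdet_R = 0.0
        rows_T = []  # per individual: (row indices into theta, Rinv block, y block)
        for i, o in enumerate(obs_sets):
            if o.size == 0:
                rows_T.append(None)
                continue
            Ri = R0[np.ix_(o, o)]
            Rinv = np.linalg.inv(Ri)
            logdet_R += float(np.linalg.slogdet(Ri)[1])
            yi = Y[i, o]
            # theta layout: [beta (m*p) | u trait-major (m*q)]
            cols = []
            for j in o:
                cols.append(np.concatenate([
                    np.arange(j * p, (j + 1) * p),  # beta for trait j
                    [m * p + j * q + obs_to_ped[i]],
                ]))
            # design row for (i, trait j): X[i] on beta_j, 1 on u_{j, ped(i)}
            Ti = np.zeros((o.size, dim))
            for a, j in enumerate(o):
                Ti[a, j * p : (j + 1) * p] = X[i]
                Ti[a, m * p + j * q + obs_to_ped[i]] = 1.0
            C += Ti.T @ Rinv @ Ti
            rhs += Ti.T @ (Rinv @ yi)
            ypy_dir += float(yi @ Rinv @ yi)
            rows_T.append((Ti, Rinv, yi, o))
        Gblock = np.kron(G0inv, Ainv_dense)
        C[m * p :, m * p :] += Gblock
        theta = np.linalg.solve(C, rhs)
        Cinv = np.linalg.inv(C)
        ypy = ypy_dir - float(rhs @ theta)
        sign, logdet_C = np.linalg.slogdet(C)
        logdet_G = q * float(np.linalg.slogdet(G0)[1]) + m * logdet_A
        ll = -0.5 * (logdet_R + logdet_G + logdet_C + ypy)
        return theta, Cinv, ll, rows_T

    ll_prev = -np.inf
    converged = False
    it = 0
    theta = np.zeros(dim)
    for it in range(1, max_iter + 1):
        theta, Cinv, ll, rows_T = build_and_invert(G0, R0)
        U = theta[m * p :].reshape(m, q)  # EBVs trait-major
        # G0 update: (u_j' Ainv u_l + tr(Ainv Cuu[j,l])) / q
        G0_new = np.zeros((m, m))
        for j in range(m):
            for l in range(j, m):
                blk = Cinv[
                    m * p + j * q : m * p + (j + 1) * q,
                    m * p + l * q : m * p + (l + 1) * q,
                ]
                val = float(U[j] @ Ainv_dense @ U[l]) + float(
                    np.sum(Ainv_dense * blk.T)
                )
                G0_new[j, l] = G0_new[l, j] = val / q
        # R0 update via conditional moments for missing traits
        acc = np.zeros((m, m))
        for i, pack in enumerate(rows_T):
            if pack is None:
                continue
            Ti, Rinv, yi, o = pack
            ehat = yi - Ti @ theta
            Moo = np.outer(ehat, ehat) + Ti @ Cinv @ Ti.T
            mset = np.setdiff1d(np.arange(m), o)
            E = np.zeros((m, m))
            E[np.ix_(o, o)] = Moo
            if mset.size:
                P = R0[np.ix_(mset, o)] @ np.linalg.inv(R0[np.ix_(o, o)])
                E[np.ix_(mset, o)] = P @ Moo
                E[np.ix_(o, mset)] = E[np.ix_(mset, o)].T
                schur = R0[np.ix_(mset, mset)] - P @ R0[np.ix_(o, mset)]
                E[np.ix_(mset, mset)] = schur + P @ Moo @ P.T
            acc += E
        R0_new = acc / n
        G0_new = (G0_new + G0_new.T) / 2
        R0_new = (R0_new + R0_new.T) / 2
        rel = max(
            float(np.max(np.abs(G0_new - G0)) / max(np.max(np.abs(G0)), 1e-12)),
            float(np.max(np.abs(R0_new - R0)) / max(np.max(np.abs(R0)), 1e-12)),
        )
        G0, R0 = G0_new, R0_new
        if rel < tol and abs(ll - ll_prev) < loglik_tol and it > 1:
            converged = True
            break
        ll_prev = ll
    theta, Cinv, ll, _ = build_and_invert(G0, R0)
    beta = theta[: m * p].reshape(m, p).T
    ebv = theta[m * p :].reshape(m, q).T  # q x m
    return G0, R0, ll, beta, ebv, it, converged


# ---------------------------------------------------------------------------
# public multitrait interfaces
# ---------------------------------------------------------------------------


def _map_traits_to_pedigree(tm: TraitMatrix, ped: Pedigree) -> np.ndarray:
    missing = [i for i in tm.ids if i not in ped.index]
    if missing:
        raise ValueError(f"phenotyped ids not in pedigree: {missing[:5]}")
    return np.array([ped.index[i] for i in tm.ids], dtype=np.int64)


def reml_multitrait(
    tm: TraitMatrix,
    ped: Pedigree,
    start: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    loglik_tol: float = 1e-6,
    X: np.ndarray | None = None,
) -> MultiTraitFit:
    """Joint m-trait EM-REML; complete data uses the spectral path,
    per-trait missingness the Henderson-MME path (small problems only)."""
    Y = tm.values
    n, m = Y.shape
    obs_to_ped = _map_traits_to_pedigree(tm, ped)
    if X is None:
        X = np.ones((n, 1))
    A = additive_relationship(ped).values
    if start is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanvar(Y, axis=0, ddof=1)
        G0 = np.diag(v / 2)
        R0 = np.diag(v / 2)
    else:
        G0, R0 = np.array(start[0], float), np.array(start[1], float)
    complete = not np.isnan(Y).any()
    if complete:
        A_obs = A[np.ix_(obs_to_ped, obs_to_ped)]
        G0, R0, ll, B, ghat_obs, it, conv = _multitrait_em_complete(
            Y, X, A_obs, G0, R0, max_iter, tol, loglik_tol
        )
        ebv = _extend_ebv_to_pedigree(ghat_obs, obs_to_ped, ped, A, G0, R0, X, Y, B)
    else:
        Ainv_dense = np.linalg.inv(A)
        G0, R0, ll, B, ebv, it, conv = _multitrait_em_missing(
            Y, X, obs_to_ped, A, Ainv_dense, G0, R0, max_iter, tol, loglik_tol
        )
    if not conv:
        warnings.warn(
            f"multitrait REML did not converge in {max_iter} iterations",
            ConvergenceWarning,
        )
    return MultiTraitFit(
        G0=G0, R0=R0, ebv=ebv, fixed_effects=B, loglik=ll,
        iterations=it, converged=conv, ids=ped.ids, trait_names=tm.trait_names,
    )


def _extend_ebv_to_pedigree(ghat_obs, obs_to_ped, ped, A, G0, R0, X, Y, B):
    """Replace spectral-path genetic predictions with the exact stacked-MME
    BLUP over the full pedigree at the converged (G0, R0)."""
    del ghat_obs, A, B  # the MME solve recomputes exact BLUPs
    _, ebv = _fit_multitrait_arrays(Y, X, obs_to_ped, ped, G0, R0)
    return ebv


def reml_bivariate(
    tm: TraitMatrix,
    ped: Pedigree,
    start: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    loglik_tol: float = 1e-6,
) -> MultiTraitFit:
    """Two-trait REML (genetic and residual covariance of a trait pair)."""
    if tm.values.shape[1] != 2:
        raise ValueError("reml_bivariate expects exactly 2 traits")
    both = ~np.isnan(tm.values).any(axis=1)
    if both.sum() >= 3:
        common = tm.values[both]
        if np.allclose(common[:, 0], common[:, 1], atol=1e-12):
            raise ValueError(
                "the two responses are identical on every shared individual; "
                "the residual covariance matrix is degenerate"
            )
    return reml_multitrait(tm, ped, start=start, max_iter=max_iter, tol=tol,
                           loglik_tol=loglik_tol)


def assemble_covariance(
    univariate: Sequence[VarianceComponents],
    pairwise: Mapping[tuple[int, int], MultiTraitFit],
    m: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fill G0/R0 from univariate diagonals and pairwise covariances.

    All m(m-1)/2 pairs must be present.  If either assembled matrix is not
    positive semi-definite its eigenvalues are clipped at 1e-6 of the largest
    ("bending"); the repair is logged and flagged in the returned bool.
    """
    if len(univariate) != m:
        raise ValueError("need one univariate fit per trait")
    needed = set(combinations(range(m), 2))
    have = {tuple(sorted(k)) for k in pairwise}
    missing = sorted(needed - have)
    if missing:
        raise ValueError(f"missing pairwise fits for trait pairs: {missing}")
    G0 = np.diag([vc.sigma_a2 for vc in univariate]).astype(float)
    R0 = np.diag([vc.sigma_e2 for vc in univariate]).astype(float)
    for (i, j), fit in pairwise.items():
        i, j = sorted((i, j))
        G0[i, j] = G0[j, i] = fit.G0[0, 1]
        R0[i, j] = R0[j, i] = fit.R0[0, 1]
    bent = False
    out = []
    for name, M in (("G0", G0), ("R0", R0)):
        evals, evecs = np.linalg.eigh(M)
        floor = 1e-6 * float(evals.max())
        if evals.min() < 0:
            bent = True
            logger.warning(
                "%s not PSD (min eigenvalue %.3e); bending eigenvalues to %.3e",
                name, evals.min(), floor,
            )
            M = evecs @ np.diag(np.clip(evals, floor, None)) @ evecs.T
            M = (M + M.T) / 2
        out.append(M)
    return out[0], out[1], bent


def _fit_multitrait_arrays(
    Y: np.ndarray,
    X: np.ndarray,
    obs_to_ped: np.ndarray,
    ped: Pedigree,
    G0: np.ndarray,
    R0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked sparse MME BLUP at fixed (G0, R0); missing cells allowed.

    Returns (fixed effects p x m, EBV matrix n_ped x m)."""
    n, m = Y.shape
    p = X.shape[1]
    q = len(ped)
    cond = np.linalg.cond(G0)
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-8 * float(np.trace(G0)) / m
        logger.warning("G0 singular or near-singular; adding ridge %.3e", ridge)
        G0 = G0 + ridge * np.eye(m)
    G0inv = np.linalg.inv(G0)
    Ainv = relationship_inverse(ped)
    dim = m * p + m * q
    rows, cols, vals = [], [], []
    rhs = np.zeros(dim)

    def add_block(r_idx, c_idx, block):
        for a, r in enumerate(r_idx):
            for b, c in enumerate(c_idx):
                v = block[a, b]
                if v != 0.0:
                    rows.append(r)
                    cols.append(c)
                    vals.append(v)

    for i in range(n):
        o = np.where(~np.isnan(Y[i]))[0]
        if o.size == 0:
            continue
        Rinv = np.linalg.inv(R0[np.ix_(o, o)])
        yi = Y[i, o]
        k = obs_to_ped[i]
        idx = []
        basis = []  # each observed trait contributes X[i] on beta_j and 1 on u
        for j in o:
            idx.append((j, k))
        # T' Rinv T over the compact coordinate set:
        # coordinates: for each observed trait j -> [beta_j (p), u_{j,k} (1)]
        coords = []
        for j in o:
            coords.append(list(range(j * p, (j + 1) * p)) + [m * p + j * q + k])
        xi = X[i]
        Tloc = np.zeros((o.size, o.size * (p + 1)))
        flat_coords = []
        for a, j in enumerate(o):
            Tloc[a, a * (p + 1) : a * (p + 1) + p] = xi
            Tloc[a, a * (p + 1) + p] = 1.0
            flat_coords.extend(coords[a])
        block = Tloc.T @ Rinv @ Tloc
        add_block(flat_coords, flat_coords, block)
        rhs_local = Tloc.T @ (Rinv @ yi)
        for c, v in zip(flat_coords, rhs_local):
            rhs[c] += v
    C = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsc()
    # add the G-inverse block at offset m*p
    Gblk = sp.kron(sp.csc_matrix(G0inv), sp.csc_matrix(Ainv), format="coo")
    Gblk = sp.coo_matrix(
        (Gblk.data, (Gblk.row + m * p, Gblk.col + m * p)), shape=(dim, dim)
    )
    C = (C + Gblk.tocsc()).tocsc()
    sol = _solve_possibly_singular(C, rhs)
    beta = sol[: m * p].reshape(m, p).T
    ebv = sol[m * p :].reshape(m, q).T
    return beta, ebv


def fit_multitrait(
    tm: TraitMatrix,
    ped: Pedigree,
    G0: np.ndarray,
    R0: np.ndarray,
    X: np.ndarray | None = None,
) -> MultiTraitFit:
    """Multitrait BLUP with fixed covariance matrices G0 and R0.

    Solves the stacked mixed-model equations with genetic covariance
    G0 (x) A and residual covariance R0 (x) I restricted to observed cells;
    no variance re-estimation takes place.  With m = 1 this reduces exactly
    to :func:`solve_mme`.
    """
    G0 = np.atleast_2d(np.asarray(G0, float))
    R0 = np.atleast_2d(np.asarray(R0, float))
    Y = tm.values
    m = Y.shape[1]
    if G0.shape != (m, m) or R0.shape != (m, m):
        raise ValueError("G0/R0 dimensions do not match the trait count")
    obs_to_ped = _map_traits_to_pedigree(tm, ped)
    if X is None:
        X = np.ones((Y.shape[0], 1))
    beta, ebv = _fit_multitrait_arrays(Y, X, obs_to_ped, ped, G0, R0)
    return MultiTraitFit(
        G0=G0, R0=R0, ebv=ebv, fixed_effects=beta, loglik=None,
        iterations=0, converged=True, ids=ped.ids, trait_names=tm.trait_names,
    )


def staged_multitrait_evaluation(
    tm: TraitMatrix,
    ped: Pedigree,
    algorithm: str = "em",
    bivariate_max_iter: int = 200,
    bivariate_tol: float = 1e-6,
    univariate_max_iter: int = 1000,
) -> tuple[MultiTraitFit, StageReport]:
    """Three-stage multitrait evaluation for many traits.

    (a) univariate REML per trait for starting values, (b) pairwise
    bivariate REML of all m(m-1)/2 trait combinations to fill G0 and R0,
    (c) one multitrait BLUP with the assembled (bent if necessary)
    covariance matrices held fixed.
    """
    Y = tm.values
    m = Y.shape[1]
    if m < 2:
        raise ValueError("staged evaluation needs at least 2 traits")
    A = additive_relationship(ped).values
    Ainv = relationship_inverse(ped)
    uni: list[VarianceComponents] = []
    uni_iters, uni_conv = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(m):
            try:
                design = ModelDesign.from_phenotypes(tm.ids, Y[:, j], ped)
                vc, fit = reml_univariate(
                    design, ped, algorithm=algorithm, A=A, Ainv=Ainv,
                    max_iter=univariate_max_iter,
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"stage a (univariate REML) failed for trait "
                    f"{tm.trait_names[j]!r}: {exc}"
                ) from exc
            uni.append(vc)
            uni_iters.append(len(fit.trace) - 1)
            uni_conv.append(fit.converged)
        pair_fits: dict[tuple[int, int], MultiTraitFit] = {}
        pair_iters, pair_conv = [], []
        pairs = list(combinations(range(m), 2))
        for i, j in pairs:
            sub = TraitMatrix(
                Y[:, [i, j]], tm.ids, (tm.trait_names[i], tm.trait_names[j])
            )
            g_start = np.array(
                [[uni[i].sigma_a2, 0.0], [0.0, uni[j].sigma_a2]]
            )
            r_start = np.array(
                [[uni[i].sigma_e2, 0.0], [0.0, uni[j].sigma_e2]]
            )
            try:
                fit = reml_bivariate(
                    sub, ped, start=(g_start, r_start),
                    max_iter=bivariate_max_iter, tol=bivariate_tol,
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"stage b (bivariate REML) failed for pair "
                    f"({tm.trait_names[i]}, {tm.trait_names[j]}): {exc}"
                ) from exc
            pair_fits[(i, j)] = fit
            pair_iters.append(fit.iterations)
            pair_conv.append(fit.converged)
    G0, R0, bent = assemble_covariance(uni, pair_fits, m)
    try:
        final = fit_multitrait(tm, ped, G0, R0)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage c (multitrait BLUP) failed: {exc}") from exc
    report = StageReport(
        univariate_iterations=tuple(uni_iters),
        univariate_converged=tuple(uni_conv),
        bivariate_pairs=tuple(pairs),
        bivariate_iterations=tuple(pair_iters),
        bivariate_converged=tuple(pair_conv),
        bending_applied=bent,
    )
    return final, report


def count_bivariate_fits(m: int) -> int:
    """Number of pairwise bivariate analyses the staged procedure schedules."""
    return m * (m - 1) // 2
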