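"""Synthetic pedigrees and multitrait phenotypes for method validation.

Phenotypes follow the additive animal model: breeding-value rows are drawn
recursively down the pedigree (founders ~ MVN(0, G0); offspring receive the
parent average plus a Mendelian-sampling deviation with covariance
(1/2)(1 - (F_sire + F_dam)/2) G0), residual rows are MVN(0, R0), and
Y = mu + a + e.  Missingness is applied completely at random (MCAR), the
only mechanism modelled.  Scenario presets echo two forest-tree breeding
designs: a Scots pine progeny trial (controlled crosses among seed-orchard
parents, 15 or 10 traits, ~13% missing cells in the larger subset) and a
Loblolly pine breeding population (controlled crosses of 32 parents, 26
traits), both scaled down to at most ~600 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .pca import TraitMatrix
from .pedigree import Pedigree, inbreeding_coefficients


@dataclass(frozen=True)
class SimulationConfig:
    founders: int
    generations: int
    families_per_generation: int
    offspring_per_family: int
    trait_means: np.ndarray
    G0: np.ndarray
    R0: np.ndarray
    missing_rate: float = 0.0
    mechanism: str = "MCAR"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trait_means", np.asarray(self.trait_means, float))
        for name in ("G0", "R0"):
            M = np.atleast_2d(np.asarray(getattr(self, name), float))
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
            object.__setattr__(self, name, M)
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing rate must be in [0, 1)")
        if self.mechanism != "MCAR":
            raise ValueError("only MCAR missingness is implemented")
        if min(self.founders, self.generations, self.families_per_generation,
               self.offspring_per_family) < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "founders": self.founders,
            "generations": self.generations,
            "families_per_generation": self.families_per_generation,
            "offspring_per_family": self.offspring_per_family,
            "trait_means": self.trait_means.tolist(),
            "G0": self.G0.tolist(),
            "R0": self.R0.tolist(),
            "missing_rate": self.missing_rate,
            "mechanism": self.mechanism,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree of random full-sib families.

    Generation 0 holds the founders; each later generation consists of
    ``families_per_generation`` random sire x dam pairs drawn from the
    previous generation, each producing ``offspring_per_family`` offspring.
    """
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str | None, str | None]] = []
    previous = [f"G0_{i + 1}" for i in range(config.founders)]
    if len(previous) < 2 and config.generations > 1:
        raise ValueError("need at least 2 founders to form matings")
    records.extend((ind, None, None) for ind in previous)
    for g in range(1, config.generations):
        if len(previous) < 2:
            raise ValueError(f"generation {g - 1} too small to form matings")
        current: list[str] = []
        for fam in range(config.families_per_generation):
            sire, dam = rng.choice(previous, size=2, replace=False)
            for o in range(config.offspring_per_family):
                ind = f"G{g}_F{fam + 1}_{o + 1}"
                records.append((ind, str(sire), str(dam)))
                current.append(ind)
        previous = current
    return Pedigree.from_records(records)


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix (exact zeros preserved)."""
    evals, evecs = np.linalg.eigh(M)
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_traits(
    ped: Pedigree, config: SimulationConfig
) -> tuple[TraitMatrix, np.ndarray]:
    """Phenotypes and true breeding values under the additive model.

    Returns a complete TraitMatrix ``Y = mu + a + e`` and the n x m matrix of
    true breeding values ``a``, ordered like the pedigree.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = config.n_traits
    n = len(ped)
    Lg = _psd_factor(config.G0)
    Lr = _psd_factor(config.R0)
    F = inbreeding_coefficients(ped)
    a = np.zeros((n, m))
    z = rng.standard_normal((n, m))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a[i] = Lg @ z[i]
        else:
            mid = np.zeros(m)
            if s >= 0:
                mid += 0.5 * a[s]
            if d >= 0:
                mid += 0.5 * a[d]
            Fs = F[s] if s >= 0 else 0.0
            Fd = F[d] if d >= 0 else 0.0
            if s >= 0 and d >= 0:
                dvar = 0.5 * (1.0 - 0.5 * (Fs + Fd))
            else:
                dvar = 0.75 - 0.25 * (Fs if s >= 0 else Fd)
            a[i] = mid + np.sqrt(dvar) * (Lg @ z[i])
    e = rng.standard_normal((n, m)) @ Lr.T
    Y = config.trait_means + a + e
    tm = TraitMatrix(Y, ped.ids, tuple(f"trait_{j + 1}" for j in range(m)))
    return tm, a


def apply_missingness(
    tm: TraitMatrix, rate: float, mechanism: str = "MCAR", seed: int = 0
) -> TraitMatrix:
    """Mask each cell independently with probability ``rate`` (MCAR)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if mechanism != "MCAR":
        raise ValueError("only MCAR missingness is implemented")
    if rate == 0.0:
        return tm
    rng = np.random.default_rng(seed)
    for attempt in range(2):
        mask = rng.random(tm.values.shape) < rate
        mask &= ~tm.mask  # already-missing cells stay missing
        full = tm.mask | mask
        if not full.all(axis=0).any():
            vals = tm.values.copy()
            vals[mask] = np.nan
            return TraitMatrix(vals, tm.ids, tm.trait_names)
    raise ValueError("missingness rate empties an entire trait")


def _block_covariance(
    h2: np.ndarray,
    blocks: Sequence[Sequence[int]],
    within: float,
    between: float,
    genetic: bool,
) -> np.ndarray:
    """Block-structured covariance: traits in the same biological block are
    more strongly correlated than traits across blocks."""
    m = h2.size
    C = np.full((m, m), between)
    for blk in blocks:
        for i in blk:
            for j in blk:
                C[i, j] = within
    np.fill_diagonal(C, 1.0)
    evals = np.linalg.eigvalsh(C)
    if evals.min() < 1e-8:  # mild shrink toward identity if needed
        lam = max(0.0, (1e-6 - evals.min()) / (1.0 - evals.min()))
        C = (1 - lam) * C + lam * np.eye(m)
    v = h2 if genetic else (1.0 - h2)
    D = np.sqrt(v)
    return D[:, None] * C * D[None, :]


_SCOTS_SMALL_H2 = np.array(
    [0.077, 0.120, 0.242, 0.047, 0.236, 0.372, 0.131, 0.382,
     0.479, 0.112, 0.262, 0.573, 0.390, 0.084, 0.110]
)
_SCOTS_LARGE_H2 = np.array(
    [0.147, 0.208, 0.041, 0.320, 0.347, 0.191, 0.249, 0.369, 0.323, 0.147]
)
_LOBLOLLY_H2 = np.array(
    [0.337, 0.500, 0.544, 0.646, 0.589, 0.570, 0.538, 0.424, 0.510,
     0.223, 0.546, 0.553, 0.409, 0.558, 0.456, 0.087, 0.269, 0.116,
     0.157, 0.190, 0.177, 0.190, 0.114, 0.165, 0.087, 0.318]
)


def scenario_presets(name: str, seed: int = 0) -> SimulationConfig:
    """Named scaled-down study designs.

    - ``scots-small``: complete 15-trait progeny-trial subset.
    - ``scots-large``: 10 traits with 13.3% MCAR missing cells.
    - ``loblolly``: 26 traits from controlled crosses of 32 parents.

    Each preset keeps the published per-trait narrow-sense heritabilities
    (unit phenotypic variance, so sigma_a2 = h2 and sigma_e2 = 1 - h2) and a
    production/quality block correlation structure; population sizes are
    scaled to at most ~600 individuals.
    """
    if name == "scots-small":
        h2 = _SCOTS_SMALL_H2
        # production traits: growth measures; quality: branching/stem form
        blocks = [[0, 1, 2, 9, 10, 11, 12], [3, 4, 5, 6, 7, 8, 13, 14]]
        G0 = _block_covariance(h2, blocks, 0.6, 0.1, genetic=True)
        R0 = _block_covariance(h2, blocks, 0.3, 0.05, genetic=False)
        return SimulationConfig(
            founders=40, generations=2, families_per_generation=28,
            offspring_per_family=20, trait_means=np.zeros(h2.size),
            G0=G0, R0=R0, missing_rate=0.0, seed=seed,
        )
    if name == "scots-large":
        h2 = _SCOTS_LARGE_H2
        blocks = [[0, 1, 5, 6, 7, 8], [2, 3, 4, 9]]
        G0 = _block_covariance(h2, blocks, 0.6, 0.1, genetic=True)
        R0 = _block_covariance(h2, blocks, 0.3, 0.05, genetic=False)
        return SimulationConfig(
            founders=40, generations=2, families_per_generation=28,
            offspring_per_family=20, trait_means=np.zeros(h2.size),
            G0=G0, R0=R0, missing_rate=0.133, seed=seed,
        )
    if name == "loblolly":
        h2 = _LOBLOLLY_H2
        production = [0, 1, 2, 3, 4, 5, 6, 7, 10, 11, 12, 13, 14, 15, 16]
        quality = [8, 9, 22, 23, 24, 25]
        disease = [17, 18, 19, 20, 21]
        blocks = [production, quality, disease]
        G0 = _block_covariance(h2, blocks, 0.5, 0.1, genetic=True)
        R0 = _block_covariance(h2, blocks, 0.25, 0.05, genetic=False)
        return SimulationConfig(
            founders=32, generations=2, families_per_generation=28,
            offspring_per_family=20, trait_means=np.zeros(h2.size),
            G0=G0, R0=R0, missing_rate=0.10, seed=seed,
        )
    raise ValueError(
        f"unknown preset {name!r}; choose scots-small, scots-large or loblolly"
    )


def random_psd_covariance(
    m: int, variances: np.ndarray | float = 1.0, seed: int = 0
) -> np.ndarray:
    """Random PSD covariance with the requested diagonal (for simulations)."""
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((m, m + 2))
    C = W @ W.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    v = np.broadcast_to(np.asarray(variances, float), (m,))
    s = np.sqrt(v)
    return s[:, None] * C * s[None, :]


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    rows = []
    for i, ind in enumerate(ped.ids):
        s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0"
        d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0"
        rows.append((ind, s, d))
    pd.DataFrame(rows, columns=["id", "sire", "dam"]).to_csv(path, index=False)


def write_truth(ped: Pedigree, true_bv: np.ndarray, trait_names: Sequence[str],
                path: str | Path) -> None:
    """Long-format truth file id,trait,true_bv for recovery tests."""
    recs = [
        (ped.ids[i], trait_names[j], true_bv[i, j])
        for i in range(true_bv.shape[0])
        for j in range(true_bv.shape[1])
    ]
    pd.DataFrame(recs, columns=["id", "trait", "true_bv"]).to_csv(path, index=False)
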