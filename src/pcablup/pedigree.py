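"""Pedigree parsing and additive-relationship algebra.

A pedigree is an ordered list of (individual, sire, dam) trios; unknown
parents are permitted.  From it we derive inbreeding coefficients F, the
additive (numerator) relationship matrix A by the tabular recursion

    a_ij = 1/2 (a_j,sire(i) + a_j,dam(i)),    a_ii = 1 + 1/2 a_sire(i),dam(i),

and the sparse inverse of A directly from pedigree structure using
Henderson's rules with Mendelian-sampling variances
d_i = 1/2 - 1/4 (F_sire + F_dam) (terms for unknown parents dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: parent codes treated as "unknown" by default; breeding-program file
#: dialects vary, so the set is configurable in :func:`read_pedigree`.
DEFAULT_UNKNOWN_CODES = frozenset({"0", "", "NA", "."})

#: pedigree size above which inbreeding switches from the O(n^2)-memory
#: tabular method to the Meuwissen–Luo ancestor-tracing algorithm.
_TABULAR_LIMIT = 2000


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclass(frozen=True)
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    ids : list of str
        Individual identifiers in topological order (parents before
        offspring).  Ids are opaque strings.
    sire, dam : ndarray of int
        0-based positional index of each individual's parents in ``ids``;
        ``-1`` encodes an unknown parent.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            object.__setattr__(self, "index", {i: k for k, i in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire < 0) & (self.dam < 0)))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build a pedigree from (id, sire-or-None, dam-or-None) trios.

        Parents that never appear as individuals are auto-promoted to
        founders (logged).  Records may arrive in any order; the result is
        topologically sorted, so every known parent precedes its offspring.
        """
        recs = [(str(i), s, d) for i, s, d in records]
        seen: set[str] = set()
        for ind, _, _ in recs:
            if ind in seen:
                raise PedigreeError(f"duplicate individual id: {ind!r}")
            seen.add(ind)
        for ind, s, d in recs:
            if s is not None and s == ind:
                raise PedigreeError(f"individual {ind!r} listed as its own sire")
            if d is not None and d == ind:
                raise PedigreeError(f"individual {ind!r} listed as its own dam")
        promoted = []
        for _, s, d in list(recs):
            for parent in (s, d):
                if parent is not None and parent not in seen:
                    recs.append((parent, None, None))
                    seen.add(parent)
                    promoted.append(parent)
        if promoted:
            logger.info(
                "auto-promoted %d undeclared parents to founders: %s",
                len(promoted),
                ", ".join(promoted[:10]) + ("..." if len(promoted) > 10 else ""),
            )

        # Kahn topological sort, stable in input order so that re-reading the
        # same file yields the same internal ordering.
        parents = {ind: [p for p in (s, d) if p is not None] for ind, s, d in recs}
        children: dict[str, list[str]] = {ind: [] for ind, _, _ in recs}
        indeg = {ind: 0 for ind, _, _ in recs}
        for ind, ps in parents.items():
            for p in ps:
                children[p].append(ind)
                indeg[ind] += 1
        order: list[str] = []
        ready = [ind for ind, _, _ in recs if indeg[ind] == 0]
        while ready:
            nxt = ready.pop(0)
            order.append(nxt)
            for ch in children[nxt]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    ready.append(ch)
        if len(order) != len(recs):
            cycle = sorted(ind for ind, deg in indeg.items() if deg > 0)
            raise PedigreeError(
                "pedigree contains a cycle (individuals that are their own "
                f"ancestors): {', '.join(cycle)}"
            )
        pos = {ind: k for k, ind in enumerate(order)}
        by_id = {ind: (s, d) for ind, s, d in recs}
        sire = np.array(
            [pos[by_id[i][0]] if by_id[i][0] is not None else -1 for i in order],
            dtype=np.int64,
        )
        dam = np.array(
            [pos[by_id[i][1]] if by_id[i][1] is not None else -1 for i in order],
            dtype=np.int64,
        )
        return cls(ids=tuple(order), sire=sire, dam=dam)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Dense additive relationship matrix with row/column ids.

    ``values`` is symmetric PSD with ``diag = 1 + F`` (founders exactly 1).
    """

    values: np.ndarray
    ids: tuple[str, ...]

    def to_triplets(self) -> pd.DataFrame:
        """Lower-triangle ``row_id, col_id, value`` triplet export."""
        rows, cols = np.tril_indices(len(self.ids))
        return pd.DataFrame(
            {
                "row_id": [self.ids[r] for r in rows],
                "col_id": [self.ids[c] for c in cols],
                "value": self.values[rows, cols],
            }
        )


def read_pedigree(
    path: str | Path,
    unknown_codes: Sequence[str] | frozenset[str] = DEFAULT_UNKNOWN_CODES,
) -> Pedigree:
    """Read a delimited pedigree file with header columns id, sire, dam.

    Comma or tab delimiters are autodetected.  Parent entries matching
    ``unknown_codes`` (default ``{"0", "", "NA", "."}``) become unknown.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    required = ["id", "sire", "dam"]
    if cols[:3] != required:
        raise PedigreeError(
            f"pedigree file must start with header columns {required}, got {cols[:3]}"
        )
    codes = set(unknown_codes)

    def clean(v: str) -> str | None:
        v = v.strip()
        return None if v in codes else v

    records = [
        (row[0].strip(), clean(row[1]), clean(row[2]))
        for row in df.itertuples(index=False)
    ]
    return Pedigree.from_records(records)


def _mendelian_variance(ped: Pedigree, F: np.ndarray, use_inbreeding: bool) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance d_i for each individual."""
    Fs = np.where(ped.sire >= 0, F[np.maximum(ped.sire, 0)], 0.0)
    Fd = np.where(ped.dam >= 0, F[np.maximum(ped.dam, 0)], 0.0)
    if not use_inbreeding:
        Fs = np.zeros_like(Fs)
        Fd = np.zeros_like(Fd)
    d = np.ones(len(ped))
    both = (ped.sire >= 0) & (ped.dam >= 0)
    one_s = (ped.sire >= 0) & (ped.dam < 0)
    one_d = (ped.sire < 0) & (ped.dam >= 0)
    d[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    d[one_s] = 0.75 - 0.25 * Fs[one_s]
    d[one_d] = 0.75 - 0.25 * Fd[one_d]
    return d


def _inbreeding_tabular(ped: Pedigree) -> np.ndarray:
    return np.diag(additive_relationship(ped).values) - 1.0


def _inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    """Ancestor-tracing inbreeding (Meuwissen–Luo), O(n * ancestry depth).

    Uses A = T D T': the diagonal a_ii is the d-weighted squared gene-flow
    row of i, accumulated by walking i's ancestry once.
    """
    n = len(ped)
    F = np.zeros(n)
    sire, dam = ped.sire, ped.dam
    d_cache = np.ones(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        ds = 0.0 if s < 0 else F[s]
        dd = 0.0 if dm < 0 else F[dm]
        if s >= 0 and dm >= 0:
            d_cache[i] = 0.5 - 0.25 * (ds + dd)
        elif s >= 0 or dm >= 0:
            d_cache[i] = 0.75 - 0.25 * (ds if s >= 0 else dd)
        if s < 0 or dm < 0:
            F[i] = 0.0
            continue
        # a_ii = sum_j L_ij^2 d_j over i's ancestry (including i itself)
        L: dict[int, float] = {i: 1.0}
        a_ii = 0.0
        for j in range(i, -1, -1):
            c = L.pop(j, 0.0)
            if c == 0.0:
                continue
            a_ii += c * c * d_cache[j]
            if sire[j] >= 0:
                L[sire[j]] = L.get(sire[j], 0.0) + 0.5 * c
            if dam[j] >= 0:
                L[dam[j]] = L.get(dam[j], 0.0) + 0.5 * c
        F[i] = a_ii - 1.0
    return F


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F per individual, in pedigree order.

    F_i is half the additive relationship of i's parents; founders and
    offspring of unknown x unknown matings have F = 0.  Small pedigrees go
    through the tabular method; large ones through Meuwissen–Luo ancestor
    tracing (the two agree on overlapping sizes).
    """
    if len(ped) <= _TABULAR_LIMIT:
        return _inbreeding_tabular(ped)
    return _inbreeding_meuwissen_luo(ped)


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Dense additive relationship matrix A by the tabular recursion."""
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(values=A, ids=ped.ids)


def relationship_inverse(ped: Pedigree, inbreeding: bool = True) -> sp.csr_matrix:
    """Sparse inverse of A assembled directly from the pedigree.

    Henderson's rules: each individual contributes 1/d_i to its own cell,
    -1/(2 d_i) to individual-parent cells and 1/(4 d_i) among its known
    parents, with d_i the Mendelian-sampling variance.  ``inbreeding=False``
    uses d_i as if all parents were non-inbred.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped) if inbreeding else np.zeros(n)
    d = _mendelian_variance(ped, F, use_inbreeding=inbreeding)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        b = 1.0 / d[i]
        add(i, i, b)
        known = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        for p in known:
            add(i, p, -0.5 * b)
            add(p, i, -0.5 * b)
        for p in known:
            for q in known:
                add(p, q, 0.25 * b)
    return sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n), dtype=float)
    )


def write_triplets(matrix: RelationshipMatrix | sp.spmatrix, ids: Sequence[str], path: str | Path) -> None:
    """Write a (possibly sparse) symmetric matrix as lower-triangle triplets."""
    if isinstance(matrix, RelationshipMatrix):
        df = matrix.to_triplets()
    else:
        coo = sp.tril(sp.coo_matrix(matrix))
        df = pd.DataFrame(
            {
                "row_id": [ids[r] for r in coo.row],
                "col_id": [ids[c] for c in coo.col],
                "value": coo.data,
            }
        )
    df.to_csv(path, index=False)
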