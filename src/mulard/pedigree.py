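"""Pedigree ingestion and additive (numerator) relationship machinery.

Each parental line of a crossbreeding scheme carries its own pedigree; the
additive relationship matrix A of that pedigree, together with the line's
genetic covariance matrix, defines the prior covariance of the line-specific
transmitted effects in the crossbred model.

Unknown parents are coded 0 in files and -1 internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1


@dataclass
class Pedigree:
    """Topologically sorted pedigree for one line.

    Attributes
    ----------
    ids : array of original animal identifiers, parents before offspring
    sire, dam : integer positions into ``ids`` (``-1`` = unknown)
    line : free-form tag, e.g. ``"common"`` or ``"muscovy"``
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    line: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(self._index) != len(self.ids):
            self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate animal ids in pedigree")

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, animal) -> int:
        return self._index[animal]

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))

    def to_frame(self) -> pd.DataFrame:
        def back(pos):
            return np.where(pos == UNKNOWN, 0, np.asarray(self.ids)[np.maximum(pos, 0)])

        return pd.DataFrame(
            {"animal": self.ids, "sire": back(self.sire), "dam": back(self.dam)}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _toposort(animals, sires, dams):
    """Order animals so parents precede offspring; raise on cycles."""
    index = {a: i for i, a in enumerate(animals)}
    if len(index) != len(animals):
        dup = pd.Series(animals).loc[lambda s: s.duplicated()].tolist()
        raise ValueError(f"duplicate animal ids: {dup[:5]}")
    n = len(animals)
    state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 in-stack, 2 done
    order: list[int] = []
    for start in range(n):
        if state[start]:
            continue
        stack = [(start, 0)]
        while stack:
            node, phase = stack.pop()
            if phase == 0:
                if state[node] == 1:
                    raise ValueError(f"pedigree cycle involving id {animals[node]}")
                if state[node] == 2:
                    continue
                state[node] = 1
                stack.append((node, 1))
                for parent in (sires[node], dams[node]):
                    if parent in index:
                        p = index[parent]
                        if state[p] == 1:
                            raise ValueError(
                                f"pedigree cycle involving id {animals[p]}"
                            )
                        if state[p] == 0:
                            stack.append((p, 0))
            else:
                state[node] = 2
                order.append(node)
    return order, index


def from_frame(frame: pd.DataFrame, line: str = "") -> Pedigree:
    """Build a validated, sorted :class:`Pedigree` from an animal/sire/dam table."""
    cols = list(frame.columns[:3])
    animals = frame[cols[0]].to_numpy()
    sires = frame[cols[1]].to_numpy()
    dams = frame[cols[2]].to_numpy()
    for i, a in enumerate(animals):
        if a == sires[i] or a == dams[i]:
            raise ValueError(f"animal {a} listed as its own parent")
    order, index = _toposort(animals, sires, dams)
    ids = animals[order]
    pos = {a: i for i, a in enumerate(ids)}

    def resolve(parents):
        out = np.full(len(ids), UNKNOWN, dtype=np.int64)
        for i, a in enumerate(ids):
            p = parents[index[a]]
            if p != 0 and not pd.isna(p):
                if p not in pos:
                    raise ValueError(f"parent {p} of animal {a} not in pedigree")
                out[i] = pos[p]
        return out

    return Pedigree(ids=ids, sire=resolve(sires), dam=resolve(dams), line=line)


def read_pedigree(path, line: str = "") -> Pedigree:
    """Read an ``animal,sire,dam`` CSV (0 = unknown parent, one header row)."""
    return from_frame(pd.read_csv(path), line=line)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    Computes A_ii = sum_j L_ij^2 D_j over the ancestors j of i, where L is
    the Cholesky-style path-coefficient factor and D the Mendelian-sampling
    variance; F_i = A_ii - 1. An unknown parent is an unrelated non-inbred
    founder, so animals with any unknown parent have F = 0.
    """
    n = len(ped)
    f = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            continue
        L = np.zeros(i + 1)
        L[i] = 1.0
        a_ii = 0.0
        for j in range(i, -1, -1):
            if L[j] == 0.0:
                continue
            sj, dj = ped.sire[j], ped.dam[j]
            if sj != UNKNOWN:
                L[sj] += 0.5 * L[j]
            if dj != UNKNOWN:
                L[dj] += 0.5 * L[j]
            a_ii += L[j] * L[j] * _mendelian_variance(ped, f, j)
        f[i] = a_ii - 1.0
    return f


def _mendelian_variance(ped: Pedigree, f: np.ndarray, j: int) -> float:
    s, d = ped.sire[j], ped.dam[j]
    fs = f[s] if s != UNKNOWN else 0.0
    fd = f[d] if d != UNKNOWN else 0.0
    known = int(s != UNKNOWN) + int(d != UNKNOWN)
    if known == 2:
        return 0.5 - 0.25 * (fs + fd)
    if known == 1:
        return 0.75 - 0.25 * (fs + fd)
    return 1.0


def build_A(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix by the tabular method.

    Handles inbreeding exactly: a_ii = 1 + 0.5 * a(sire, dam).
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a_sd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            val = 0.0
            if s != UNKNOWN:
                val += 0.5 * A[j, s]
            if d != UNKNOWN:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def build_A_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with exact inbreeding.

    Uses the decomposition A = T D T' where D is diagonal with the
    Mendelian-sampling variances; A^-1 = (T^-1)' D^-1 T^-1 accumulates at
    most 9 entries per animal.
    """
    n = len(ped)
    f = inbreeding(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        dinv = 1.0 / _mendelian_variance(ped, f, i)
        entries = [(i, 1.0)]
        if s != UNKNOWN:
            entries.append((s, -0.5))
        if d != UNKNOWN:
            entries.append((d, -0.5))
        for a, wa in entries:
            for b, wb in entries:
                rows.append(a)
                cols.append(b)
                vals.append(wa * wb * dinv)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def write_triplets(matrix, path) -> None:
    """Export a (sparse or dense) relationship matrix as row,col,value CSV."""
    coo = sparse.coo_matrix(matrix)
    pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
        path, index=False
    )
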