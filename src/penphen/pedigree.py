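"""Pedigree handling and the numerator relationship matrix.

The additive genetic covariance among animals in the animal model is
``A * sigma2_u``, where ``A`` is the numerator relationship matrix (twice
the kinship matrix; diagonal ``1 + F`` with ``F`` the inbreeding
coefficient).  The mixed-model machinery never needs dense ``A`` itself,
only its sparse inverse, which is assembled directly from the pedigree by
Henderson's rules with Mendelian-sampling variances adjusted for parental
inbreeding.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = 0  # file-level code for an unknown parent


class PedigreeError(ValueError):
    """Malformed pedigree (cycles, unknown animals, bad codes)."""


@dataclass
class Pedigree:
    """Animal-sire-dam triples with internal 0-based indices, -1 = unknown."""

    ids: np.ndarray            # animal identifiers, in storage order
    sire: np.ndarray           # index of sire in `ids`, -1 if unknown
    dam: np.ndarray            # index of dam in `ids`, -1 if unknown
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.ids) == len(self.sire) == len(self.dam)):
            raise PedigreeError("ids, sire, dam must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise PedigreeError("duplicate animal ids in pedigree")
        self._index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in np.asarray(animal_ids)],
                            dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message path
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    @classmethod
    def from_triples(cls, triples) -> "Pedigree":
        """Build from (animal, sire, dam) id triples; parent id 0/""/None = unknown."""
        animals = [t[0] for t in triples]
        index = {a: i for i, a in enumerate(animals)}

        def code(p):
            if p in (0, "0", "", None):
                return -1
            if p not in index:
                raise PedigreeError(f"parent {p!r} has no own pedigree record")
            return index[p]

        sire = [code(t[1]) for t in triples]
        dam = [code(t[2]) for t in triples]
        return cls(np.asarray(animals), np.asarray(sire), np.asarray(dam))

    def to_frame(self) -> pd.DataFrame:
        def decode(idx):
            return [self.ids[i] if i >= 0 else 0 for i in idx]

        return pd.DataFrame(
            {"animal": self.ids, "sire": decode(self.sire), "dam": decode(self.dam)}
        )

    def is_sorted(self) -> bool:
        idx = np.arange(self.n)
        ok_s = (self.sire < idx) | (self.sire < 0)
        ok_d = (self.dam < idx) | (self.dam < 0)
        return bool(np.all(ok_s & ok_d))


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so every parent precedes its offspring.

    Stable: among animals whose parents are already placed, original file
    order is preserved.  Raises :class:`PedigreeError` naming an animal on
    a cycle if the parentage graph is cyclic.
    """
    n = ped.n
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) < n:
        stuck = int(np.flatnonzero(indeg > 0)[0])
        raise PedigreeError(
            f"pedigree contains a parentage cycle involving animal {ped.ids[stuck]!r}"
        )
    order = np.asarray(order)
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)

    def remap(par):
        return np.where(par >= 0, pos[np.maximum(par, 0)], -1)

    return Pedigree(ped.ids[order], remap(ped.sire)[order], remap(ped.dam)[order])


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with inbreeding coefficients."""

    A: np.ndarray
    F: np.ndarray
    ids: np.ndarray


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ij = 0.5 (a_{j,s(i)} + a_{j,d(i)}) for j < i and
    a_ii = 1 + 0.5 a_{s(i),d(i)}; unknown parents contribute zero
    (unrelated, non-inbred base population).
    """
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    n = ped.n
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
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(A=A, F=np.diag(A) - 1.0, ids=ped.ids)


def inbreeding(ped: Pedigree, method: str = "auto") -> np.ndarray:
    """Inbreeding coefficients F for a sorted pedigree.

    method="tabular" builds the full A (quadratic memory, fine to a few
    thousand animals); method="recursive" is the Meuwissen & Luo style
    ancestor-traversal that needs only O(n) memory.  "auto" switches to
    the recursive method above 5000 animals.
    """
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    if method == "auto":
        method = "tabular" if ped.n <= 5000 else "recursive"
    if method == "tabular":
        return build_A(ped).F
    if method != "recursive":
        raise ValueError(f"unknown inbreeding method {method!r}")

    n = ped.n
    F = np.zeros(n)
    # Mendelian-sampling variance d_i, using F = -1 for an unknown parent
    # so that d covers the one- and no-parent cases automatically.
    d = np.zeros(n)
    for i in range(n):
        fs = F[ped.sire[i]] if ped.sire[i] >= 0 else -1.0
        fd = F[ped.dam[i]] if ped.dam[i] >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        s, dd = ped.sire[i], ped.dam[i]
        if s < 0 or dd < 0:
            F[i] = 0.0  # kinship with an unknown (base) parent is zero
            continue
        # a_ii = sum_j L_ij^2 d_j over ancestors j (including i): F_i = a_ii - 1
        coeff = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lj = coeff.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            for p in (ped.sire[j], ped.dam[j]):
                if p >= 0:
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    For animal i with Mendelian-sampling variance
    d_i = 1 - 0.25 * sum over known parents p of (1 + F_p), the inverse
    receives 1/d_i at (i,i), -1/(2 d_i) at (i, parent) and 1/(4 d_i) at
    every (parent, parent) pair of known parents.
    """
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    rows, cols, vals = [], [], []
    for i in range(n):
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        d = 1.0 - sum(0.25 * (1.0 + F[p]) for p in parents)
        if d <= 0:
            raise PedigreeError(f"non-positive Mendelian variance for {ped.ids[i]!r}")
        a = 1.0 / d
        rows.append(i); cols.append(i); vals.append(a)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-a / 2.0, -a / 2.0]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(a / 4.0)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def relationship_submatrix(A_inv: sp.spmatrix, idx: np.ndarray) -> np.ndarray:
    """Relationships among the animals `idx` (positions), from sparse A⁻¹.

    Solves A⁻¹ X = E (columns of the identity at `idx`) with a sparse LU
    factorisation, so dense A is never formed for the whole pedigree.
    """
    from scipy.sparse.linalg import splu

    idx = np.asarray(idx, dtype=np.int64)
    uniq, inv = np.unique(idx, return_inverse=True)
    lu = splu(sp.csc_matrix(A_inv))
    rhs = np.zeros((A_inv.shape[0], len(uniq)))
    rhs[uniq, np.arange(len(uniq))] = 1.0
    cols = lu.solve(rhs)
    sub = cols[uniq, :]
    sub = 0.5 * (sub + sub.T)  # symmetrise away LU round-off
    return sub[np.ix_(inv, inv)]


# ---------------------------------------------------------------- file I/O

def read_pedigree(path) -> Pedigree:
    """Read a 3-column animal/sire/dam file (whitespace or comma separated, 0 = unknown)."""
    text = Path(path).read_text().strip()
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                     skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs 3 columns: animal sire dam")
    if list(df.iloc[0].str.lower())[:3] == ["animal", "sire", "dam"]:
        df = df.iloc[1:]
    cols = [df.iloc[:, j] for j in range(3)]
    try:  # integer ids are common; match the dtype phenotype tables carry
        cols = [c.astype(np.int64) for c in cols]
    except (TypeError, ValueError):
        pass
    triples = list(zip(cols[0], cols[1].replace("0", 0), cols[2].replace("0", 0)))
    return Pedigree.from_triples(triples)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def write_sparse_coo(mat: sp.spmatrix, path) -> None:
    """Coordinate-format text export (i, j, value), 0-based indices."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write("i,j,value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i},{j},{v!r}\n")
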