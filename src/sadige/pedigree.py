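"""Pedigree storage, additive relationship matrix A and its sparse inverse.

The additive (numerator) relationship matrix gives expected allele
sharing between relatives; its inverse is sparse (nonzeros only among
animal/sire/dam triples) and is what makes pedigree mixed models
tractable at scale.  Inbreeding is accumulated with the Meuwissen-Luo
algorithm so the inverse is exact on arbitrary pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "build_A",
    "build_A_inverse",
    "inbreeding_coefficients",
    "mendelian_variance_scalars",
    "mean_cage_relatedness",
]

UNKNOWN = -1


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree (parents before offspring).

    ``sire`` / ``dam`` hold positional indices into ``ids`` or -1 for an
    unknown parent (treated as an unrelated founder contribution).
    """

    ids: tuple
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate animal ids in pedigree")
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            a = np.asarray(arr, dtype=np.int64)
            if a.shape != (n,):
                raise ValueError(f"{name} array has wrong length")
            if np.any(a >= np.arange(n)):
                raise ValueError(
                    "parents must precede offspring (cycle or ordering error)"
                )
            if np.any(a < UNKNOWN):
                raise ValueError(f"invalid {name} index")
            object.__setattr__(self, name, a)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.asarray([lookup[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in pedigree") from exc

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "Pedigree":
        """Build from a 3-column table (animal, sire, dam).

        0, NA or empty denote unknown parents.  Rows are re-ordered
        topologically if needed; a parent that never appears as an
        animal is added as a founder.
        """
        cols = list(frame.columns[:3])
        animals = frame[cols[0]].tolist()
        if len(set(animals)) != len(animals):
            dup = frame[cols[0]][frame[cols[0]].duplicated()].iloc[0]
            raise ValueError(f"duplicate animal id in pedigree: {dup!r}")

        def clean(v):
            if pd.isna(v) or v == 0 or v == "0" or v == "":
                return None
            return v

        parent_of = {
            a: (clean(s), clean(d))
            for a, s, d in zip(
                animals, frame[cols[1]].tolist(), frame[cols[2]].tolist()
            )
        }
        # implicit founders: parents never listed as animals
        known = set(animals)
        extras = []
        for s, d in parent_of.values():
            for p in (s, d):
                if p is not None and p not in known:
                    known.add(p)
                    extras.append(p)
        order: list = []
        seen: dict = {}

        def visit(a, stack):
            state = seen.get(a)
            if state == 2:
                return
            if state == 1:
                raise ValueError(f"pedigree cycle involving animal {a!r}")
            seen[a] = 1
            for p in parent_of.get(a, (None, None)):
                if p is not None:
                    visit(p, stack)
            seen[a] = 2
            order.append(a)

        for a in extras + animals:
            visit(a, None)
        idx = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam = np.full(len(order), UNKNOWN, dtype=np.int64)
        for a, (s, d) in parent_of.items():
            if s is not None:
                sire[idx[a]] = idx[s]
            if d is not None:
                dam[idx[a]] = idx[d]
        return Pedigree(tuple(order), sire, dam)

    def to_frame(self) -> pd.DataFrame:
        def back(i):
            return 0 if i == UNKNOWN else self.ids[i]

        return pd.DataFrame(
            {
                "animal": list(self.ids),
                "sire": [back(i) for i in self.sire],
                "dam": [back(i) for i in self.dam],
            }
        )


def build_A(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix by the tabular method."""
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Meuwissen-Luo inbreeding coefficients F."""
    return _meuwissen_luo(ped)[0]


def _meuwissen_luo(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Return (F, d) where d are Mendelian sampling variance scalars.

    Uses the Meuwissen-Luo algorithm: for each animal, the i-th row of
    the Cholesky factor L of A is generated by tracing ancestors, and
    ``A_ii = sum_j L_ij^2 d_j``.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        s, dd = ped.sire[i], ped.dam[i]
        fs = F[s] if s != UNKNOWN else -1.0  # F of unknown parent coded -1
        fd = F[dd] if dd != UNKNOWN else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s == UNKNOWN and dd == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate L[i, j] over ancestors j by downward recursion
        L = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lij = L.pop(j, 0.0)
            if lij == 0.0:
                continue
            sj, dj = ped.sire[j], ped.dam[j]
            if sj != UNKNOWN:
                L[sj] = L.get(sj, 0.0) + 0.5 * lij
            if dj != UNKNOWN:
                L[dj] = L.get(dj, 0.0) + 0.5 * lij
            aii += lij * lij * d[j]
        F[i] = aii - 1.0
    return F, d


def mendelian_variance_scalars(ped: Pedigree) -> np.ndarray:
    """Per-animal Mendelian sampling variance scalar d_i.

    The within-family deviation of an offspring's breeding value has
    covariance ``d_i * Sigma`` with ``d_i = 0.5 - 0.25 (F_s + F_d)``
    (unknown parents contribute F = -1, i.e. founder variance).
    """
    return _meuwissen_luo(ped)[1]


def build_A_inverse(
    ped: Pedigree, inbreeding: bool = True
) -> sparse.csc_matrix:
    """Sparse A^-1 by Henderson's rules.

    With ``inbreeding=True`` (default) the Mendelian variance scalars
    account for parental inbreeding (Meuwissen-Luo), making the inverse
    exact on arbitrary pedigrees.
    """
    n = ped.n
    if inbreeding:
        d = _meuwissen_luo(ped)[1]
    else:
        # classic rules: d depends only on number of known parents
        known = (ped.sire != UNKNOWN).astype(float) + (
            ped.dam != UNKNOWN
        ).astype(float)
        d = 1.0 - 0.25 * known
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        b = 1.0 / d[i]
        s, dd = ped.sire[i], ped.dam[i]
        parents = [p for p in (s, dd) if p != UNKNOWN]
        add(i, i, b)
        for p in parents:
            add(i, p, -0.5 * b)
            add(p, i, -0.5 * b)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * b)
    return sparse.csc_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )


def log_det_A(ped: Pedigree) -> float:
    """log |A| = sum log d_i (A = L D L' with unit-triangular L)."""
    return float(np.sum(np.log(_meuwissen_luo(ped)[1])))


def mean_cage_relatedness(A: np.ndarray, groups: dict) -> float:
    """Average additive relatedness among cage mates, averaged over cages.

    ``groups`` maps group id -> sequence of row indices into ``A``.
    """
    per_group = []
    for gid, members in groups.items():
        members = np.asarray(members, dtype=np.int64)
        k = len(members)
        if k < 2:
            raise ValueError(f"group {gid!r} has fewer than 2 members")
        sub = A[np.ix_(members, members)]
        off = (sub.sum() - np.trace(sub)) / (k * (k - 1))
        per_group.append(off)
    return float(np.mean(per_group))
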