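"""Small exact linear algebra helpers over Z and Q.

Everything here works on tuples of ints / Fractions; sizes are tiny
(ambient dimension <= ~16), so clarity wins over asymptotics.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import List, Optional, Sequence, Tuple

IntVec = Tuple[int, ...]


def primitivize(vec: Sequence[Fraction | int]) -> IntVec:
    """Scale a rational vector to its primitive integer form (gcd 1, same ray)."""
    fracs = [Fraction(x) for x in vec]
    if all(f == 0 for f in fracs):
        return tuple(0 for _ in fracs)
    denom = 1
    for f in fracs:
        denom = denom * f.denominator // gcd(denom, f.denominator)
    ints = [int(f * denom) for f in fracs]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    return tuple(x // g for x in ints)


def dot(a: Sequence, b: Sequence):
    return sum(x * y for x, y in zip(a, b))


def frac_rank(rows: Sequence[Sequence[Fraction | int]]) -> int:
    """Rank over Q by Gaussian elimination."""
    mat = [[Fraction(x) for x in r] for r in rows]
    rank = 0
    ncols = len(mat[0]) if mat else 0
    col = 0
    while rank < len(mat) and col < ncols:
        piv = next((i for i in range(rank, len(mat)) if mat[i][col] != 0), None)
        if piv is None:
            col += 1
            continue
        mat[rank], mat[piv] = mat[piv], mat[rank]
        pv = mat[rank][col]
        for i in range(rank + 1, len(mat)):
            if mat[i][col] != 0:
                f = mat[i][col] / pv
                mat[i] = [a - f * b for a, b in zip(mat[i], mat[rank])]
        rank += 1
        col += 1
    return rank


class SpanTracker:
    """Incremental row-space tracker for greedy independent-row selection."""

    def __init__(self, dim: int) -> None:
        self.dim = dim
        self._rows: List[List[Fraction]] = []  # kept in echelon form
        self._pivots: List[int] = []

    @property
    def rank(self) -> int:
        return len(self._rows)

    def _reduce(self, vec: Sequence) -> List[Fraction]:
        v = [Fraction(x) for x in vec]
        for row, p in zip(self._rows, self._pivots):
            if v[p] != 0:
                f = v[p] / row[p]
                v = [a - f * b for a, b in zip(v, row)]
        return v

    def extends_span(self, vec: Sequence) -> bool:
        return any(x != 0 for x in self._reduce(vec))

    def add(self, vec: Sequence) -> bool:
        """Add the row if independent; returns True if the span grew."""
        v = self._reduce(vec)
        piv = next((i for i, x in enumerate(v) if x != 0), None)
        if piv is None:
            return False
        self._rows.append(v)
        self._pivots.append(piv)
        return True


def frac_inverse(rows: Sequence[Sequence[Fraction | int]]) -> List[List[Fraction]]:
    """Exact inverse of a square matrix (rows of Fractions); raises on singular."""
    n = len(rows)
    aug = [[Fraction(x) for x in r] + [Fraction(int(i == j)) for j in range(n)]
           for i, r in enumerate(rows)]
    for col in range(n):
        piv = next((i for i in range(col, n) if aug[i][col] != 0), None)
        if piv is None:
            raise ValueError("singular matrix")
        aug[col], aug[piv] = aug[piv], aug[col]
        pv = aug[col][col]
        aug[col] = [x / pv for x in aug[col]]
        for i in range(n):
            if i != col and aug[i][col] != 0:
                f = aug[i][col]
                aug[i] = [a - f * b for a, b in zip(aug[i], aug[col])]
    return [r[n:] for r in aug]


def diagonalize_integer(mat: Sequence[Sequence[int]]):
    """Diagonalize over Z with transforms: returns (U, D, V) with U @ A @ V = D.

    U (m x m) and V (n x n) are unimodular integer matrices; D is diagonal as an
    m x n list of lists.  (No divisibility-chain normalization: callers here only
    need the zero/nonzero pattern, e.g. for kernel lattices.)
    """
    A = [list(map(int, r)) for r in mat]
    m = len(A)
    n = len(A[0]) if m else 0
    U = [[int(i == j) for j in range(m)] for i in range(m)]
    V = [[int(i == j) for j in range(n)] for i in range(n)]

    def swap_rows(i, j):
        A[i], A[j] = A[j], A[i]
        U[i], U[j] = U[j], U[i]

    def swap_cols(i, j):
        for r in A:
            r[i], r[j] = r[j], r[i]
        for r in V:
            r[i], r[j] = r[j], r[i]

    def add_row(dst, src, f):
        A[dst] = [a + f * b for a, b in zip(A[dst], A[src])]
        U[dst] = [a + f * b for a, b in zip(U[dst], U[src])]

    def add_col(dst, src, f):
        for r in A:
            r[dst] += f * r[src]
        for r in V:
            r[dst] += f * r[src]

    t = 0
    while t < min(m, n):
        # locate smallest nonzero pivot in the remaining block
        best = None
        for i in range(t, m):
            for j in range(t, n):
                if A[i][j] != 0 and (best is None or abs(A[i][j]) < abs(A[best[0]][best[1]])):
                    best = (i, j)
        if best is None:
            break
        swap_rows(t, best[0])
        swap_cols(t, best[1])
        dirty = True
        while dirty:
            dirty = False
            for i in range(t + 1, m):
                if A[i][t] != 0:
                    q = A[i][t] // A[t][t]
                    add_row(i, t, -q)
                    if A[i][t] != 0:  # remainder smaller than pivot: swap up
                        swap_rows(t, i)
                        dirty = True
            for j in range(t + 1, n):
                if A[t][j] != 0:
                    q = A[t][j] // A[t][t]
                    add_col(j, t, -q)
                    if A[t][j] != 0:
                        swap_cols(t, j)
                        dirty = True
        if A[t][t] < 0:
            A[t] = [-x for x in A[t]]
            U[t] = [-x for x in U[t]]
        t += 1
    return U, A, V


def kernel_lattice_basis(rows: Sequence[Sequence[int]], dim: int) -> List[IntVec]:
    """Z-basis of {x in Z^dim : rows @ x = 0} (columns of V at zero invariant factors)."""
    if not rows:
        return [tuple(int(i == j) for i in range(dim)) for j in range(dim)]
    _, D, V = diagonalize_integer(rows)
    m = len(rows)
    # columns j of V with D[j][j] == 0 (or beyond the diagonal) span the kernel
    basis = []
    for j in range(dim):
        dj = D[j][j] if j < min(m, dim) else 0
        if dj == 0:
            basis.append(tuple(V[i][j] for i in range(dim)))
    return basis


def verify_snf(mat, U, D, V) -> bool:
    """Check U @ mat @ V == D (used defensively in tests)."""
    m, n = len(mat), len(mat[0])
    UM = [[sum(U[i][k] * mat[k][j] for k in range(m)) for j in range(n)] for i in range(m)]
    UMV = [[sum(UM[i][k] * V[k][j] for k in range(n)) for j in range(n)] for i in range(m)]
    return UMV == [list(r) for r in D]
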