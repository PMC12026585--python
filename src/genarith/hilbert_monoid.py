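"""Pointed rational cones, dual cones, and Hilbert bases of dual monoids.

A :class:`RationalCone` is stored by its generator rows.  The monoid of
interest is the set of integer vectors with non-negative inner product
against every generator (the dual region intersected with the lattice);
:func:`hilbert_basis` returns its unique minimal generating set, which exists
and is finite for pointed monoids (Gordan).

The native algorithm is built for small dimensions (<= ~16) and exact
arithmetic:

1. explicit equality pairs (rows ``a`` and ``-a``) are eliminated by passing
   to the integer kernel lattice of the equalities;
2. a full-rank subset of the inequality rows defines a simplicial monoid whose
   generators are its primitive extreme rays plus the lattice points of the
   half-open fundamental parallelepiped;
3. the remaining halfspaces are intersected one at a time with a
   Pottier-style completion (sum positive/negative pairs, discard reducible
   candidates);
4. a final degree-graded reduction keeps exactly the irreducible elements.

Plain-text Normaliz ``.in`` / ``.out`` interchange is provided so results can
be cross-checked against an external Normaliz binary when one is available.
"""

from __future__ import annotations

import itertools
import math
import re
import shutil
import subprocess
import tempfile
from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._intlinalg import (SpanTracker, diagonalize_integer, dot, frac_inverse, frac_rank,
                         kernel_lattice_basis, primitivize)

__all__ = [
    "RationalCone",
    "HilbertBasis",
    "NormalizDocument",
    "NonPointedError",
    "ResourceLimitError",
    "NormalizParseError",
    "dual_cone",
    "hilbert_basis",
    "is_in_monoid",
    "decompose",
    "magic_square_cone",
    "read_normaliz",
    "write_normaliz",
    "parse_normaliz_output",
    "write_normaliz_output",
    "run_normaliz",
]

IntVec = Tuple[int, ...]


class NonPointedError(ValueError):
    """The dual monoid is not pointed; its minimal generating set is not unique."""


class ResourceLimitError(RuntimeError):
    """Enumeration bound exceeded before closure."""


class NormalizParseError(ValueError):
    def __init__(self, message: str, line: int) -> None:
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class RationalCone:
    """Integer cone given by generator rows (rational input is primitivized)."""

    generators: Tuple[IntVec, ...]
    ambient_dim: int

    def __post_init__(self) -> None:
        if not self.generators:
            raise ValueError("cone needs at least one generator")
        if any(len(g) != self.ambient_dim for g in self.generators):
            raise ValueError("generator length must equal ambient_dim")

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence], ambient_dim: Optional[int] = None
                  ) -> "RationalCone":
        prim = []
        seen = set()
        dim = ambient_dim if ambient_dim is not None else len(rows[0])
        for r in rows:
            p = primitivize(r)
            if any(p) and p not in seen:
                seen.add(p)
                prim.append(p)
        if not prim:
            prim = [tuple(0 for _ in range(dim))]
        return cls(generators=tuple(prim), ambient_dim=dim)

    @property
    def monoid_is_pointed(self) -> bool:
        """Pointedness of {v : <v, gen> >= 0 for all gens} (rank test)."""
        return frac_rank(self.generators) == self.ambient_dim


@dataclass(frozen=True)
class HilbertBasis:
    """Minimal generating set of the dual monoid of ``cone``."""

    elements: Tuple[IntVec, ...]
    cone: Optional[RationalCone]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements",
                           tuple(sorted(tuple(int(x) for x in e) for e in self.elements)))

    def __len__(self) -> int:
        return len(self.elements)

    def to_json_dict(self) -> Dict:
        return {
            "elements": [list(e) for e in self.elements],
            "cone": [list(g) for g in self.cone.generators] if self.cone else None,
        }


def is_in_monoid(v: Sequence[int], cone: RationalCone) -> bool:
    """True iff v has non-negative inner product with every generator."""
    if len(v) != cone.ambient_dim:
        raise ValueError(f"dimension mismatch: {len(v)} != {cone.ambient_dim}")
    return all(dot(v, c) >= 0 for c in cone.generators)


# ---------------------------------------------------------------------------
# dual cone by incremental double description
# ---------------------------------------------------------------------------

def dual_cone(cone: RationalCone) -> RationalCone:
    """Generator description of {v : <v, c> >= 0 for every generator c}.

    Returned generators are the extreme rays plus a +/- pair for every
    lineality direction, so the conic hull of the output equals the dual
    region exactly.
    """
    d = cone.ambient_dim
    lineality: List[List[Fraction]] = [[Fraction(int(i == j)) for j in range(d)]
                                       for i in range(d)]
    rays: List[List[Fraction]] = []
    processed: List[IntVec] = []

    for a in cone.generators:
        av_lin = [dot(a, l) for l in lineality]
        pivot = next((i for i, x in enumerate(av_lin) if x != 0), None)
        if pivot is not None:
            l0 = lineality[pivot]
            if av_lin[pivot] < 0:
                l0 = [-x for x in l0]
            al0 = dot(a, l0)
            lineality = [
                [x - (dot(a, l) / al0) * y for x, y in zip(l, l0)]
                for i, l in enumerate(lineality) if i != pivot
            ]
            rays = [[x - (dot(a, r) / al0) * y for x, y in zip(r, l0)] for r in rays]
            rays.append(l0)
        else:
            sval = [dot(a, r) for r in rays]
            pos = [r for r, s in zip(rays, sval) if s > 0]
            zer = [r for r, s in zip(rays, sval) if s == 0]
            neg = [r for r, s in zip(rays, sval) if s < 0]
            new: List[List[Fraction]] = []
            free_dim = d - len(lineality)
            for p in pos:
                for m in neg:
                    if _adjacent(p, m, rays, processed, free_dim):
                        sp, sm = dot(a, p), dot(a, m)
                        new.append([sp * y - sm * x for x, y in zip(p, m)])
            rays = pos + zer + new
        rays = [list(map(Fraction, primitivize(r))) for r in rays]
        # dedupe
        uniq, seen = [], set()
        for r in rays:
            t = tuple(r)
            if t not in seen:
                seen.add(t)
                uniq.append(r)
        rays = uniq
        processed.append(a)

    gens: List[Sequence] = list(rays)
    for l in lineality:
        gens.append(l)
        gens.append([-x for x in l])
    return RationalCone.from_rows(gens, ambient_dim=d)


def _adjacent(p, m, rays, processed, free_dim) -> bool:
    """Algebraic adjacency test for DD: common active rows have rank dim - 2."""
    if free_dim <= 2:
        return True
    active = [a for a in processed if dot(a, p) == 0 and dot(a, m) == 0]
    if not active:
        return free_dim <= 2
    return frac_rank(active) >= free_dim - 2


# ---------------------------------------------------------------------------
# native Hilbert basis
# ---------------------------------------------------------------------------

_PARALLELEPIPED_CAP = 300_000
_COMPLETION_BUDGET = 2_000_000


def hilbert_basis(cone: RationalCone) -> HilbertBasis:
    """Unique minimal generating set of the dual monoid of ``cone``.

    Raises :class:`NonPointedError` when the monoid contains a line (minimal
    generating sets are then not unique) and :class:`ResourceLimitError` when
    the exact enumeration bounds are exceeded.
    """
    d = cone.ambient_dim
    rows = [r for r in cone.generators if any(r)]
    if frac_rank(rows) < d:
        raise NonPointedError(
            f"inequality rows have rank < ambient dimension {d}; "
            "the dual monoid contains a line")
    rowset = set(rows)
    eq_reps, ineq = [], []
    for r in rows:
        neg = tuple(-x for x in r)
        if neg in rowset:
            if r > neg:  # keep one representative per +/- pair
                eq_reps.append(r)
        else:
            ineq.append(r)
    if eq_reps:
        K = kernel_lattice_basis(eq_reps, d)
        if not K:
            return HilbertBasis(elements=(), cone=cone)
        red_rows = []
        for a in ineq:
            red_rows.append(tuple(dot(a, kj) for kj in K))
        elements_red = _core_hilbert(red_rows, len(K))
        elements = [tuple(sum(K[j][i] * y[j] for j in range(len(K))) for i in range(d))
                    for y in elements_red]
    else:
        elements = _core_hilbert(ineq, d)
    return HilbertBasis(elements=tuple(elements), cone=cone)


def _core_hilbert(rows: Sequence[IntVec], d: int) -> List[IntVec]:
    clean, seen = [], set()
    for r in rows:
        p = primitivize(r)
        if any(p) and p not in seen:
            seen.add(p)
            clean.append(p)
    if frac_rank(clean) < d:
        raise NonPointedError("reduced inequality system is rank-deficient")
    tracker = SpanTracker(d)
    base, rest = [], []
    for a in clean:
        (base if tracker.add(a) else rest).append(a)
    S = _reduce_to_basis(_simplicial_generators(base), base, base)
    processed = list(base)
    pending = list(rest)
    while pending:
        # dynamic order: the halfspace violated by fewest current generators
        # keeps the completion sets small
        def n_cut(a):
            return sum(1 for v in S if dot(a, v) < 0)
        pending.sort(key=n_cut)
        a = pending.pop(0)
        S = _halfspace_step(S, processed, a)
        processed.append(a)
        # auto-reduction: carry only the Hilbert basis of the intermediate monoid
        S = _reduce_to_basis(S, processed, base)
    return _reduce_to_basis(S, processed, base)


def _simplicial_generators(base: List[IntVec]) -> List[IntVec]:
    """Generators of {x in Z^d : B x >= 0} for independent rows B: primitive
    extreme rays plus the fundamental-parallelepiped lattice points.

    Parallelepiped points are enumerated exactly as coset representatives of
    Z^d modulo the ray lattice (Smith normal form), so the work is
    proportional to the index |det R|, not to a bounding box.
    """
    d = len(base)
    Binv = frac_inverse(base)
    rays: List[IntVec] = []
    for j in range(d):
        rays.append(primitivize([Binv[i][j] for i in range(d)]))
    R = [[rays[j][i] for j in range(d)] for i in range(d)]  # columns = rays
    U, D, _V = diagonalize_integer(R)
    diag = [abs(D[i][i]) for i in range(d)]
    total = math.prod(diag)
    if total > _PARALLELEPIPED_CAP:
        raise ResourceLimitError(
            f"fundamental parallelepiped has {total} residues (cap {_PARALLELEPIPED_CAP})")
    Uinv = frac_inverse(U)
    Rinv = frac_inverse(R)
    pts: List[IntVec] = []
    for t in itertools.product(*(range(x) for x in diag)):
        if not any(t):
            continue
        x = [sum(Uinv[i][j] * t[j] for j in range(d)) for i in range(d)]
        lam = [sum(Rinv[i][j] * x[j] for j in range(d)) for i in range(d)]
        frac = [l - (l.numerator // l.denominator) for l in lam]
        p = [sum(R[i][j] * frac[j] for j in range(d)) for i in range(d)]
        assert all(f.denominator == 1 for f in p)
        pt = tuple(int(f) for f in p)
        if any(pt):
            pts.append(pt)
    out, seen = [], set()
    for v in rays + pts:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _halfspace_step(S: List[IntVec], prev_rows: List[IntVec], a: IntVec) -> List[IntVec]:
    """One Pottier completion step: intersect the monoid <S> with {a.x >= 0}."""
    if not S:
        return []
    prevT = np.array(prev_rows, dtype=np.int64).T
    a_np = np.array(a, dtype=np.int64)

    S = list(S)
    S_np = np.array(S, dtype=np.int64)
    aval = S_np @ a_np
    members = set(S)

    pos = [i for i, s in enumerate(aval) if s > 0]
    neg = [i for i, s in enumerate(aval) if s < 0]
    queue = deque((p, m) for p in pos for m in neg)
    steps = 0
    while queue:
        steps += 1
        if steps > _COMPLETION_BUDGET:
            raise ResourceLimitError("halfspace completion budget exceeded")
        ip, im = queue.popleft()
        c_np = S_np[ip] + S_np[im]
        c = tuple(int(x) for x in c_np)
        if not any(c) or c in members:
            continue
        ac = int(c_np @ a_np)
        # reducibility: exists s in S with compatible a-sign and c - s feasible
        # for all previously processed halfspaces
        if ac >= 0:
            sign_ok = (aval >= 0) & (aval <= ac)
        else:
            sign_ok = (aval <= 0) & (aval >= ac)
        if np.any(sign_ok):
            diffs = c_np - S_np[sign_ok]
            nz = np.any(diffs != 0, axis=1)
            if nz.any() and np.all(diffs[nz] @ prevT >= 0, axis=1).any():
                continue
        members.add(c)
        idx = len(S)
        S.append(c)
        S_np = np.vstack([S_np, c_np])
        aval = np.append(aval, ac)
        if ac > 0:
            queue.extend((idx, m) for m in neg)
            pos.append(idx)
        elif ac < 0:
            queue.extend((p, idx) for p in pos)
            neg.append(idx)
    keep = [s for s, v in zip(S, aval) if v >= 0]
    return keep


def _reduce_to_basis(S: List[IntVec], all_rows: List[IntVec],
                     base: List[IntVec]) -> List[IntVec]:
    """Degree-graded global reduction: keep exactly the irreducible elements."""
    if not S:
        return []
    d = len(S[0])
    w = tuple(sum(r[j] for r in base) for j in range(d))  # > 0 on the monoid
    uniq = sorted(set(S), key=lambda v: (dot(w, v), v))
    rowsT = np.array(all_rows, dtype=np.int64).T
    kept: List[IntVec] = []
    kept_np = np.zeros((0, d), dtype=np.int64)
    for v in uniq:
        if not any(v):
            continue
        v_np = np.array(v, dtype=np.int64)
        if len(kept):
            diffs = v_np - kept_np
            nz = np.any(diffs != 0, axis=1)
            if nz.any() and np.all(diffs[nz] @ rowsT >= 0, axis=1).any():
                continue
        kept.append(v)
        kept_np = np.vstack([kept_np, v_np])
    return kept


# ---------------------------------------------------------------------------
# decomposition witness (generation property)
# ---------------------------------------------------------------------------

def decompose(v: Sequence[int], basis: HilbertBasis) -> Optional[Dict[IntVec, int]]:
    """Non-negative integer coefficients over basis elements summing to v.

    Returns ``None`` when v is outside the monoid.  Existence is guaranteed
    for monoid members when the basis is correct.
    """
    if basis.cone is None:
        raise ValueError("basis has no attached cone")
    vt = tuple(int(x) for x in v)
    if not is_in_monoid(vt, basis.cone):
        return None
    rows = [r for r in basis.cone.generators if any(r)]
    d = basis.cone.ambient_dim
    w = tuple(sum(r[j] for r in rows) for j in range(d))
    elems = sorted(basis.elements, key=lambda e: -dot(w, e))
    dead: set = set()

    def rec(u: IntVec) -> Optional[List[IntVec]]:
        if not any(u):
            return []
        if u in dead:
            return None
        du = dot(w, u)
        for e in elems:
            if dot(w, e) > du:
                continue
            r = tuple(a - b for a, b in zip(u, e))
            if all(dot(r, c) >= 0 for c in rows):
                sub = rec(r)
                if sub is not None:
                    return [e] + sub
        dead.add(u)
        return None

    parts = rec(vt)
    if parts is None:  # should not happen for a correct basis
        raise ResourceLimitError("no decomposition found for a monoid member")
    out: Dict[IntVec, int] = {}
    for e in parts:
        out[e] = out.get(e, 0) + 1
    return out


# ---------------------------------------------------------------------------
# special cones
# ---------------------------------------------------------------------------

def magic_square_cone(k: int) -> RationalCone:
    """Constraint cone whose dual monoid is the k x k magic squares
    (non-negative integer matrices with all row and column sums equal)."""
    d = k * k
    gens: List[IntVec] = []
    for i in range(d):
        gens.append(tuple(int(i == j) for j in range(d)))

    def line(indices) -> List[int]:
        v = [0] * d
        for idx in indices:
            v[idx] = 1
        return v

    eqs: List[List[int]] = []
    row0 = line(range(k))
    for i in range(1, k):
        ri = line(range(i * k, i * k + k))
        eqs.append([a - b for a, b in zip(ri, row0)])
    for j in range(k):
        cj = line(range(j, d, k))
        eqs.append([a - b for a, b in zip(cj, row0)])
    for e in eqs:
        if any(e):
            gens.append(tuple(e))
            gens.append(tuple(-x for x in e))
    return RationalCone.from_rows(gens, ambient_dim=d)


# ---------------------------------------------------------------------------
# Normaliz plain-text interchange
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizDocument:
    """One matrix block of the classic Normaliz plain dialect."""

    matrix: Tuple[IntVec, ...]
    input_type: str = "integral_closure"

    @property
    def nrows(self) -> int:
        return len(self.matrix)

    @property
    def ncols(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0


def write_normaliz(cone: RationalCone, path, input_type: str = "integral_closure") -> None:
    """Classic plain format: row count, column count, rows, type keyword."""
    lines = [str(len(cone.generators)), str(cone.ambient_dim)]
    for g in cone.generators:
        lines.append(" ".join(str(x) for x in g))
    lines.append(input_type)
    Path(path).write_text("\n".join(lines) + "\n")


def read_normaliz(path) -> RationalCone:
    """Parse a classic plain-format cone file; errors carry line numbers."""
    doc = read_normaliz_document(path)
    return RationalCone.from_rows(doc.matrix, ambient_dim=doc.ncols)


def read_normaliz_document(path) -> NormalizDocument:
    raw = Path(path).read_text().splitlines()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw)
             if ln.strip() and not ln.strip().startswith("/*")]
    if len(lines) < 2:
        raise NormalizParseError("expected row and column counts", 1)
    try:
        nrows = int(lines[0][1])
    except ValueError:
        raise NormalizParseError(f"bad row count {lines[0][1]!r}", lines[0][0]) from None
    try:
        ncols = int(lines[1][1])
    except ValueError:
        raise NormalizParseError(f"bad column count {lines[1][1]!r}", lines[1][0]) from None
    if len(lines) < 2 + nrows:
        last = lines[-1][0] if lines else 1
        raise NormalizParseError(f"expected {nrows} matrix rows", last)
    matrix: List[IntVec] = []
    for lineno, text in lines[2:2 + nrows]:
        parts = text.split()
        if len(parts) != ncols:
            raise NormalizParseError(
                f"expected {ncols} entries, got {len(parts)}", lineno)
        try:
            matrix.append(tuple(int(p) for p in parts))
        except ValueError:
            raise NormalizParseError(f"non-integer entry in {text!r}", lineno) from None
    input_type = "integral_closure"
    if len(lines) > 2 + nrows:
        input_type = lines[2 + nrows][1].split()[0]
    return NormalizDocument(matrix=tuple(matrix), input_type=input_type)


_HB_HEADER = re.compile(r"^\s*(\d+)\s+Hilbert basis elements")


def parse_normaliz_output(path) -> HilbertBasis:
    """Extract the Hilbert-basis block from a Normaliz ``.out`` file."""
    raw = Path(path).read_text().splitlines()
    for i, ln in enumerate(raw):
        m = _HB_HEADER.match(ln)
        if m:
            count = int(m.group(1))
            elements: List[IntVec] = []
            j = i + 1
            while j < len(raw) and len(elements) < count:
                parts = raw[j].split()
                if parts and all(re.fullmatch(r"-?\d+", p) for p in parts):
                    elements.append(tuple(int(p) for p in parts))
                elif elements:
                    break
                j += 1
            if len(elements) != count:
                raise NormalizParseError(
                    f"expected {count} basis vectors, found {len(elements)}", i + 1)
            return HilbertBasis(elements=tuple(elements), cone=None)
    raise NormalizParseError("no Hilbert basis section found", len(raw))


def write_normaliz_output(basis: HilbertBasis, path) -> None:
    lines = [f"{len(basis.elements)} Hilbert basis elements:", ""]
    for e in basis.elements:
        lines.append(" " + " ".join(str(x) for x in e))
    Path(path).write_text("\n".join(lines) + "\n")


def run_normaliz(cone: RationalCone, binary: str = "normaliz") -> HilbertBasis:
    """Shell out to an external Normaliz binary (optional cross-check backend).

    The cone rows are passed as ``inequalities`` so the external computation
    matches the native dual-monoid semantics.  Raises ``FileNotFoundError``
    with guidance when the binary is absent.
    """
    exe = shutil.which(binary)
    if exe is None:
        raise FileNotFoundError(
            f"Normaliz binary {binary!r} not found on PATH; install Normaliz or "
            "use the native backend")
    with tempfile.TemporaryDirectory() as td:
        inpath = Path(td) / "cone.in"
        write_normaliz(cone, inpath, input_type="inequalities")
        subprocess.run([exe, str(inpath)], check=True, capture_output=True)
        return parse_normaliz_output(Path(td) / "cone.out")
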