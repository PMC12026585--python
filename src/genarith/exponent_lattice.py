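"""Exponent-space lattice vectors, per-species cone matrices, dual sampling.

Step 2 of the workflow turns each rate equation into homogenized lattice
vectors (one per monomial after the rational-function rewrite clears negative
exponents), orders them lexicographically, and builds the gene-interaction
matrix whose interior rows are adjacent-pair differences.  Step 3 turns each
such matrix into square integer "dual" matrices: rows are integer vectors with
non-negative inner product against every cone row, drawn either
deterministically (shortest vectors, reverse-lex tie-break, independent rows)
or by seeded sampling with Boltzmann weights ``exp(-|v|^2 / T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._intlinalg import SpanTracker, dot, primitivize
from .gexpr import GExpr, GExprLike, as_gexpr, dominated_min
from .powerlaw_cascade import SSystemEquation

__all__ = [
    "LatticeVector",
    "GeneInteractionMatrix",
    "BoltzmannConfig",
    "StructureError",
    "AmbiguousSymbolicOrderError",
    "InsufficientCandidatesError",
    "exponent_vectors",
    "build_cone_matrix",
    "boltzmann_dual_matrices",
    "candidate_pool",
]


class StructureError(ValueError):
    """Shape/structure violation while assembling a cone matrix."""


class AmbiguousSymbolicOrderError(ValueError):
    """An ordering/min involving the symbolic g is undecidable; substitute it."""


class InsufficientCandidatesError(RuntimeError):
    """Too few dual-feasible vectors inside the search radius."""


@dataclass(frozen=True)
class LatticeVector:
    """A homogenized exponent vector: n species entries plus one extra slot."""

    entries: Tuple[GExpr, ...]
    homogenizing_coordinate: GExpr = field(default_factory=lambda: as_gexpr(1))

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(as_gexpr(e) for e in self.entries))
        object.__setattr__(self, "homogenizing_coordinate",
                           as_gexpr(self.homogenizing_coordinate))
        n_sym = sum(e.is_symbolic for e in self.full)
        if n_sym > 1:
            raise StructureError("at most one symbolic entry per lattice vector")

    @property
    def full(self) -> Tuple[GExpr, ...]:
        """Entries with the homogenizing coordinate appended (length n + 1)."""
        return self.entries + (self.homogenizing_coordinate,)

    @property
    def dimension(self) -> int:
        return len(self.entries) + 1

    @property
    def is_symbolic(self) -> bool:
        return any(e.is_symbolic for e in self.full)

    def subs(self, g_value) -> Tuple[Fraction, ...]:
        return tuple(e.subs(g_value) for e in self.full)

    def __sub__(self, other: "LatticeVector") -> "LatticeVector":
        if self.dimension != other.dimension:
            raise StructureError("dimension mismatch in lattice subtraction")
        return LatticeVector(
            entries=tuple(a - b for a, b in zip(self.entries, other.entries)),
            homogenizing_coordinate=self.homogenizing_coordinate - other.homogenizing_coordinate,
        )

    def strip_homogenization(self) -> Tuple[GExpr, ...]:
        return self.entries


def _lex_key(vec: LatticeVector, g_value: Optional[Fraction]):
    if g_value is not None:
        return vec.subs(g_value)
    out = []
    for e in vec.full:
        if e.is_symbolic:
            raise AmbiguousSymbolicOrderError(
                "lexicographic position of a symbolic entry needs a g value")
        out.append(e.const)
    return tuple(out)


def _lex_less_symbolic(a: LatticeVector, b: LatticeVector) -> bool:
    """Strict lex compare decidable for all g >= 0; raises when it is not."""
    for x, y in zip(a.full, b.full):
        le = x.le_for_all_g(y)
        ge = y.le_for_all_g(x)
        if le and ge:  # equal for all g
            continue
        if le is True and ge is False:
            return True
        if ge is True and le is False:
            return False
        raise AmbiguousSymbolicOrderError(
            "lexicographic order depends on the value of g; substitute a candidate")
    return False


def exponent_vectors(equation: SSystemEquation, n: int) -> List[LatticeVector]:
    """One homogenized lattice vector per monomial term of the equation.

    The equation is treated as a rational function and rewritten with all
    exponents in the numerator: any negative exponent column is cleared by
    multiplying every term by the common denominator monomial, so degradation
    and feedback exponents re-appear with positive sign on the other terms.
    """
    terms = list(equation.production) + list(equation.degradation)
    raw = [[as_gexpr(e) for e in t.exponents] for t in terms]
    zero = as_gexpr(0)
    shifts = []
    for j in range(n):
        col_min = dominated_min([row[j] for row in raw])
        neg = col_min.le_for_all_g(zero)
        shifts.append(-col_min if (neg and not col_min.is_zero) else zero)
    vecs = []
    for row in raw:
        vecs.append(LatticeVector(
            entries=tuple(e + s for e, s in zip(row, shifts)),
            homogenizing_coordinate=as_gexpr(1)))
    return vecs


@dataclass(frozen=True)
class GeneInteractionMatrix:
    """Lattice-cone matrix: lex-ordered originals with interior differences."""

    species_index: int
    rows: Tuple[LatticeVector, ...]
    provenance: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.provenance):
            raise StructureError("provenance must cover every row")
        if self.provenance[0] != "original" or self.provenance[-1] != "original":
            raise StructureError("first and last rows must be original vectors")

    @property
    def dimension(self) -> int:
        return self.rows[0].dimension

    def numeric_rows(self, g_value=None) -> List[Tuple[int, ...]]:
        """Primitive integer rows with g substituted; zero rows dropped."""
        out = []
        for r in self.rows:
            if r.is_symbolic and g_value is None:
                raise AmbiguousSymbolicOrderError("numeric rows need a g value")
            vals = r.subs(g_value) if r.is_symbolic else tuple(e.exact() for e in r.full)
            row = primitivize(vals)
            if any(row):
                out.append(row)
        # drop duplicates, keep order
        seen, uniq = set(), []
        for row in out:
            if row not in seen:
                seen.add(row)
                uniq.append(row)
        return uniq


def build_cone_matrix(vectors: Sequence[LatticeVector],
                      g_value: Optional[Fraction] = None,
                      species_index: int = 0) -> GeneInteractionMatrix:
    """Sort vectors lexicographically and insert adjacent-pair differences.

    Rows come out as ``[first original, diffs..., last original]`` with k - 1
    difference rows for k originals.  Symbolic entries are ordered by the
    substituted candidate ``g_value`` when given, else only if the order is
    decidable for every g >= 0.
    """
    vecs = list(vectors)
    if len(vecs) < 2:
        raise StructureError("need at least 2 lattice vectors")
    if any(v.dimension != vecs[0].dimension for v in vecs):
        raise StructureError("mixed lattice dimensions")
    if g_value is not None or not any(v.is_symbolic for v in vecs):
        vecs.sort(key=lambda v: _lex_key(v, g_value))
    else:
        # insertion sort with the symbolically decidable comparator
        ordered: List[LatticeVector] = []
        for v in vecs:
            k = len(ordered)
            while k > 0 and _lex_less_symbolic(v, ordered[k - 1]):
                k -= 1
            ordered.insert(k, v)
        vecs = ordered
    rows = [vecs[0]]
    prov = ["original"]
    for a, b in zip(vecs[:-1], vecs[1:]):
        rows.append(b - a)
        prov.append("difference")
    rows.append(vecs[-1])
    prov.append("original")
    return GeneInteractionMatrix(species_index=species_index,
                                 rows=tuple(rows), provenance=tuple(prov))


@dataclass(frozen=True)
class BoltzmannConfig:
    """Reproducible sampling configuration for the dual-matrix step."""

    temperature: float = 1.0
    seed: int = 0
    search_radius: int = 2
    sample_count: int = 1
    mode: str = "deterministic"  # or "stochastic"

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.search_radius <= 0 or self.sample_count <= 0:
            raise ValueError("temperature, search_radius and sample_count must be positive")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")


@lru_cache(maxsize=128)
def candidate_pool(dim: int, radius: int) -> Tuple[Tuple[int, ...], ...]:
    """All nonzero integer vectors with ||v||^2 <= radius^2, sorted by
    (norm^2, reverse-lexicographic) so that +e_j precedes -e_j."""
    budget = radius * radius
    out: List[Tuple[int, ...]] = []

    def rec(prefix: List[int], remaining: int, pos: int) -> None:
        if pos == dim:
            if any(prefix):
                out.append(tuple(prefix))
            return
        r = int(remaining ** 0.5)
        while (r + 1) * (r + 1) <= remaining:
            r += 1
        for v in range(-r, r + 1):
            prefix.append(v)
            rec(prefix, remaining - v * v, pos + 1)
            prefix.pop()

    rec([], budget, 0)
    out.sort(key=lambda v: (sum(x * x for x in v), tuple(-x for x in v)))
    return tuple(out)


def _feasible(pool, cone_rows) -> List[Tuple[int, ...]]:
    if not cone_rows:
        return list(pool)
    P = np.array(pool, dtype=np.int64)
    C = np.array(cone_rows, dtype=np.int64)
    ok = np.all(P @ C.T >= 0, axis=1)
    return [pool[i] for i in np.nonzero(ok)[0]]


def boltzmann_dual_matrices(cone: GeneInteractionMatrix, config: BoltzmannConfig,
                            g_value: Optional[Fraction] = None) -> List[np.ndarray]:
    """Square integer matrices whose rows are dual-feasible for the cone.

    Deterministic mode returns one matrix: the shortest feasible vectors
    (reverse-lex tie-break) greedily kept while they enlarge the linear span,
    until the matrix is square of size n + 1.  Stochastic mode returns
    ``sample_count`` matrices sampled without replacement with probability
    proportional to ``exp(-|v|^2 / temperature)`` under the fixed seed.
    """
    rows = cone.numeric_rows(g_value)
    d = cone.dimension
    pool = candidate_pool(d, config.search_radius)
    feas = _feasible(pool, rows)
    if len(feas) < d:
        raise InsufficientCandidatesError(
            f"only {len(feas)} dual-feasible vectors within radius "
            f"{config.search_radius}; raise search_radius")
    if config.mode == "deterministic":
        tracker = SpanTracker(d)
        chosen: List[Tuple[int, ...]] = []
        for v in feas:
            if tracker.add(v):
                chosen.append(v)
            if len(chosen) == d:
                break
        if len(chosen) < d:
            raise InsufficientCandidatesError(
                f"dual-feasible vectors within radius {config.search_radius} "
                f"span only rank {len(chosen)} < {d}; raise search_radius")
        return [np.array(chosen, dtype=np.int64)]
    rng = np.random.default_rng(config.seed)
    norms = np.array([sum(x * x for x in v) for v in feas], dtype=float)
    w = np.exp(-norms / config.temperature)
    w = w / w.sum()
    mats = []
    for _ in range(config.sample_count):
        idx = rng.choice(len(feas), size=d, replace=False, p=w)
        idx = np.sort(idx)  # deterministic row order given the selection
        mats.append(np.array([feas[i] for i in idx], dtype=np.int64))
    return mats
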