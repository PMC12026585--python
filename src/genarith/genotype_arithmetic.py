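"""Fixed-point constraints on the unknown order and the prediction pipeline.

Step 5 of the workflow: pair the symbolic lattice vector ``b(g)`` of the
feedback equation with geometric basis vectors; the requirement that every
monomial limit stays finite at the torus boundary is exactly
``<b(g), h_j> >= 0`` for every basis element ``h_j``, a system of affine
inequalities in g.  On top of that this module aggregates the per-cone
permuted-identity bases into an exactly bistochastic matrix, interprets its
entries as genotype/phenotype ratios, selects the maximum-projection rows,
and ties everything together in :func:`predict_binding_sites`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._intlinalg import dot
from .config import RunConfig
from .exponent_lattice import (BoltzmannConfig, GeneInteractionMatrix,
                               LatticeVector, boltzmann_dual_matrices,
                               build_cone_matrix, exponent_vectors)
from .gexpr import GExpr, as_gexpr
from .hilbert_monoid import HilbertBasis, RationalCone, hilbert_basis, run_normaliz
from .powerlaw_cascade import (CascadeModel, StabilityReport,
                               build_end_product_cascade, linearize_and_classify)

__all__ = [
    "GConstraint",
    "ConstraintSystem",
    "GRange",
    "BistochasticMatrix",
    "PredictionReport",
    "PipelineError",
    "CompletionError",
    "BistochasticityError",
    "fixed_point_constraints",
    "solve_g_range",
    "aggregate_bistochastic",
    "genotype_phenotype_ratios",
    "max_projection_rows",
    "permutation_from_basis",
    "cascade_cones",
    "symbolic_feedback_vector",
    "predict_binding_sites",
]

IntVec = Tuple[int, ...]


class PipelineError(RuntimeError):
    """Failure in a pipeline stage; carries the stage label."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class CompletionError(ValueError):
    """A Hilbert basis cannot be completed to a permuted identity matrix."""


class BistochasticityError(ValueError):
    """Aggregate line sums are not all 1 (generators were not permutations)."""


# ---------------------------------------------------------------------------
# constraint system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GConstraint:
    """The inequality ``coeff_g * g + constant >= 0``."""

    coeff_g: Fraction
    constant: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeff_g", Fraction(self.coeff_g))
        object.__setattr__(self, "constant", Fraction(self.constant))

    @property
    def vacuous(self) -> bool:
        return self.coeff_g == 0 and self.constant >= 0

    def holds_at(self, g: Fraction) -> bool:
        return self.coeff_g * Fraction(g) + self.constant >= 0


@dataclass(frozen=True)
class ConstraintSystem:
    constraints: Tuple[GConstraint, ...]
    source: Tuple[str, ...]  # provenance, aligned with constraints

    def __post_init__(self) -> None:
        if len(self.constraints) != len(self.source):
            raise ValueError("provenance must cover every constraint")

    def __len__(self) -> int:
        return len(self.constraints)

    def holds_at(self, g) -> bool:
        return all(c.holds_at(g) for c in self.constraints)

    @staticmethod
    def merge(systems: Sequence["ConstraintSystem"]) -> "ConstraintSystem":
        cons: List[GConstraint] = []
        srcs: List[str] = []
        seen = set()
        for sys_ in systems:
            for c, s in zip(sys_.constraints, sys_.source):
                key = (c.coeff_g, c.constant, s)
                if key not in seen:
                    seen.add(key)
                    cons.append(c)
                    srcs.append(s)
        return ConstraintSystem(tuple(cons), tuple(srcs))


def fixed_point_constraints(basis: Union[HilbertBasis, Sequence[Sequence[int]]],
                            b: LatticeVector,
                            source: str = "") -> ConstraintSystem:
    """One constraint ``<b(g), h_j> >= 0`` per basis element ``h_j``.

    The limit of the monomial ``X ** <b, h>`` as X -> 0 is finite exactly when
    the exponent is non-negative, so each basis vector contributes one affine
    inequality in g.
    """
    elements = basis.elements if isinstance(basis, HilbertBasis) else \
        [tuple(int(x) for x in e) for e in basis]
    bfull = b.full
    cons: List[GConstraint] = []
    srcs: List[str] = []
    for h in elements:
        if len(h) != len(bfull):
            raise ValueError(f"dimension mismatch: basis element {h} vs b of "
                             f"length {len(bfull)}")
        expr = as_gexpr(0)
        for coeff, hj in zip(bfull, h):
            expr = expr + coeff * Fraction(hj)
        cons.append(GConstraint(coeff_g=expr.gcoef, constant=expr.const))
        srcs.append(f"{source}|h={','.join(map(str, h))}")
    return ConstraintSystem(tuple(cons), tuple(srcs))


# ---------------------------------------------------------------------------
# g range
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GRange:
    """Admissible interval for g; ``None`` bounds mean unbounded."""

    lower: Optional[Fraction]
    upper: Optional[Fraction]
    integer_candidates: Tuple[int, ...]
    truncated: bool = False
    empty: bool = False

    def contains(self, g) -> bool:
        if self.empty:
            return False
        gq = Fraction(g)
        if self.lower is not None and gq < self.lower:
            return False
        if self.upper is not None and gq > self.upper:
            return False
        return True


def _range_from_bounds(lower: Optional[Fraction], upper: Optional[Fraction],
                       candidate_cap: int) -> GRange:
    if lower is not None and upper is not None and lower > upper:
        return GRange(lower=lower, upper=upper, integer_candidates=(),
                      truncated=False, empty=True)
    truncated = False
    if lower is None:
        lo_i, truncated = -candidate_cap, True
    else:
        lo_i = math.ceil(lower)
    if upper is None:
        hi_i, truncated = candidate_cap, True
    else:
        hi_i = math.floor(upper)
    cands = tuple(range(lo_i, hi_i + 1))
    return GRange(lower=lower, upper=upper, integer_candidates=cands,
                  truncated=truncated)


def solve_g_range(system: ConstraintSystem, mode: str = "intersect",
                  candidate_cap: int = 12) -> GRange:
    """Solve the inequality system for g.

    ``intersect``: tightest interval satisfying every constraint individually.
    ``summed``: the single interval of the constraint obtained by summing all
    (coeff_g, constant) pairs — a strictly weaker aggregation, kept because it
    is the literally stated rule.  Integer candidates of unbounded intervals
    are truncated at ``candidate_cap`` and flagged.
    """
    if not len(system):
        raise ValueError("empty constraint system")
    if mode not in ("intersect", "summed"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "summed":
        K = sum((c.coeff_g for c in system.constraints), Fraction(0))
        C = sum((c.constant for c in system.constraints), Fraction(0))
        pairs = [(K, C)]
    else:
        pairs = [(c.coeff_g, c.constant) for c in system.constraints]
    lower: Optional[Fraction] = None
    upper: Optional[Fraction] = None
    for k, c in pairs:
        if k == 0:
            if c < 0:  # infeasible constant constraint
                return GRange(lower=Fraction(0), upper=Fraction(-1),
                              integer_candidates=(), empty=True)
            continue
        bound = -c / k
        if k > 0:
            lower = bound if lower is None else max(lower, bound)
        else:
            upper = bound if upper is None else min(upper, bound)
    return _range_from_bounds(lower, upper, candidate_cap)


# ---------------------------------------------------------------------------
# bistochastic aggregation
# ---------------------------------------------------------------------------

FracMat = Tuple[Tuple[Fraction, ...], ...]


def _as_frac_matrix(mat) -> FracMat:
    return tuple(tuple(Fraction(int(x)) if isinstance(x, (int, np.integer))
                       else Fraction(x) for x in row) for row in mat)


@dataclass(frozen=True)
class BistochasticMatrix:
    """Exact rational doubly stochastic aggregate of generator matrices."""

    values: FracMat
    divisor: int
    components: Tuple[FracMat, ...]

    @property
    def size(self) -> int:
        return len(self.values)

    def line_sums(self) -> Tuple[Tuple[Fraction, ...], Tuple[Fraction, ...]]:
        rows = tuple(sum(r, Fraction(0)) for r in self.values)
        cols = tuple(sum(r[j] for r in self.values) for j in range(self.size))
        return rows, cols

    def as_float(self) -> np.ndarray:
        return np.array([[float(x) for x in r] for r in self.values])


def aggregate_bistochastic(generator_matrices: Sequence, divisor: int) -> BistochasticMatrix:
    """Sum the generator matrices and divide by ``divisor`` (exact rationals).

    Raises :class:`BistochasticityError` unless every row and column sum of
    the result equals 1 and all entries are non-negative — the diagnostic that
    fires when upstream generators are not permutation matrices.
    """
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    comps = [_as_frac_matrix(m) for m in generator_matrices]
    if not comps:
        raise ValueError("no generator matrices")
    size = len(comps[0])
    for m in comps:
        if len(m) != size or any(len(r) != size for r in m):
            raise ValueError("generator matrices must all be square of equal size")
    values = tuple(
        tuple(sum(m[i][j] for m in comps) / divisor for j in range(size))
        for i in range(size))
    M = BistochasticMatrix(values=values, divisor=divisor, components=tuple(comps))
    rows, cols = M.line_sums()
    if any(x < 0 for r in values for x in r):
        raise BistochasticityError("aggregate has negative entries")
    bad = [s for s in rows + cols if s != 1]
    if bad:
        raise BistochasticityError(
            f"line sums are not all 1 (got {sorted(set(map(str, bad)))}); "
            "upstream generators are not permutation matrices")
    return M


def genotype_phenotype_ratios(M: BistochasticMatrix) -> FracMat:
    """Entries of M read as binding-site occupancy probabilities.

    The matrix entries already are the genotype/phenotype ratios; this is the
    semantic relabeling, kept as an operation for report clarity.
    """
    return M.values


def max_projection_rows(M: BistochasticMatrix, b: LatticeVector,
                        g_value) -> List[int]:
    """0-based indices of all rows attaining the maximal inner product with
    b(g_value); ties are all reported in ascending order."""
    bvals = b.subs(g_value)
    if len(bvals) != M.size:
        raise ValueError(f"dimension mismatch: b has {len(bvals)}, M is {M.size}")
    dots = [sum(r[j] * bvals[j] for j in range(M.size)) for r in M.values]
    best = max(dots)
    return [i for i, v in enumerate(dots) if v == best]


# ---------------------------------------------------------------------------
# permuted-identity completion
# ---------------------------------------------------------------------------

def permutation_from_basis(basis: Union[HilbertBasis, Sequence[Sequence[int]]],
                           dim: int) -> np.ndarray:
    """Complete a Hilbert basis to a permuted identity matrix.

    Every element must be a unit vector ``e_a`` or a difference ``e_a - e_b``;
    each difference contributes the transposition (a b), and the permutation
    matrix is the product of those transpositions (applied in sorted order)
    acting on the identity.  Anything else raises :class:`CompletionError`:
    for the end-product-inhibition family the bases are exactly of this shape.
    """
    elements = basis.elements if isinstance(basis, HilbertBasis) else \
        [tuple(int(x) for x in e) for e in basis]
    swaps: List[Tuple[int, int]] = []
    for h in elements:
        if len(h) != dim:
            raise CompletionError(f"element {h} has wrong dimension (need {dim})")
        pos = [i for i, x in enumerate(h) if x > 0]
        neg = [i for i, x in enumerate(h) if x < 0]
        if len(pos) == 1 and not neg and h[pos[0]] == 1:
            continue  # unit vector: contributes the identity on its coordinate
        if len(pos) == 1 and len(neg) == 1 and h[pos[0]] == 1 and h[neg[0]] == -1:
            swaps.append((pos[0], neg[0]))
            continue
        raise CompletionError(
            f"basis element {h} is neither a unit nor a difference vector")
    perm = list(range(dim))
    for a, b_ in sorted(swaps):
        perm[a], perm[b_] = perm[b_], perm[a]
    P = np.zeros((dim, dim), dtype=np.int64)
    for i, j in enumerate(perm):
        P[i, j] = 1
    return P


# ---------------------------------------------------------------------------
# cone assembly for a cascade
# ---------------------------------------------------------------------------

def symbolic_feedback_vector(model: CascadeModel) -> LatticeVector:
    """The g-carrying homogenized lattice vector of the feedback equation."""
    vecs = exponent_vectors(model.equations[0], model.n)
    for v in vecs:
        if v.is_symbolic:
            return v
    raise PipelineError("step2:lattice", "model has no symbolic lattice vector")


def cascade_cones(model: CascadeModel, g_value,
                  ) -> List[Tuple[str, GeneInteractionMatrix]]:
    """Per-species lattice cones plus the normalization constraint cone D.

    D is built from the all-ones lattice vector together with the bare
    homogenizing unit; it contributes the extra cone that makes the
    aggregation divisor equal species + constraints.
    """
    n = model.n
    cones: List[Tuple[str, GeneInteractionMatrix]] = []
    for eq in model.equations:
        vecs = exponent_vectors(eq, n)
        cones.append((f"X{eq.species_index}",
                      build_cone_matrix(vecs, g_value=Fraction(g_value),
                                        species_index=eq.species_index)))
    zero = LatticeVector(entries=tuple(as_gexpr(0) for _ in range(n)))
    ones = LatticeVector(entries=tuple(as_gexpr(1) for _ in range(n)))
    cones.append(("D", build_cone_matrix([zero, ones], g_value=Fraction(g_value),
                                         species_index=0)))
    return cones


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeArtifacts:
    """Everything the pipeline derived for one cone at one candidate g."""

    label: str
    cone_rows: Tuple[IntVec, ...]
    dual_matrix: Tuple[IntVec, ...]
    basis: HilbertBasis
    permutation: Tuple[IntVec, ...]


@dataclass(frozen=True)
class PredictionReport:
    n: int
    config: RunConfig
    g_range: GRange                      # intersect mode (default)
    g_range_summed: GRange
    constraint_system: ConstraintSystem
    divisor: int
    bistochastic: BistochasticMatrix
    ratios: FracMat
    max_projection_rows: Tuple[int, ...]
    projection_g: int
    stability_at_candidates: Dict[int, str]
    admissible_candidates: Tuple[int, ...]
    artifacts: Tuple[ConeArtifacts, ...]
    eigenvalues_at_candidates: Dict[int, Tuple[complex, ...]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def frac(x):
            return str(Fraction(x))

        def rng(r: GRange):
            return {
                "lower": None if r.lower is None else frac(r.lower),
                "upper": None if r.upper is None else frac(r.upper),
                "integer_candidates": list(r.integer_candidates),
                "truncated": r.truncated,
                "empty": r.empty,
            }

        return {
            "n": self.n,
            "config": self.config.to_dict(),
            "g_range": rng(self.g_range),
            "g_range_summed": rng(self.g_range_summed),
            "constraints": [
                {"coeff_g": frac(c.coeff_g), "constant": frac(c.constant), "source": s}
                for c, s in zip(self.constraint_system.constraints,
                                self.constraint_system.source)
            ],
            "divisor": self.divisor,
            "bistochastic": [[frac(x) for x in row] for row in self.bistochastic.values],
            "ratios": [[frac(x) for x in row] for row in self.ratios],
            "max_projection_rows": list(self.max_projection_rows),
            "projection_g": self.projection_g,
            "stability_at_candidates": {str(k): v for k, v in
                                        sorted(self.stability_at_candidates.items())},
            "admissible_candidates": list(self.admissible_candidates),
            "artifacts": [
                {
                    "label": a.label,
                    "cone_rows": [list(r) for r in a.cone_rows],
                    "dual_matrix": [list(r) for r in a.dual_matrix],
                    "hilbert_basis": [list(e) for e in a.basis.elements],
                    "permutation": [list(r) for r in a.permutation],
                }
                for a in self.artifacts
            ],
        }


def _geometry_at(model: CascadeModel, gamma: int, bconf: BoltzmannConfig,
                 backend: str) -> List[ConeArtifacts]:
    arts: List[ConeArtifacts] = []
    for label, cone in cascade_cones(model, gamma):
        try:
            mats = boltzmann_dual_matrices(cone, bconf, g_value=Fraction(gamma))
        except Exception as exc:
            raise PipelineError("step3:boltzmann", f"cone {label} at g={gamma}: {exc}")
        dual = mats[0]
        rcone = RationalCone.from_rows([tuple(int(x) for x in r) for r in dual])
        try:
            if backend == "normaliz":
                basis = run_normaliz(rcone)
                basis = HilbertBasis(elements=basis.elements, cone=rcone)
            else:
                basis = hilbert_basis(rcone)
        except Exception as exc:
            raise PipelineError("step4:hilbert", f"cone {label} at g={gamma}: {exc}")
        try:
            perm = permutation_from_basis(basis, cone.dimension)
        except CompletionError as exc:
            raise PipelineError("step4:hilbert", f"cone {label} at g={gamma}: {exc}")
        arts.append(ConeArtifacts(
            label=label,
            cone_rows=tuple(cone.numeric_rows(Fraction(gamma))),
            dual_matrix=tuple(tuple(int(x) for x in r) for r in dual),
            basis=basis,
            permutation=tuple(tuple(int(x) for x in r) for r in perm),
        ))
    return arts


def predict_binding_sites(n: int, config: Optional[RunConfig] = None) -> PredictionReport:
    """End-to-end prediction of the unknown feedback order for a length-n cascade.

    Builds the cascade, sweeps integer candidates 0..g_max (the geometry needs
    numeric exponents), derives the fixed-point constraint system from the
    permuted-identity bases at each candidate, keeps self-consistent
    candidates, solves the g range in both modes, aggregates the permutation
    matrices into the bistochastic matrix, and classifies stability at every
    integer candidate.  Fully deterministic under a fixed seed.
    """
    if config is None:
        try:
            config = RunConfig(n=n)
        except ValueError as exc:
            raise PipelineError("config", str(exc))
    if config.n != n:
        raise PipelineError("config", f"config.n={config.n} does not match n={n}")
    if not 3 <= n <= 12:
        raise PipelineError("config", f"pathway length must be in 3..12, got {n}")

    try:
        model = build_end_product_cascade(n, alpha=config.alpha, beta=config.beta,
                                          h=config.h)
    except Exception as exc:
        raise PipelineError("step1:model", str(exc))
    b = symbolic_feedback_vector(model)
    bconf = BoltzmannConfig(temperature=config.temperature, seed=config.seed,
                            search_radius=config.search_radius,
                            sample_count=config.sample_count,
                            mode=config.sample_mode)

    systems: Dict[int, ConstraintSystem] = {}
    artifacts_by_g: Dict[int, List[ConeArtifacts]] = {}
    admissible: List[int] = []
    for gamma in range(0, config.g_max + 1):
        arts = _geometry_at(model, gamma, bconf, config.backend)
        artifacts_by_g[gamma] = arts
        per_cone = [fixed_point_constraints(a.permutation, b,
                                            source=f"{a.label}@g={gamma}")
                    for a in arts]
        sys_g = ConstraintSystem.merge(per_cone)
        systems[gamma] = sys_g
        if sys_g.holds_at(gamma):
            admissible.append(gamma)

    if not admissible:
        raise PipelineError("step5:constraints",
                            "no self-consistent integer candidate in 0..g_max")
    union = ConstraintSystem.merge([systems[g] for g in admissible])
    g_range = solve_g_range(union, "intersect", candidate_cap=config.g_max)
    g_range_summed = solve_g_range(union, "summed", candidate_cap=config.g_max)

    g_ref = admissible[0]
    arts_ref = artifacts_by_g[g_ref]
    divisor = len(arts_ref)  # species cones + constraint cones
    try:
        M = aggregate_bistochastic([a.permutation for a in arts_ref], divisor)
    except BistochasticityError as exc:
        raise PipelineError("aggregate", str(exc))
    ratios = genotype_phenotype_ratios(M)

    stability: Dict[int, str] = {}
    eigs: Dict[int, Tuple[complex, ...]] = {}
    for gamma in sorted(set(g_range.integer_candidates) | set(admissible)):
        if gamma < 0:
            continue
        try:
            rep: StabilityReport = linearize_and_classify(model, gamma)
        except Exception as exc:
            raise PipelineError("stability", f"g={gamma}: {exc}")
        stability[gamma] = rep.classification
        eigs[gamma] = tuple(complex(e) for e in rep.eigenvalues)

    stable_cands = [g for g, c in sorted(stability.items()) if c == "stable" and g > 0]
    projection_g = stable_cands[-1] if stable_cands else g_ref
    proj_rows = tuple(max_projection_rows(M, b, projection_g))

    return PredictionReport(
        n=n, config=config, g_range=g_range, g_range_summed=g_range_summed,
        constraint_system=union, divisor=divisor, bistochastic=M, ratios=ratios,
        max_projection_rows=proj_rows, projection_g=projection_g,
        stability_at_candidates=stability,
        admissible_candidates=tuple(admissible),
        artifacts=tuple(arts_ref),
        eigenvalues_at_candidates=eigs,
    )
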