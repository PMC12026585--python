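"""Power-law (S-system) models of end-product-inhibition cascades.

The model family is a linear chain ``X1 -> X2 -> ... -> Xn`` in which the end
product ``Xn`` inhibits the first (allosteric) step.  Each species has one
production and one degradation power-law term; the inhibitory feedback is
carried by the exponent of ``Xn`` in the first equation.  The feedback
strength ``g`` is stored as a *structural* non-negative order and applied with
a negative sign in the rate law (``Xn ** -g``), so reported values match the
binding-site count convention.

Provides exact model construction, rate evaluation, steady states (log-linear
solve with a damped-Newton fallback), stiff log-space simulation, and local
stability classification from the Jacobian spectrum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

from .gexpr import G, GExpr, GExprLike, as_gexpr

__all__ = [
    "PowerLawTerm",
    "SSystemEquation",
    "CascadeModel",
    "SteadyState",
    "StabilityReport",
    "InvalidCascadeError",
    "DomainError",
    "NonconvergenceError",
    "SimulationError",
    "SYMBOLIC",
    "build_end_product_cascade",
    "evaluate_rates",
    "solve_steady_state",
    "simulate",
    "linearize_and_classify",
    "model_to_json",
    "model_from_json",
]

#: Marker accepted by :func:`build_end_product_cascade` for the unknown order.
SYMBOLIC = "symbolic"


class InvalidCascadeError(ValueError):
    """Malformed cascade specification (length, rates, shapes)."""


class DomainError(ValueError):
    """Evaluation outside the domain of the power law (non-positive state)."""


class NonconvergenceError(RuntimeError):
    """Steady-state solve failed; carries diagnostics."""

    def __init__(self, message: str, last_state: Optional[np.ndarray] = None,
                 residual: Optional[float] = None) -> None:
        super().__init__(message)
        self.last_state = last_state
        self.residual = residual


class SimulationError(RuntimeError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message: str, t_last: float, state_last: np.ndarray) -> None:
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass(frozen=True)
class PowerLawTerm:
    """One monomial rate term ``rate_constant * prod_j Xj ** exponents[j]``."""

    rate_constant: float
    exponents: Tuple[GExpr, ...]

    def __post_init__(self) -> None:
        if not self.rate_constant > 0:
            raise DomainError(f"rate constant must be positive, got {self.rate_constant}")
        object.__setattr__(self, "exponents", tuple(as_gexpr(e) for e in self.exponents))

    @property
    def is_symbolic(self) -> bool:
        return any(e.is_symbolic for e in self.exponents)

    def value(self, X: Sequence[float], g_value: Optional[Fraction]) -> float:
        v = float(self.rate_constant)
        for x, e in zip(X, self.exponents):
            if e.is_symbolic:
                if g_value is None:
                    raise DomainError("symbolic exponent requires a g value")
                p = float(e.subs(g_value))
            else:
                p = float(e.const)
            if p != 0.0:
                v *= x ** p
        return v


@dataclass(frozen=True)
class SSystemEquation:
    """dX_i/dt = sum(production) - sum(degradation); one term each here."""

    species_index: int  # 1-based
    production: Tuple[PowerLawTerm, ...]
    degradation: Tuple[PowerLawTerm, ...]

    def __post_init__(self) -> None:
        if not self.production or not self.degradation:
            raise InvalidCascadeError("production and degradation must be non-empty")

    def rate(self, X: Sequence[float], g_value: Optional[Fraction]) -> float:
        return (sum(t.value(X, g_value) for t in self.production)
                - sum(t.value(X, g_value) for t in self.degradation))


@dataclass(frozen=True)
class CascadeModel:
    """An n-species end-product-inhibition S-system with one optional unknown."""

    n: int
    equations: Tuple[SSystemEquation, ...]
    unknown_position: Optional[Tuple[int, int]]  # (equation index, species index), 1-based
    feedback_edge: Tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        if self.feedback_edge == (0, 0):
            object.__setattr__(self, "feedback_edge", (self.n, 1))
        n_sym = sum(t.is_symbolic for eq in self.equations for t in eq.production + eq.degradation)
        if n_sym > 1:
            raise InvalidCascadeError("at most one exponent may be symbolic")

    @property
    def is_symbolic(self) -> bool:
        return self.unknown_position is not None and any(
            t.is_symbolic for eq in self.equations for t in eq.production + eq.degradation)

    @property
    def intermediate_count(self) -> int:
        return self.n - 2

    def structural_g(self) -> Optional[Fraction]:
        """The stored structural feedback order, if numeric (None if symbolic)."""
        i, j = (self.unknown_position or (1, self.n))
        exp = self.equations[i - 1].production[0].exponents[j - 1]
        if exp.is_symbolic:
            return None
        return -exp.const


def _vector(v: Optional[Sequence[float]], n: int, name: str) -> Tuple[Fraction, ...]:
    if v is None:
        return tuple(Fraction(1) for _ in range(n))
    vals = tuple(Fraction(x) if not isinstance(x, float) else Fraction(x).limit_denominator(10**9)
                 for x in v)
    if len(vals) != n:
        raise InvalidCascadeError(f"{name} must have length {n}, got {len(vals)}")
    if any(x <= 0 for x in vals):
        raise DomainError(f"{name} entries must be positive")
    return vals


def build_end_product_cascade(
    n: int,
    g: Union[str, GExpr, int, Fraction] = SYMBOLIC,
    alpha: Optional[Sequence[float]] = None,
    beta: Optional[Sequence[float]] = None,
    h: Optional[Sequence[float]] = None,
) -> CascadeModel:
    """Build the length-n end-product-inhibition cascade.

    Equation 1: ``dX1/dt = alpha1 * Xn**(-g) - beta1 * X1**h1`` (inhibitory
    feedback carried on Xn); equations i >= 2: ``dXi/dt = alphai * X(i-1) -
    betai * Xi**hi``.  ``g`` may be :data:`SYMBOLIC` (default) or a
    non-negative rational structural order.
    """
    if n < 3:
        raise InvalidCascadeError(f"pathway length must be >= 3, got {n}")
    alpha_v = _vector(alpha, n, "alpha")
    beta_v = _vector(beta, n, "beta")
    h_v = _vector(h, n, "h")

    if g == SYMBOLIC or (isinstance(g, GExpr) and g.is_symbolic):
        fb = -G
    else:
        gq = Fraction(g) if not isinstance(g, GExpr) else g.exact()
        if gq < 0:
            raise DomainError(f"structural feedback order must be >= 0, got {gq}")
        fb = as_gexpr(-gq)

    zero = as_gexpr(0)
    eqs = []
    for i in range(1, n + 1):
        pexp = [zero] * n
        dexp = [zero] * n
        if i == 1:
            pexp[n - 1] = fb
        else:
            pexp[i - 2] = as_gexpr(1)
        dexp[i - 1] = as_gexpr(h_v[i - 1])
        eqs.append(SSystemEquation(
            species_index=i,
            production=(PowerLawTerm(float(alpha_v[i - 1]), tuple(pexp)),),
            degradation=(PowerLawTerm(float(beta_v[i - 1]), tuple(dexp)),),
        ))
    return CascadeModel(n=n, equations=tuple(eqs), unknown_position=(1, n))


def evaluate_rates(model: CascadeModel, X: Sequence[float],
                   g_value: Optional[Union[int, Fraction]] = None) -> np.ndarray:
    """dX/dt at state ``X`` with the unknown substituted by ``g_value``."""
    Xa = np.asarray(X, dtype=float)
    if Xa.shape != (model.n,):
        raise InvalidCascadeError(f"state must have length {model.n}")
    if np.any(Xa <= 0):
        raise DomainError("power law rates are undefined at non-positive concentrations")
    gq = None if g_value is None else Fraction(g_value)
    return np.array([eq.rate(Xa, gq) for eq in model.equations])


def _exponent_matrix(model: CascadeModel, g_value: Optional[Fraction]):
    """(net exponent matrix A, rhs b) of the log-space steady-state system."""
    n = model.n
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i, eq in enumerate(model.equations):
        p, d = eq.production[0], eq.degradation[0]
        for j in range(n):
            pe, de = p.exponents[j], d.exponents[j]
            pv = float(pe.subs(g_value)) if pe.is_symbolic else float(pe.const)
            dv = float(de.subs(g_value)) if de.is_symbolic else float(de.const)
            A[i, j] = pv - dv
        b[i] = math.log(d.rate_constant / p.rate_constant)
    return A, b


def jacobian(model: CascadeModel, X: Sequence[float],
             g_value: Optional[Union[int, Fraction]] = None) -> np.ndarray:
    """Analytic Jacobian of the rate law at ``X``."""
    Xa = np.asarray(X, dtype=float)
    gq = None if g_value is None else Fraction(g_value)
    n = model.n
    J = np.zeros((n, n))
    for i, eq in enumerate(model.equations):
        for sign, terms in ((1.0, eq.production), (-1.0, eq.degradation)):
            for t in terms:
                val = t.value(Xa, gq)
                for j, e in enumerate(t.exponents):
                    p = float(e.subs(gq)) if e.is_symbolic else float(e.const)
                    if p != 0.0:
                        J[i, j] += sign * val * p / Xa[j]
    return J


@dataclass(frozen=True)
class SteadyState:
    concentrations: np.ndarray
    residual_norm: float


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray
    classification: str  # stable | marginal | unstable_oscillatory | unstable_divergent


def solve_steady_state(model: CascadeModel,
                       g_value: Optional[Union[int, Fraction]] = None,
                       tol: float = 1e-10, max_iter: int = 200,
                       method: str = "auto") -> SteadyState:
    """Positive steady state via the exact log-linear solve, Newton fallback.

    The S-system steady-state condition is linear in ``log X``; when the net
    exponent matrix is non-singular that solve is exact.  Otherwise (or if the
    residual check fails) a damped Newton iteration in log space is run.
    ``method`` may force one route ("linear" / "newton"); "auto" tries the
    linear solve first.
    """
    if model.is_symbolic and g_value is None:
        raise InvalidCascadeError("symbolic model needs g_value")
    if method not in ("auto", "linear", "newton"):
        raise ValueError(f"unknown method {method!r}")
    gq = None if g_value is None else Fraction(g_value)
    A, b = _exponent_matrix(model, gq)
    y = None
    if method != "newton":
        try:
            y = np.linalg.solve(A, b)  # A y = ln(beta/alpha)
        except np.linalg.LinAlgError:
            y = None
        if y is not None:
            X = np.exp(y)
            res = float(np.max(np.abs(evaluate_rates(model, X, gq))))
            if res < tol:
                return SteadyState(concentrations=X, residual_norm=res)
        if method == "linear":
            raise NonconvergenceError("log-linear solve failed to meet tolerance",
                                      last_state=None if y is None else np.exp(y))
        y = None if y is not None and not np.all(np.isfinite(y)) else y
    # damped Newton in log space
    y = np.zeros(model.n) if y is None or not np.all(np.isfinite(y)) else y
    last_res = math.inf
    for _ in range(max_iter):
        X = np.exp(y)
        F = evaluate_rates(model, X, gq)
        res = float(np.max(np.abs(F)))
        if res < tol:
            return SteadyState(concentrations=X, residual_norm=res)
        J = jacobian(model, X, gq) * X[np.newaxis, :]  # d rate / d y
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-8:
            y_new = y + lam * step
            res_new = float(np.max(np.abs(evaluate_rates(model, np.exp(y_new), gq))))
            if res_new < res:
                break
            lam *= 0.5
        y = y + lam * step
        if abs(res - last_res) < 1e-16 and res >= tol:
            break
        last_res = res
    X = np.exp(y)
    res = float(np.max(np.abs(evaluate_rates(model, X, gq))))
    raise NonconvergenceError(
        f"steady-state solve did not reach tol={tol} (residual {res:.3e})",
        last_state=X, residual=res)


def simulate(model: CascadeModel, g_value: Optional[Union[int, Fraction]],
             X0: Sequence[float], t_grid: Sequence[float],
             rtol: float = 1e-8, atol: float = 1e-12) -> np.ndarray:
    """Integrate the cascade on ``t_grid``; returns a (len(t), n) matrix.

    Integration runs in log-concentration space so trajectories stay positive
    by construction; a stiff-capable method is used.
    """
    X0a = np.asarray(X0, dtype=float)
    if np.any(X0a <= 0):
        raise DomainError("initial state must be positive")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise InvalidCascadeError("t_grid must be strictly increasing with >= 2 points")
    gq = None if g_value is None else Fraction(g_value)

    def rhs(_t, y):
        X = np.exp(y)
        return evaluate_rates(model, X, gq) / X

    def jac(_t, y):
        X = np.exp(y)
        Jx = jacobian(model, X, gq)
        rates = evaluate_rates(model, X, gq)
        return (Jx * X[np.newaxis, :]) / X[:, np.newaxis] - np.diag(rates / X)

    sol = solve_ivp(rhs, (t[0], t[-1]), np.log(X0a), t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol, jac=jac)
    if not sol.success:
        t_last = float(sol.t[-1]) if len(sol.t) else float(t[0])
        state = np.exp(sol.y[:, -1]) if sol.y.size else X0a
        raise SimulationError(f"integrator failed: {sol.message}", t_last, state)
    return np.exp(sol.y).T


def classify_eigenvalues(eigs: np.ndarray, tol: float = 1e-9) -> str:
    """Pure classification rule on the spectrum (threshold ``tol``)."""
    re = eigs.real
    if np.all(re < -tol):
        return "stable"
    if np.all(re <= tol):
        return "marginal"
    unstable = eigs[re > tol]
    if np.any(np.abs(unstable.imag) > tol):
        return "unstable_oscillatory"
    return "unstable_divergent"


def linearize_and_classify(model: CascadeModel,
                           g_value: Optional[Union[int, Fraction]] = None,
                           tol: float = 1e-9) -> StabilityReport:
    """Eigenvalues of the Jacobian at the steady state, plus classification."""
    ss = solve_steady_state(model, g_value)
    J = jacobian(model, ss.concentrations, g_value)
    eigs = np.linalg.eigvals(J)
    return StabilityReport(eigenvalues=eigs, classification=classify_eigenvalues(eigs, tol))


# -- serialization ---------------------------------------------------------

def model_to_json(model: CascadeModel) -> str:
    """Serialize the builder parameters of a cascade (JSON document)."""
    alpha = [eq.production[0].rate_constant for eq in model.equations]
    beta = [eq.degradation[0].rate_constant for eq in model.equations]
    h = [str(eq.degradation[0].exponents[eq.species_index - 1].const)
         for eq in model.equations]
    g_struct = model.structural_g()
    doc = {
        "n": model.n,
        "alpha": alpha,
        "beta": beta,
        "h": h,
        "g": SYMBOLIC if g_struct is None else str(g_struct),
        "unknown_position": list(model.unknown_position or ()),
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def model_from_json(text: str) -> CascadeModel:
    doc = json.loads(text)
    g = doc["g"] if doc["g"] == SYMBOLIC else Fraction(doc["g"])
    return build_end_product_cascade(
        n=doc["n"], g=g,
        alpha=[Fraction(str(a)) for a in doc["alpha"]],
        beta=[Fraction(str(b)) for b in doc["beta"]],
        h=[Fraction(x) for x in doc["h"]],
    )
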