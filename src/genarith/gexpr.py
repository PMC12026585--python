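"""Exact affine expressions in the single unknown kinetic order.

Kinetic orders are exact rationals except for one distinguished unknown ``g``
(structurally non-negative).  Every exponent in the package is a
:class:`GExpr` ``const + gcoef * g``; plain rationals are the ``gcoef == 0``
special case.  Comparisons are only offered where they are decidable for
*every* g >= 0, which is all the lattice bookkeeping needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Optional, Union

RationalLike = Union[int, Fraction, Rational]


@dataclass(frozen=True)
class GExpr:
    """Affine expression ``const + gcoef * g`` with exact rational fields."""

    const: Fraction = Fraction(0)
    gcoef: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "const", Fraction(self.const))
        object.__setattr__(self, "gcoef", Fraction(self.gcoef))

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "GExprLike") -> "GExpr":
        o = as_gexpr(other)
        return GExpr(self.const + o.const, self.gcoef + o.gcoef)

    __radd__ = __add__

    def __sub__(self, other: "GExprLike") -> "GExpr":
        o = as_gexpr(other)
        return GExpr(self.const - o.const, self.gcoef - o.gcoef)

    def __rsub__(self, other: "GExprLike") -> "GExpr":
        return as_gexpr(other) - self

    def __neg__(self) -> "GExpr":
        return GExpr(-self.const, -self.gcoef)

    def __mul__(self, other: RationalLike) -> "GExpr":
        q = Fraction(other)
        return GExpr(self.const * q, self.gcoef * q)

    __rmul__ = __mul__

    # -- queries -----------------------------------------------------------
    @property
    def is_symbolic(self) -> bool:
        return self.gcoef != 0

    @property
    def is_zero(self) -> bool:
        return self.const == 0 and self.gcoef == 0

    def subs(self, g_value: RationalLike) -> Fraction:
        """Evaluate at a concrete structural value of g."""
        return self.const + self.gcoef * Fraction(g_value)

    def exact(self) -> Fraction:
        """Return the value if it is constant, else raise ``ValueError``."""
        if self.is_symbolic:
            raise ValueError(f"expression {self} is symbolic in g")
        return self.const

    # -- decidable order under the convention g >= 0 ----------------------
    def le_for_all_g(self, other: "GExprLike") -> Optional[bool]:
        """Whether ``self <= other`` holds for every g >= 0.

        Returns True/False when decidable from the coefficient pattern,
        ``None`` when the answer depends on the value of g.
        """
        d = as_gexpr(other) - self
        if d.const >= 0 and d.gcoef >= 0:
            return True
        if d.const < 0 and d.gcoef <= 0:
            return False
        if d.const <= 0 and d.gcoef < 0:
            return False
        return None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if not self.is_symbolic:
            return str(self.const)
        gpart = "g" if self.gcoef == 1 else ("-g" if self.gcoef == -1 else f"{self.gcoef}*g")
        if self.const == 0:
            return gpart
        sign = "+" if self.gcoef > 0 else ""
        return f"{self.const}{sign}{gpart}"


GExprLike = Union[GExpr, RationalLike]

#: The unknown kinetic order itself.
G = GExpr(Fraction(0), Fraction(1))


def as_gexpr(x: GExprLike) -> GExpr:
    if isinstance(x, GExpr):
        return x
    return GExpr(Fraction(x), Fraction(0))


def dominated_min(values: Iterable[GExpr]) -> GExpr:
    """The element that is <= all others for every g >= 0.

    Raises ``ValueError`` if no element dominates (undecidable without a
    concrete g); callers then must substitute a candidate value first.
    """
    vals = [as_gexpr(v) for v in values]
    if not vals:
        raise ValueError("empty value list")
    for cand in vals:
        if all(cand.le_for_all_g(v) for v in vals):
            return cand
    raise ValueError("minimum is not decidable for all g >= 0; substitute a value")
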