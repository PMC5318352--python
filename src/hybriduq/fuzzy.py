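"""Generalized and interval-valued fuzzy numbers with α-cut arithmetic.

A *generalized fuzzy number* (GFN) is a possibility distribution written
``[a, b, c, d; w]``: membership rises linearly from 0 at ``a`` to the height
``w ∈ (0, 1]`` at ``b``, stays at ``w`` on the core ``[b, c]``, and falls
linearly back to 0 at ``d``. Triangular numbers ``[a, b, c; w]`` are the
special case ``b == c``. An *interval-valued fuzzy number* (IVFN) assigns each
point an interval of membership grades, bounded by an upper membership
function (UMF) and a lower membership function (LMF), each itself a GFN with
the LMF nested inside the UMF.

The α-cut — the crisp set of points with membership at least α — is the
workhorse of possibilistic uncertainty propagation: for these piecewise-linear
shapes every non-empty cut is a closed interval obtained by interpolating the
two legs at level α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

__all__ = [
    "CutInterval",
    "EMPTY_CUT",
    "GeneralizedFuzzyNumber",
    "IntervalValuedFuzzyNumber",
    "IvfnCut",
    "GeneralizedIvfnError",
    "alpha_cut",
    "membership",
    "alpha_cut_ivfn",
    "validate",
    "require_normal_ivfn",
]

#: Relative tolerance for invariant checks (pure arithmetic; tight is safe).
REL_TOL = 1e-9


def _close(x: float, y: float) -> bool:
    return math.isclose(x, y, rel_tol=REL_TOL, abs_tol=1e-300)


@dataclass(frozen=True)
class CutInterval:
    """A closed interval ``[lo, hi]``, or the distinguished empty cut.

    The empty cut is the value of an α-cut taken above a fuzzy number's
    height; it compares equal to :data:`EMPTY_CUT`.
    """

    lo: float = math.nan
    hi: float = math.nan
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and not self.lo <= self.hi:  # also rejects NaN
            raise ValueError(f"cut interval requires lo <= hi, got [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.hi - self.lo

    @property
    def midpoint(self) -> float:
        if self.empty:
            raise ValueError("empty cut has no midpoint")
        return 0.5 * (self.lo + self.hi)

    def contains(self, other: "CutInterval", tol: float = REL_TOL) -> bool:
        """Subset test ``other ⊆ self`` with relative slack ``tol``."""
        if other.empty:
            return True
        if self.empty:
            return False
        slack = tol * max(1.0, abs(self.lo), abs(self.hi))
        return self.lo - slack <= other.lo and other.hi <= self.hi + slack

    def __contains__(self, x: float) -> bool:
        return (not self.empty) and self.lo <= x <= self.hi


#: The empty α-cut (returned above a fuzzy number's height).
EMPTY_CUT = CutInterval(empty=True)


@dataclass(frozen=True)
class GeneralizedFuzzyNumber:
    """Trapezoidal possibility distribution ``[a, b, c, d; w]`` with height w ≤ 1.

    Parameters
    ----------
    a, b, c, d
        Support left end, core left end, core right end, support right end,
        in the units of the quantity being described. Must satisfy
        ``a <= b <= c <= d``.
    w
        Height: the maximum membership grade, in ``(0, 1]``. A *normal*
        fuzzy number has ``w == 1``; heights below 1 encode an expert's
        bounded confidence in the distribution itself.
    """

    a: float
    b: float
    c: float
    d: float
    w: float = 1.0

    # -- constructors -------------------------------------------------

    @classmethod
    def triangular(cls, a: float, b: float, c: float, w: float = 1.0) -> "GeneralizedFuzzyNumber":
        """Triangular ``[a, b, c; w]``, normalized to the trapezoidal form (a, b, b, c)."""
        return cls(a, b, b, c, w)

    @classmethod
    def trapezoidal(
        cls, a: float, b: float, c: float, d: float, w: float = 1.0
    ) -> "GeneralizedFuzzyNumber":
        return cls(a, b, c, d, w)

    @classmethod
    def crisp(cls, x: float) -> "GeneralizedFuzzyNumber":
        """Degenerate fuzzy number concentrated at ``x`` (a constant)."""
        return cls(x, x, x, x, 1.0)

    # -- descriptors ---------------------------------------------------

    @property
    def height(self) -> float:
        return self.w

    @property
    def support(self) -> CutInterval:
        return CutInterval(self.a, self.d)

    @property
    def core(self) -> CutInterval:
        return CutInterval(self.b, self.c)

    @property
    def is_crisp(self) -> bool:
        return self.a == self.d

    # -- operations ----------------------------------------------------

    def alpha_cut(self, alpha: float) -> CutInterval:
        """The α-cut ``{x : μ(x) >= α}``.

        For ``α <= w`` this is the closed interval
        ``[a + (b-a)·α/w, d − (d-c)·α/w]``; above the height the cut is
        empty. ``α == w`` (within tolerance) returns the core.
        """
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
        if alpha > self.w and not _close(alpha, self.w):
            return EMPTY_CUT
        t = min(alpha, self.w) / self.w
        lo = self.a + (self.b - self.a) * t
        hi = self.d - (self.d - self.c) * t
        if lo > hi:  # float round-off at the core (mathematically lo <= hi)
            lo = hi = 0.5 * (lo + hi)
        return CutInterval(lo, hi)

    def membership(self, x: float) -> float:
        """Piecewise-linear membership degree in ``[0, w]``.

        Zero-width legs (``a == b`` or ``c == d``) use the limit convention:
        membership jumps to ``w`` at the knot, keeping α-cuts total.
        """
        if x < self.a or x > self.d:
            return 0.0
        if self.b <= x <= self.c:
            return self.w
        if x < self.b:  # a <= x < b with a < b
            return self.w * (x - self.a) / (self.b - self.a)
        return self.w * (self.d - x) / (self.d - self.c)

    def validate(self) -> list[str]:
        """Return every violated invariant (empty list when well-formed)."""
        violations: list[str] = []
        knots = (self.a, self.b, self.c, self.d)
        if any(not math.isfinite(k) for k in knots):
            violations.append(f"knots not finite: {knots}")
        elif not (self.a <= self.b <= self.c <= self.d):
            violations.append(f"knots not sorted: a <= b <= c <= d required, got {knots}")
        if not (math.isfinite(self.w) and 0.0 < self.w <= 1.0):
            violations.append(f"height must lie in (0, 1], got {self.w}")
        return violations

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        if self.b == self.c:
            return {"type": "tri", "knots": [self.a, self.b, self.d], "height": self.w}
        return {"type": "trap", "knots": [self.a, self.b, self.c, self.d], "height": self.w}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneralizedFuzzyNumber":
        kind = d.get("type", "trap")
        knots = list(d["knots"])
        w = float(d.get("height", 1.0))
        if kind == "tri":
            if len(knots) != 3:
                raise ValueError(f"triangular number needs 3 knots, got {len(knots)}")
            return cls.triangular(*map(float, knots), w=w)
        if kind == "trap":
            if len(knots) != 4:
                raise ValueError(f"trapezoidal number needs 4 knots, got {len(knots)}")
            return cls.trapezoidal(*map(float, knots), w=w)
        raise ValueError(f"unknown fuzzy number type {kind!r}")

    def __str__(self) -> str:
        if self.b == self.c:
            return f"[{self.a:g}, {self.b:g}, {self.d:g}; {self.w:g}]"
        return f"[{self.a:g}, {self.b:g}, {self.c:g}, {self.d:g}; {self.w:g}]"


@dataclass(frozen=True)
class IvfnCut:
    """The α-cut of an IVFN: a (possibly empty) cut of each bounding MF.

    When both are non-empty the UMF cut contains the LMF cut:
    ``umf_cut.lo <= lmf_cut.lo <= lmf_cut.hi <= umf_cut.hi``.
    """

    lmf_cut: CutInterval
    umf_cut: CutInterval


@dataclass(frozen=True)
class IntervalValuedFuzzyNumber:
    """A pair of nested membership functions bounding an imprecise membership grade.

    ``umf`` (upper membership function) dominates ``lmf`` (lower membership
    function) pointwise. *Normal* IVFNs have both heights equal to 1;
    *generalized* IVFNs (LMF height < 1) and *completely generalized* IVFNs
    (both < 1) are representable but rejected by the propagation engine —
    see :func:`require_normal_ivfn`.
    """

    umf: GeneralizedFuzzyNumber
    lmf: GeneralizedFuzzyNumber

    @property
    def is_normal(self) -> bool:
        return self.umf.w == 1.0 and self.lmf.w == 1.0

    def alpha_cut(self, alpha: float) -> IvfnCut:
        """Three-case α-cut.

        Both cuts when ``α <= h(lmf)``; only the UMF cut when
        ``h(lmf) < α <= h(umf)``; both empty above ``h(umf)``.
        """
        return IvfnCut(lmf_cut=self.lmf.alpha_cut(alpha), umf_cut=self.umf.alpha_cut(alpha))

    def validate(self) -> list[str]:
        violations = [f"umf: {v}" for v in self.umf.validate()]
        violations += [f"lmf: {v}" for v in self.lmf.validate()]
        if violations:
            return violations
        if self.lmf.w > self.umf.w and not _close(self.lmf.w, self.umf.w):
            violations.append(
                f"LMF height {self.lmf.w} exceeds UMF height {self.umf.w}"
            )
            return violations
        # Legs are linear, so cut nesting at alpha = 0 and alpha = h(lmf)
        # implies nesting at every level in between.
        for alpha in (0.0, self.lmf.w):
            cut = self.alpha_cut(alpha)
            if not cut.umf_cut.contains(cut.lmf_cut):
                violations.append(
                    f"LMF alpha-cut not nested in UMF alpha-cut at alpha={alpha:g}: "
                    f"lmf=[{cut.lmf_cut.lo:g}, {cut.lmf_cut.hi:g}], "
                    f"umf=[{cut.umf_cut.lo:g}, {cut.umf_cut.hi:g}]"
                )
        return violations

    def to_dict(self) -> dict:
        return {"umf": self.umf.to_dict(), "lmf": self.lmf.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalValuedFuzzyNumber":
        return cls(
            umf=GeneralizedFuzzyNumber.from_dict(d["umf"]),
            lmf=GeneralizedFuzzyNumber.from_dict(d["lmf"]),
        )

    def __str__(self) -> str:
        return f"{{umf={self.umf}, lmf={self.lmf}}}"


class GeneralizedIvfnError(ValueError):
    """Raised when a non-normal IVFN reaches the propagation engine.

    The hybrid propagation scheme is defined for normal IVFNs (both bounding
    membership functions of height 1) only; generalized IVFN inputs are out
    of its domain rather than malformed.
    """


FuzzyInput = Union[GeneralizedFuzzyNumber, IntervalValuedFuzzyNumber]


def alpha_cut(g: GeneralizedFuzzyNumber, alpha: float) -> CutInterval:
    """Functional alias for :meth:`GeneralizedFuzzyNumber.alpha_cut`."""
    return g.alpha_cut(alpha)


def membership(g: GeneralizedFuzzyNumber, x: float) -> float:
    """Functional alias for :meth:`GeneralizedFuzzyNumber.membership`."""
    return g.membership(x)


def alpha_cut_ivfn(f: IntervalValuedFuzzyNumber, alpha: float) -> IvfnCut:
    """Functional alias for :meth:`IntervalValuedFuzzyNumber.alpha_cut`."""
    return f.alpha_cut(alpha)


def validate(obj: FuzzyInput) -> list[str]:
    """Every violated invariant of a fuzzy number or IVFN (empty when valid)."""
    return obj.validate()


def require_normal_ivfn(f: IntervalValuedFuzzyNumber, name: str = "") -> None:
    """Reject non-normal IVFNs at engine entry.

    Raises
    ------
    GeneralizedIvfnError
        If either bounding membership function has height < 1 (the
        propagation scheme has no defined semantics for that case).
    ValueError
        If the IVFN is malformed (distinct from the unsupported-but-valid
        generalized case).
    """
    violations = f.validate()
    if violations:
        raise ValueError(f"malformed IVFN {name or f}: " + "; ".join(violations))
    if not f.is_normal:
        raise GeneralizedIvfnError(
            f"generalized IVFN unsupported{f' for parameter {name}' if name else ''}: "
            f"propagation requires both membership-function heights equal to 1, "
            f"got h(umf)={f.umf.w:g}, h(lmf)={f.lmf.w:g}"
        )
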