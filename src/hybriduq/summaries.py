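"""P-box and fractile-membership summaries of propagated CDF families.

Two readings of a CDF family:

* **Probability box** — the α = 0 member of a pass has the widest cuts, so its
  minima/maxima ECDFs envelope every other member pointwise; that pair bounds
  all CDFs consistent with the stated uncertainty. Summaries (range, mean,
  variance) are interval-valued because each Monte Carlo draw contributes an
  interval ``[min_i, max_i]`` rather than a point.

* **Fractile membership function** — fixing a cumulative probability p and
  sweeping α, the interval ``[Q_p(minima), Q_p(maxima)]`` per level traces out
  a trapezoidal generalized fuzzy number of the output at that fractile: the
  α = 0 interval is the support, the α = w interval the core, and the height
  is w. The UMF pass yields the upper membership function, the LMF pass the
  lower one, together a completely generalized interval-valued fuzzy number.

Quantiles come in two modes: ``"empirical"`` reads them off the Monte Carlo
ECDFs (the general path); ``"analytic"`` pushes the closed-form quantile of a
single probabilistic parameter through the corner evaluation, which is exact
for models monotone in that parameter and makes the summaries deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Literal

import numpy as np

from .engine import CDFFamily, MembershipPass, ModelSpec, corner_envelope
from .fuzzy import CutInterval, GeneralizedFuzzyNumber
from .sampling import quantile as _dist_quantile

__all__ = [
    "PBox",
    "FractileMF",
    "pbox",
    "pbox_range",
    "pbox_mean",
    "pbox_variance",
    "interval_variance_bounds",
    "fractile_mf",
]

QuantileMode = Literal["empirical", "analytic"]


@dataclass(frozen=True)
class PBox:
    """Bounding CDF pair of one pass: α = 0 minima (left/upper CDF bound) and
    maxima (right/lower CDF bound), with the per-draw intervals retained for
    interval-valued summaries."""

    pass_: MembershipPass
    minima: np.ndarray
    maxima: np.ndarray
    family: CDFFamily

    @cached_property
    def ecdf_min(self):
        return self.family.member(self.pass_, 0.0).ecdf_min

    @cached_property
    def ecdf_max(self):
        return self.family.member(self.pass_, 0.0).ecdf_max

    def to_frame(self):
        import pandas as pd

        left = self.ecdf_min.to_frame().assign(curve="min")
        right = self.ecdf_max.to_frame().assign(curve="max")
        return pd.concat([left, right], ignore_index=True)[["curve", "value", "cum_prob"]]


def pbox(family: CDFFamily, pass_: MembershipPass = MembershipPass.UMF) -> PBox:
    """P-box of a pass: the α = 0 envelope of the family's CDFs."""
    member = family.member(pass_, 0.0)  # raises KeyError if absent
    return PBox(pass_=pass_, minima=member.minima, maxima=member.maxima, family=family)


def _analytic_curve_quantile(
    model: ModelSpec,
    pass_: MembershipPass,
    alpha: float,
    curve: Literal["min", "max"],
    p: float,
) -> float:
    """Closed-form p-quantile of the min/max corner curve.

    Valid when the model has at most one probabilistic parameter and is
    monotone in it: the p-quantile of a monotone transform g(X) is
    g(F⁻¹(p)) for increasing g and g(F⁻¹(1-p)) for decreasing g. The
    direction is detected by evaluating g at two interior quantiles.
    """
    if len(model.probabilistic) > 1:
        raise ValueError(
            "analytic quantile mode requires at most one probabilistic parameter; "
            f"model {model.name!r} has {len(model.probabilistic)}"
        )
    cuts = model.fuzzy_cuts(alpha, pass_)
    idx = 0 if curve == "min" else 1

    if not model.probabilistic:
        return float(corner_envelope(model, {}, cuts)[idx])

    (name, spec), = model.probabilistic.items()

    def g(x: float) -> float:
        return float(corner_envelope(model, {name: x}, cuts)[idx])

    if spec.family == "constant":
        return g(spec.value)
    lo, hi = _dist_quantile(spec, 0.25), _dist_quantile(spec, 0.75)
    increasing = g(hi) >= g(lo)
    return g(_dist_quantile(spec, p if increasing else 1.0 - p))


def pbox_range(
    pb: PBox,
    p_low: float = 0.005,
    p_high: float = 0.995,
    mode: QuantileMode = "empirical",
) -> CutInterval:
    """Interval-valued range of the p-box.

    Reported between the ``p_low`` quantile of the minima curve and the
    ``p_high`` quantile of the maxima curve (defaults 0.5th/99.5th
    percentiles) rather than the absolute sample extremes, which are unstable
    at finite Monte Carlo size.
    """
    if not (0.0 < p_low < p_high < 1.0):
        raise ValueError(
            f"range percentiles must satisfy 0 < p_low < p_high < 1, got ({p_low}, {p_high})"
        )
    if mode == "analytic":
        model, pass_ = pb.family.model, pb.pass_
        lo = _analytic_curve_quantile(model, pass_, 0.0, "min", p_low)
        hi = _analytic_curve_quantile(model, pass_, 0.0, "max", p_high)
    else:
        lo = pb.ecdf_min.quantile(p_low)
        hi = pb.ecdf_max.quantile(p_high)
    return CutInterval(float(lo), float(hi))


def pbox_mean(pb: PBox) -> CutInterval:
    """Interval mean: averages of the per-draw corner minima and maxima."""
    return CutInterval(float(np.mean(pb.minima)), float(np.mean(pb.maxima)))


def _max_variance_exact(lo: np.ndarray, hi: np.ndarray, denom: float) -> float:
    """Exact max variance over endpoint selections by vectorized enumeration."""
    n = lo.size
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    x = np.where(bits == 1, hi, lo)
    dev = x - x.mean(axis=1, keepdims=True)
    return float(np.max(np.sum(dev**2, axis=1)) / denom)


def _max_variance_bound(lo: np.ndarray, hi: np.ndarray, denom: float) -> float:
    """Guaranteed upper bound of the max variance for large n.

    For any reference point t, Σ(x_i − t)²/n ≥ variance of the selection and
    each term is maximized at the endpoint farther from t, so
    U(t) = Σ max((lo_i − t)², (hi_i − t)²) / n dominates every selection's
    variance. U is piecewise quadratic with breakpoints at the interval
    midpoints; minimizing it per midpoint segment (vertex t* = mean of the
    farther endpoints, clamped) gives min_t U(t) in O(n log n). The bound is
    attained — i.e. equals the true maximum — whenever the farther-endpoint
    selection at the optimal t has mean t (the usual case for overlapping
    interval data); computing the exact maximum in general is NP-hard.
    """
    n = lo.size
    order = np.argsort(lo + hi)  # ascending midpoint
    lo_s, hi_s = lo[order], hi[order]
    mids = 0.5 * (lo_s + hi_s)
    # For t in midpoint segment k: intervals 0..k-1 (mid < t) are farther at
    # lo, intervals k..n-1 farther at hi.
    cum_lo = np.concatenate([[0.0], np.cumsum(lo_s)])
    cum_lo2 = np.concatenate([[0.0], np.cumsum(lo_s**2)])
    cum_hi = np.concatenate([[0.0], np.cumsum(hi_s[::-1])])[::-1]
    cum_hi2 = np.concatenate([[0.0], np.cumsum(hi_s[::-1] ** 2)])[::-1]
    S = cum_lo + cum_hi  # S[k], SS[k]: farther-endpoint sums at split k
    SS = cum_lo2 + cum_hi2
    segments = np.concatenate([[-np.inf], mids, [np.inf]])
    best = np.inf
    for k in range(n + 1):
        t = np.clip(S[k] / n, segments[k], segments[k + 1])
        best = min(best, (SS[k] - 2 * t * S[k] + n * t * t))
    return max(float(best) / denom, 0.0)


def interval_variance_bounds(lo, hi, ddof: int = 0) -> tuple[float, float]:
    """Bounds of the sample variance over all selections x_i ∈ [lo_i, hi_i].

    Lower bound (exact): the minimizing selection clips a common value m into
    each interval, x_i = clip(m, lo_i, hi_i); the variance is piecewise
    quadratic in m with vertex m* = S_fixed / (n - k_free) on each segment
    between endpoint breakpoints, so a sweep over segments finds the exact
    minimum — 0 precisely when all intervals share a common point.

    Upper bound: exact endpoint enumeration for n ≤ 16; for larger n, the
    guaranteed dominating bound min_t Σ max((lo_i−t)², (hi_i−t)²)/n, which is
    never below any endpoint selection's variance and coincides with the true
    maximum whenever the farther-endpoint selection at the optimum is a fixed
    point of its own mean (exact maximization is NP-hard in general).

    ``ddof`` selects the divisor ``n - ddof`` (default 0: population
    variance).
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if lo.shape != hi.shape or lo.ndim != 1:
        raise ValueError("lo and hi must be 1-d arrays of equal length")
    if np.any(lo > hi):
        raise ValueError("interval data requires lo <= hi elementwise")
    n = lo.size
    if n - ddof <= 0:
        raise ValueError(f"need n > ddof, got n={n}, ddof={ddof}")

    denom = float(n - ddof)
    if n <= 16:
        upper = _max_variance_exact(lo, hi, denom)
    else:
        upper = _max_variance_bound(lo, hi, denom)

    # ---- lower bound ------------------------------------------------------
    if np.max(lo) <= np.min(hi):
        return 0.0, upper

    # Sweep m over endpoint-breakpoint segments. As m grows, interval i is
    # fixed at lo_i while m <= lo_i, free (= m) on [lo_i, hi_i], then fixed
    # at hi_i. Maintain the fixed sums incrementally.
    points = np.unique(np.concatenate([lo, hi]))
    lo_sorted = np.sort(lo)
    hi_sorted = np.sort(hi)
    lo_cum = np.concatenate([[0.0], np.cumsum(lo_sorted)])
    lo_cum2 = np.concatenate([[0.0], np.cumsum(lo_sorted**2)])
    hi_cum = np.concatenate([[0.0], np.cumsum(hi_sorted)])
    hi_cum2 = np.concatenate([[0.0], np.cumsum(hi_sorted**2)])

    lower = np.inf
    for left, right in zip(points[:-1], points[1:]):
        mid = 0.5 * (left + right)
        n_hi_fixed = int(np.searchsorted(hi_sorted, mid))  # hi_i < mid
        n_lo_fixed = n - int(np.searchsorted(lo_sorted, mid))  # lo_i > mid
        k = n - n_hi_fixed - n_lo_fixed  # free on this segment
        S_fix = hi_cum[n_hi_fixed] + (lo_cum[n] - lo_cum[n - n_lo_fixed])
        SS_fix = hi_cum2[n_hi_fixed] + (lo_cum2[n] - lo_cum2[n - n_lo_fixed])
        candidates = [left, right]
        if 0 < k < n:
            candidates.append(min(max(S_fix / (n - k), left), right))
        for m in candidates:
            total = S_fix + k * m
            total2 = SS_fix + k * m * m
            lower = min(lower, (total2 - total**2 / n) / (n - ddof))
    return max(float(lower), 0.0), upper


def pbox_variance(pb: PBox, ddof: int = 0) -> CutInterval:
    """Interval variance of the p-box's per-draw [min, max] intervals."""
    lo_v, hi_v = interval_variance_bounds(pb.minima, pb.maxima, ddof=ddof)
    return CutInterval(lo_v, hi_v)


@dataclass(frozen=True)
class FractileMF:
    """Membership function of the output at a fixed fractile p.

    A completely generalized interval-valued fuzzy number: the UMF pass of the
    family yields ``umf``, the LMF pass ``lmf``, both trapezoids of height
    ``w`` (the α-grid ceiling). ``alpha_table`` retains the full per-level
    quantile intervals for each pass.
    """

    p: float
    height: float
    umf: GeneralizedFuzzyNumber
    lmf: GeneralizedFuzzyNumber
    alpha_table: dict[str, list[tuple[float, float, float]]]

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "height": self.height,
            "umf_knots": [self.umf.a, self.umf.b, self.umf.c, self.umf.d],
            "lmf_knots": [self.lmf.a, self.lmf.b, self.lmf.c, self.lmf.d],
            "alpha_table": {
                pass_name: [
                    {"alpha": a, "lo": lo, "hi": hi} for (a, lo, hi) in rows
                ]
                for pass_name, rows in self.alpha_table.items()
            },
        }


def fractile_mf(family: CDFFamily, p: float, mode: QuantileMode = "empirical") -> FractileMF:
    """Membership function of the output at fractile ``p``.

    For each pass and α-level, the interval between the p-quantiles of the
    minima and maxima curves; the α = 0 interval gives the trapezoid's
    support, the α = w interval its core, and the height is w.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"fractile must lie in (0, 1), got {p}")
    w = family.grid.w
    table: dict[str, list[tuple[float, float, float]]] = {}
    trapezoids: dict[str, GeneralizedFuzzyNumber] = {}
    for pass_ in (MembershipPass.UMF, MembershipPass.LMF):
        rows: list[tuple[float, float, float]] = []
        for m in family.pass_members(pass_):
            if mode == "analytic":
                lo = _analytic_curve_quantile(family.model, pass_, m.alpha, "min", p)
                hi = _analytic_curve_quantile(family.model, pass_, m.alpha, "max", p)
            else:
                lo = float(m.ecdf_min.quantile(p))
                hi = float(m.ecdf_max.quantile(p))
            rows.append((m.alpha, lo, hi))
        rows.sort(key=lambda r: r[0])
        table[pass_.value] = rows
        (_, a, d), (_, b, c) = rows[0], rows[-1]
        height = w if w > 0 else 1.0  # degenerate pure-MC family: crisp output
        trapezoids[pass_.value] = GeneralizedFuzzyNumber(a, b, c, d, w=height)
    return FractileMF(
        p=p,
        height=w if w > 0 else 1.0,
        umf=trapezoids[MembershipPass.UMF.value],
        lmf=trapezoids[MembershipPass.LMF.value],
        alpha_table=table,
    )
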