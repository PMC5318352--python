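# Methods

## Model and assumptions

`hybriduq` propagates a deterministic model whose inputs carry two kinds of
uncertainty at once: *variability* (aleatory — inherent randomness such as
body weight across a population) represented by probability distributions,
and *epistemic* uncertainty (incomplete knowledge — e.g. an expert's bounded
confidence in a concentration estimate) represented by generalized fuzzy
numbers (GFNs) and normal interval-valued fuzzy numbers (IVFNs). The two are
never collapsed into one another: randomness is sampled, possibility is
swept, and the output is reported as objects that keep the two dimensions
separate (families of CDFs, p-boxes, fractile membership functions).

Assumptions the implementation relies on:

* **Piecewise-linear membership.** GFNs are trapezoids `[a, b, c, d; w]`
  (triangles are `b = c`); membership rises linearly from 0 at `a` to `w` at
  `b`, is flat on the core, and falls linearly to 0 at `d`. Linearity between
  knots is the standard reading of the bracket notation and is what makes
  α-cuts closed intervals computable by interpolation:
  `[a + (b−a)·α/w, d − (d−c)·α/w]` for `α ≤ w`, empty above `w`. Zero-width
  legs use the limit convention (membership jumps to `w` at the knot) so the
  cut stays total.
* **Normal IVFNs at the engine.** The two-pass sweep is defined only when
  both bounding membership functions of every IVFN have height 1. Generalized
  IVFNs are representable and validate cleanly, but `propagate` rejects them
  with a dedicated `GeneralizedIvfnError` — the sweep's α-grid logic has no
  defined semantics for an LMF that vanishes below the grid ceiling.
* **Monotonicity for exact envelopes.** Per-draw extrema over the fuzzy box
  are taken at the `2^(s+n)` corners (vertex method). This is exact iff the
  model is monotone in each fuzzy argument — true of the multiplicative
  exposure model shipped as the case study (increasing in PEC and BCF,
  decreasing in BW; asserted by test against a dense-grid oracle). For
  non-monotone models the corners understate the envelope;
  `refine_nonmonotone=True` additionally evaluates a `refine_points`-per-cut
  lattice (cost grows as `refine_points^(s+n)`), which is a mitigation, not a
  guarantee.
* **Independence.** Probabilistic parameters get independent uniform streams;
  no dependence modelling.

## The sweep

The α-grid has 11 equally spaced levels from 0 to `w = min(heights of the
GFNs, 1)` — with only normal fuzzy inputs this is `0, 0.1, …, 1`; the
case-study PEC of height 0.8 gives `0, 0.08, …, 0.8`. Both grid endpoints are
evaluated. With no fuzzy parameters at all the grid degenerates to `{0}` and
the engine reduces to plain Monte Carlo (a warning is emitted).

Each probabilistic parameter's uniform stream is drawn once, before the α
loop, from a child seed spawned deterministically (sorted parameter-name
order) off the run seed, and mapped through the analytic quantile function.
Reusing the same draws across all α-levels and both passes makes the family
*exactly* nested per draw — as α grows the cuts shrink, so every per-draw
`[min, max]` interval is contained in the one below it, and every LMF-pass
interval is contained in the matching UMF-pass interval. The per-draw minima
and maxima are turned into two empirical CDFs per (pass, α); the full family
is 2 passes × 11 levels × 2 curves.

The extrema are taken per draw across corners rather than by post-hoc
envelope over `2^(s+n)` separate corner CDFs; for monotone models the two
constructions give identical envelope curves, and the per-draw form is what
makes the interval summaries (mean, variance over `[min_i, max_i]`) well
defined.

## Defaults and parameters that matter

| parameter | default | why |
|---|---|---|
| `n_mc` | 5000 | results for smooth low-dimensional models stabilise from ≈5000 draws; doubling changes the case-study summaries well under 1% |
| `alpha_steps` | 10 | 11-level grid; the conventional resolution for α-sweeps |
| `seed` | 20170131 (library default; **required** in run configs) | reproducibility is part of the contract — the CLI refuses a config without a seed |
| range percentiles | 0.5% / 99.5% | the p-box "range" is read at the 0.5th percentile of the minima curve and 99.5th of the maxima curve, not at the absolute sample extremes, which do not converge as draws grow; with BW normal this corresponds to z = ±2.576 |
| quantile mode | `empirical` | the general path; `analytic` pushes closed-form normal quantiles of a *single* probabilistic parameter through the corner evaluation (direction of monotonicity detected numerically) and makes the deterministic summaries exact and seed-free |
| `variance_ddof` | 0 | population (1/n) divisor for the interval variance; configurable |

Empirical quantiles use the type-1 generalized inverse `inf{x : F(x) ≥ p}`,
consistent with the right-continuous step CDF definition.

## Interval summaries

**Mean.** `[mean of per-draw minima, mean of per-draw maxima]` — sharp, since
the mean is monotone in each coordinate.

**Variance.** Sharp-or-conservative bounds of the sample variance over all
endpoint-respecting selections `x_i ∈ [min_i, max_i]`:

* *Lower bound (exact).* The minimizing selection clips a common value `m`
  into every interval; the variance is piecewise quadratic in `m` with vertex
  `m* = S_fixed/(n − k_free)` between endpoint breakpoints, so an
  O(n log n) sweep finds the exact minimum. It is 0 precisely when all
  intervals share a common point — which is the case for the arsenic study,
  where every draw's interval straddles the central risk values.
* *Upper bound.* Exact vectorized enumeration for n ≤ 16. For larger n the
  exact maximization is NP-hard in general, so the package reports the
  guaranteed dominating bound `min_t Σ max((lo_i − t)², (hi_i − t)²)/n`
  (piecewise quadratic in `t` with breakpoints at interval midpoints,
  minimized per segment). By construction it is never below *any* selection's
  variance, and it equals the true maximum whenever the farther-endpoint
  selection at the optimal `t` has mean `t` — the typical case for
  overlapping interval data. A midpoint-threshold split enumeration was
  considered and rejected: tested against exhaustive enumeration it can
  undershoot, because the optimality condition compares each midpoint with
  the mean of the *other* selections, which is not one global threshold.

For the case study at 5000 draws the bounds come out `[0, ≈3.3e-14]` (UMF
pass) and `[0, ≈2.0e-14]` (LMF pass), varying ≈1% with the seed.

**Fractile membership functions.** The reported trapezoid takes its support
from the α = 0 quantile interval and its core from the α = w interval. The
intermediate α-intervals are retained in `alpha_table` because the trapezoid
is an approximation at interior levels: when two fuzzy parameters multiply,
the quantile-interval endpoints are quadratic (convex) in α, so the linear
interpolation lies at or slightly above the true endpoints (≈1% at mid-grid
for the case study), exact at α = 0 and α = w. The trapezoidal report follows
the convention that arithmetic on trapezoidal fuzzy numbers is summarized by
a trapezoid of the same height.

## What the case study does and does not demonstrate

The arsenic model is real in structure (EPA food-chain exposure) but its
parameter set is illustrative. It exercises every code path with one
parameter per class (normal BW, fuzzy PEC, IVFN BCF, six constants) and is
monotone, so corner evaluation is exact and the analytic-quantile mode
applies. Passing its regression values therefore shows the sweep, the corner
evaluation and the summaries are correct for monotone multiplicative models —
it says nothing about non-monotone responses (only the dense-grid safety
valve and its documented limitation cover those), nor about dependence
between random inputs, nor about distribution families beyond normal/constant.

One unit note: the tabulated constants with CF = 1e-9 alone give hazard
quotients exactly 1000× the reference outputs; the model carries an explicit
`intake_unit_factor = 1e-3` (grams→kilograms of daily fish intake) as a
visible, configurable parameter rather than a silent correction.

## Numerical conventions

* Invariant checks use relative tolerance 1e-9 (pure arithmetic).
* `alpha_cut` collapses a sub-ulp `lo > hi` round-off at the core to the
  midpoint, keeping cuts valid at `α = w` reached through grid arithmetic.
* Artifact floats are serialized at 9 significant digits; reruns with one
  config + seed are byte-identical outside the manifest (which carries the
  timestamp).
* Derived child seeds are reduced mod 2³¹.

## Known limitations

* Curved (non-linear) membership shapes, discrete fuzzy sets and generalized
  IVFN propagation are out of scope; the latter is rejected loudly.
* Corner evaluation on non-monotone models silently understates envelopes
  unless refinement is enabled; refinement is exponential in the number of
  fuzzy parameters.
* The large-n variance upper bound is conservative in adversarial
  (non-fixed-point) configurations.
* Inline config models are limited to arithmetic expressions over a small
  numpy function whitelist.
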