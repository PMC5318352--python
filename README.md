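# hybriduq

Joint propagation of **variability** (randomness, handled probabilistically)
and **epistemic uncertainty** (knowledge gaps, handled possibilistically)
through a deterministic model — for risk assessors and modellers whose
inputs are a mix of probability distributions, generalized fuzzy numbers and
interval-valued fuzzy numbers.

## The method

Consider a model `M(P₁..Pₘ, G₁..Gₛ, F₁..Fₙ)` whose parameters split into

* `Pᵢ` — probability distributions (variability),
* `Gₖ` — generalized fuzzy numbers `[a, b, c, d; w]`, trapezoidal possibility
  distributions whose height `w ≤ 1` encodes bounded confidence,
* `Fₗ` — *normal* interval-valued fuzzy numbers (IVFNs): a pair of nested
  membership functions, upper (UMF) and lower (LMF), both of height 1, when a
  single membership curve is itself too precise a description.

The hybrid sweep:

1. build the α-grid `α = 0, w/10, …, w` with `w = min(wₖ, 1)` (11 levels);
2. draw one stream of uniform numbers per `Pᵢ` once, and map it through the
   analytic quantile function (inverse transform, default 5000 draws);
3. at each α take the α-cut of every fuzzy parameter — `s + n` closed
   intervals;
4. per Monte Carlo draw, evaluate `M` at all `2^(s+n)` corner combinations of
   the cut endpoints (vertex method — exact for models monotone in each fuzzy
   argument) and keep the minimum and maximum: across draws these form one
   lower and one upper empirical CDF;
5. sweep α: a nested **family of CDF pairs**;
6. run the sweep twice — once cutting each IVFN's UMF, once its LMF.

Two summaries follow. The α = 0 curves of a pass bound every CDF consistent
with the stated uncertainty: a **probability box** with interval-valued
range, mean and variance. And fixing a cumulative probability p, the
per-level quantile intervals trace out the **fractile membership function**:
a trapezoidal generalized fuzzy number of the output at fractile p (support
from α = 0, core from α = w, height w); the two passes give its upper and
lower membership functions.

## Worked example: arsenic in fish

The packaged case study is the EPA food-chain model for non-cancer risk from
eating arsenic-contaminated fish,

```
Risk = PEC · BCF · FIR · FR · EF · ED · CF / (BW · AT · RfD)
```

with constants AT = 25550 d, ED = 30 y, EF = 350 d/y, FR = 0.5, FIR = 170
g/day, CF = 1e-9, RfD = 3e-4 mg/(kg·day); body weight BW ~ Normal(70, 5) kg;
PEC = [4, 5, 6; 0.8] μg/l fuzzy; BCF an IVFN (UMF [35, 45, 55], LMF
[40, 45, 50] l/kg); and a g→kg intake factor of 1e-3 on FIR.

```python
import hybriduq as h

family = h.propagate(h.arsenic_risk_model(), n_mc=5000, seed=20170131)
pb = h.pbox(family, h.MembershipPass.UMF)
print(h.pbox_range(pb, mode="analytic"))
print(h.pbox_mean(pb))
print(h.fractile_mf(family, 0.95, mode="analytic").umf)
```

Running `python examples/arsenic_pbox.py` prints

```
UMF-pass p-box of the hazard quotient:
  range    [1.96688e-07, 6.72691e-07]
  mean     [2.3393e-07, 5.51406e-07]
  variance [0, 3.34174e-14]
LMF-pass p-box of the hazard quotient:
  range    [2.24787e-07, 6.11537e-07]
  mean     [2.67349e-07, 5.01278e-07]
  variance [0, 1.97803e-14]
```

— the hazard quotient lies between those two bounding CDFs no matter how the
epistemic uncertainty resolves; all bounds are orders of magnitude below 1.
`python examples/fractile_membership.py` prints the 95th-fractile risk as a
completely generalized IVFN of height 0.8,

```
UMF trapezoid [2.6388e-07, 4.05244e-07, 4.42941e-07, 6.22002e-07; 0.8]
LMF trapezoid [3.01577e-07, 4.14668e-07, 4.33517e-07, 5.65457e-07; 0.8]
```

meaning: at the most plausible readings of PEC and BCF (α = 0.8), the
95th-percentile risk is confined to roughly [4.05e-7, 4.43e-7]; admitting
every possible reading widens that to [2.64e-7, 6.22e-7].

The other example scripts cover α-cut arithmetic
(`examples/alpha_cut_basics.py`) and propagating your own model from Python
or a YAML config (`examples/custom_model.py`).

## Command line

```sh
hybriduq case-study --seed 20170131 --out out/          # regenerate the worked example
hybriduq run --config my_model.yaml --fractile 0.95     # any config-declared model
hybriduq validate --config my_model.yaml
```

`run` writes a bundle (family CSV, p-box CSVs + JSON summaries for both
passes, fractile-MF JSONs, manifest); identical config + seed reproduces it
byte-for-byte outside the manifest.

## Limitations

* Only models monotone in each fuzzy argument are handled exactly by corner
  evaluation; `refine_nonmonotone=True` adds a dense-lattice safety net.
* IVFN inputs must be normal (both heights 1); generalized IVFNs are rejected
  with a distinct error.
* Probabilistic parameters are independent; distribution families shipped:
  normal and constant.

See `docs/methods.md` for the model assumptions, numerical conventions and
design choices.
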