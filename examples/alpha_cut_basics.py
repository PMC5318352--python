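"""Generalized fuzzy numbers, IVFNs and their α-cuts.

Builds the two fuzzy inputs of the arsenic case study — a triangular
generalized fuzzy number for the predicted environmental concentration (PEC)
and a normal interval-valued fuzzy number for the bioaccumulation factor
(BCF) — and prints a few cuts. Each α-cut is the crisp interval of values
whose possibility is at least α; higher α means tighter, more plausible
intervals.
"""

from hybriduq import GeneralizedFuzzyNumber, IntervalValuedFuzzyNumber

pec = GeneralizedFuzzyNumber.triangular(4, 5, 6, w=0.8)  # μg/l, height 0.8
bcf = IntervalValuedFuzzyNumber(
    umf=GeneralizedFuzzyNumber.triangular(35, 45, 55),  # l/kg
    lmf=GeneralizedFuzzyNumber.triangular(40, 45, 50),
)

print(f"PEC = {pec}   (height {pec.height:g}; support {pec.support.lo:g}-{pec.support.hi:g})")
for alpha in (0.0, 0.4, 0.8):
    cut = pec.alpha_cut(alpha)
    print(f"  alpha={alpha:.1f}: cut [{cut.lo:g}, {cut.hi:g}], "
          f"membership at left end = {pec.membership(cut.lo):.2f}")

print(f"\nBCF = {bcf}")
for alpha in (0.0, 0.5, 1.0):
    cut = bcf.alpha_cut(alpha)
    print(f"  alpha={alpha:.1f}: LMF cut [{cut.lmf_cut.lo:g}, {cut.lmf_cut.hi:g}] "
          f"nested in UMF cut [{cut.umf_cut.lo:g}, {cut.umf_cut.hi:g}]")

# Above a membership function's height the cut is empty (3-case formula):
tall = IntervalValuedFuzzyNumber(
    umf=GeneralizedFuzzyNumber.triangular(0, 1, 2),
    lmf=GeneralizedFuzzyNumber.triangular(0.5, 1, 1.5, w=0.6),
)
cut = tall.alpha_cut(0.8)
print(f"\nalpha=0.8 above LMF height 0.6: LMF cut empty={cut.lmf_cut.empty}, "
      f"UMF cut [{cut.umf_cut.lo:g}, {cut.umf_cut.hi:g}]")
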