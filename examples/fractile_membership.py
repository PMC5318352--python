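"""Fractile membership functions of the arsenic risk.

Fixing a cumulative probability p and sweeping the α-grid turns the CDF
family into a fuzzy number of the risk at that fractile: the p-quantile
interval of the min/max curves at each α-level. The UMF pass gives the upper
membership function, the LMF pass the lower — together a completely
generalized interval-valued fuzzy number of height 0.8 (the PEC fuzzy
number's height caps the grid).
"""

import hybriduq as h

family = h.propagate(h.arsenic_risk_model(), n_mc=5000, seed=20170131)

for p in (0.95, 0.85):
    mf = h.fractile_mf(family, p, mode="analytic")
    print(f"{p:.0%} fractile of the hazard quotient (height {mf.height:g}):")
    print(f"  UMF trapezoid {mf.umf}")
    print(f"  LMF trapezoid {mf.lmf}")

mf = h.fractile_mf(family, 0.95, mode="analytic")
print("\n95% fractile, UMF pass, full alpha table (support shrinks toward the core):")
for alpha, lo, hi in mf.alpha_table["UMF"]:
    print(f"  alpha={alpha:.2f}: [{lo:.4g}, {hi:.4g}]")
print("Reading: with possibility at least 0.8, the 95th-percentile risk lies in")
print(f"[{mf.umf.b:.4g}, {mf.umf.c:.4g}]; relaxing to any possibility widens it to")
print(f"[{mf.umf.a:.4g}, {mf.umf.d:.4g}].")
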