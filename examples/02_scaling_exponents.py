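"""Scaling exponents: the random-walk null versus long memory.

DFA removes per-window linear trends from the integrated profile and fits
log F(L) against log L; uncorrelated steps give a slope β ≈ 0.5, while
persistent long-memory steps give β > 0.5. The rescaled-range Hurst
exponent α answers the same question with a different statistic (and a
known upward finite-sample bias on short uncorrelated series).
"""

from dnawalk import dfa_exponent, gen_iid_steps, gen_longmemory_steps, hurst_rs

n = 16384

iid = gen_iid_steps(n, seed=1)
est = dfa_exponent(iid)
print(f"fair-coin steps, n={n}:")
print(f"  DFA beta  = {est.exponent:.3f}  (r^2 of log-log fit {est.r_squared:.4f})")
print(f"  R/S alpha = {hurst_rs(iid).exponent:.3f}")
print("  beta near 0.5: no memory, the walk diffuses like a random walk\n")

for h in (0.6, 0.8):
    lm = gen_longmemory_steps(n, h, seed=1)
    print(f"long-memory steps (target exponent h={h}):")
    print(f"  DFA beta  = {dfa_exponent(lm).exponent:.3f}")
print("\nbeta rises with h: persistent correlations survive detrending.")
print("Sign-thresholding the Gaussian source attenuates the estimate slightly")
print("below the target h — expected, and within the estimator's tolerance.")
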