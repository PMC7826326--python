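"""Simulate the three erasure processes and check them against theory.

Full erasure: survival at lag t is exactly 1/(t+1), independent of the
valence distribution.  Single erasure: the store grows linearly as T/e.
Linear decay (no interference): survival falls like P_b(0)<a>/tau.
"""

import numpy as np

import forgetsim as fs

T = 100_000

cfg = fs.SimulationConfig("full_erasure", T=T, seed=0)
res = fs.simulate_full_erasure(cfg)
curve = fs.empirical_retention(res, max_lag=100)
print("full erasure (n=1): survival vs 1/(t+1)")
for t in (1, 10, 100):
    row = curve.iloc[t]
    print(
        f"  lag {t:>3}: {row['survival_fraction']:.4f} "
        f"(theory {1/(t+1):.4f}, "
        f"CI [{row['ci_low']:.4f}, {row['ci_high']:.4f}])"
    )
print(f"  store after {T} steps: {res.store_size[-1]} items (~log T)")

single = fs.simulate_single_erasure(
    fs.SimulationConfig("single_erasure", T=T, seed=0)
)
print(
    f"\nsingle erasure: N(T)/T = {single.store_size[-1]/T:.4f} "
    f"(theory 1/e = {1/np.e:.4f})"
)

decay = fs.simulate_linear_decay(
    fs.SimulationConfig("linear_decay", T=1_000_000, seed=0)
)
dcurve = fs.empirical_retention(decay, max_lag=100)
print("\nlinear decay, uniform a and b: tau * survival(tau) -> 0.5")
for tau in (10, 100):
    p = dcurve.iloc[tau]["survival_fraction"]
    print(f"  tau {tau:>3}: tau*R = {tau * p:.3f} "
          f"(theory {fs.kahana_adler_asymptote(0.5, 1.0, tau) * tau:.1f})")
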