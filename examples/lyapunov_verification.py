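"""Numerical Lyapunov verification of existence and ergodicity conditions.

Builds the existence Lyapunov function's weights and bound K, samples the
orthant to confirm LU <= K (global existence of a positive solution), then
assembles the ergodicity function's constants and probes the drift
condition LV <= -1 on the eight unbounded domains outside the compact box.
The small-x and all upper domains pass; the domains pinned only by small
y, z or w contain states where the positive part of the confinement term
dominates — the empirical maxima make that overshoot visible instead of
assuming the textbook bound.
"""

import numpy as np

import viralctl as v

params = v.example1()
ec = v.existence_constants(params)
print(f"existence weights: alpha={ec.alpha:g}, beta={ec.beta:g}, "
      f"gamma={ec.gamma:g}; bound K={ec.K:g}")
rng = np.random.default_rng(0)
states = np.exp(rng.uniform(np.log(1e-3), np.log(1e4), size=(50_000, 4)))
print(f"max LU over 5e4 log-uniform states: "
      f"{v.LU_value(states, params, ec).max():.2f} <= K  (existence OK)")

cc = v.ergodicity_constants(params, c1=-15.0, M=7, seed=0)
print(f"\nergodicity constants: c0={cc.c0:.5f}, c1={cc.c1:g}, M={cc.M}, "
      f"theta={cc.theta:.4f}, B={cc.B:.4g} (supremum of the confinement "
      "overshoot; positive, so the drift condition needs per-domain checks)")
report = v.verify_lv_negative(params, cc, n_samples=2000, seed=0)
for name, entry in report["domains"].items():
    flag = "pass" if entry["pass"] else "FAIL"
    print(f"  {name}: max LV = {entry['max_LV']:+.3e}  [{flag}]")
print("min ellipticity over the compact box:",
      f"{v.ellipticity_lower_bound(params, seed=0):.3e} > 0")
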