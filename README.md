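# viralctl

Stochastic within-host viral dynamics with CTL immune response and a
distributed activation delay: a seeded simulator plus a threshold-analysis
and Lyapunov-verification toolkit.

## The model

Inside a single host, susceptible target cells *x* are produced at rate λ,
die at rate *d*, and are infected by virus *y* at rate *e x y*. Infected
cells/virus die at rate *a* and are killed by cytotoxic T lymphocytes
(CTLs) *z* at rate *p y z*. CTL activation responds not to the current
viral load but to its recent history: the auxiliary compartment *w* is an
exponentially weighted average of past *y* with mean lag 1/σ (the linear
chain trick for a distributed delay). Environmental fluctuations enter as
multiplicative white noise on the first three compartments:

    dx = (λ − d x − e x y) dt + σ₁ x dB₁
    dy = (e x y − a y − p y z) dt + σ₂ y dB₂
    dz = (c w − b z) dt + σ₃ z dB₃
    dw = σ (y − w) dt

The long-run behaviour is governed by the stochastic reproduction ratio

    R0* = λ e a / ((a + σ₂²/2)² (d + σ₁²/2)),

which reduces to the deterministic R0 = λe/(ad) without noise. R0* > 1:
the process admits a unique ergodic stationary distribution and the
infection persists. R0* < 1: the viral load decays to zero almost surely,
with asymptotic exponent bounded by (a + σ₂²/2)(R0* − 1).

The package is aimed at modellers studying noise-induced extinction and
stationary behaviour in within-host epidemic models. It provides:

- **model closed forms** — drift, diffusion, R0, R0*, equilibria, the
  delay-kernel convolution oracle (`viralctl.model`);
- **seeded integrators** — the Milstein scheme (strong order 1 for this
  diagonal multiplicative noise), an Euler–Maruyama cross-check, and a
  log-space adaptive ODE solver for the deterministic limit
  (`viralctl.simulate`);
- **long-run statistics** — regime classification, stationary marginal
  summaries, extinction diagnostics (trailing ln-y slope), ergodic-average
  convergence (`viralctl.longrun`);
- **Lyapunov verification** — the existence function U with its uniform
  generator bound LU ≤ K, the ergodicity function V with its constants
  (c₀, c₁, M, θ, B), exact closed-form LU/LV, and sampled verification of
  the drift condition LV ≤ −1 off a compact box (`viralctl.lyapunov`);
- **experiment drivers** — the two built-in study presets, regime maps
  over parameter grids, plain-text config I/O (`viralctl.experiments`),
  and a thin `viralctl` CLI (`simulate`, `analyze`, `r0`, `run-example`,
  `regime-map`, `verify-lyapunov`).

Two presets encode the benchmark study conditions: `example1`
(λ = 1000, persistence) and `example2` (λ = 250, extinction), both with
d = 0.1, e = 0.002, a = 5, p = 0.2, c = 0.2, b = 0.3, σ = 0.2 and
σ₁ = σ₂ = σ₃ = 0.1.

## Worked example

```python
import viralctl as v

report = v.classify_regime(v.example1())
print(report.R0, report.R0_star, report.classification)
# 4.0 3.80191617525712 persistence

traj = v.simulate(v.example1(), v.SimConfig(dt=0.01, t_max=1000.0, seed=1))
mean_y, disc = v.ergodic_average(traj, lambda s: s[:, 1])
print(round(mean_y, 1), round(disc, 3))
# 52.8 0.041
```

R0* ≈ 3.80 > 1 places the first preset in the persistence regime. The
seeded trajectory confirms it: the time-averaged viral load settles near
52.8 (the deterministic interior equilibrium is y* ≈ 43.1; noise shifts
the stationary mean upward), and the 4.1% discrepancy between the two
halves of the post-burn-in window shows the ergodic average converging.
Running `python examples/extinction_run.py` shows the opposite regime: ten
replicates of the low-recruitment preset give a median trailing slope of
ln y of −0.076 per unit time — exponential eradication.

The `examples/` directory holds one narrative script per capability
(thresholds and regime maps, persistence, extinction, Lyapunov
verification, the delay-channel oracle); each prints the numbers it
computes and a line on what they mean.

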