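# Methods

## Model and state

The state (x, y, z, w) collects susceptible target cells, virus (or
infected cells — the model does not distinguish them), CTL effectors, and
the delayed activation signal. The Itô system is

    dx = (λ − d x − e x y) dt + σ₁ x dB₁
    dy = (e x y − a y − p y z) dt + σ₂ y dB₂
    dz = (c w − b z) dt + σ₃ z dB₃
    dw = σ (y − w) dt

with independent Brownian motions B₁..B₃. The w equation is the
linear-chain representation of a distributed delay: w(t) =
w(0)e^{−σt} + σ∫₀ᵗ e^{−σ(t−s)} y(s) ds, so CTL activation (c w) responds
to an exponentially weighted history of viral load with mean lag 1/σ.
The noise is diagonal and multiplicative; the w channel is noise-free,
which makes the diffusion degenerate (relevant for the ergodicity
argument, which needs ellipticity only on a compact box where w > 0).

Parameter units: λ in cells/time; d, e·(cells), a, c, b, σ in 1/time;
p in 1/(CTL·time); σ₁..σ₃ in time^(−1/2). Some sources write h for the
susceptible death rate; the config reader accepts `h` as an alias for
`d` and treats them as one parameter.

## Thresholds

R0 = λe/(ad) and R0* = λea/((a + σ₂²/2)²(d + σ₁²/2)). R0* ≤ R0 with
equality iff σ₁ = σ₂ = 0, and R0* is strictly decreasing in both
intensities — noise on the susceptible and virus channels is always
adverse to persistence. `classify_regime` thresholds R0* against 1
(boundary declared within relative tolerance 1e-12). The extinction-rate
bound (a + σ₂²/2)(R0* − 1) shares its sign with R0* − 1; below threshold
it upper-bounds limsup ln y(t)/t. The bound is reported but never
asserted against empirical slopes: its derivation replaces the
time-average of x by λ/(d + σ₁²/2) and then multiplies by a/(a + σ₂²/2),
which is loose near x ≈ λ/d — measured decay in the extinction preset is
an order of magnitude slower (≈ −0.05 to −0.005 per unit time against a
bound of −0.248). Only the sign is treated as reproducible.

On the presets the formula gives R0* = 3.802 (λ = 1000) and 0.9505
(λ = 250). The package treats the formula as definitive and the regime
classification — above or below 1 — as the reproducible claim.

## Integrators

`milstein_step` implements, per noisy component u with amplitude σᵢu,

    u' = u + f_u dt + σᵢ u √dt ξ + (σᵢ² u / 2) dt (ξ² − 1),

the strong-order-1 scheme for diagonal multiplicative noise; w gets the
noise-free Euler update. `euler_maruyama_step` drops the (ξ² − 1) terms
and serves as a cross-check. Draws are standard normals in fixed order
(ξ, η, ζ) per step from `numpy.random.Generator(PCG64(seed))`; a
trajectory is a deterministic function of (params, config), and ensemble
replicate r reuses the config with seed + r. Defaults dt = 0.01,
record_every = 10: at the preset noise levels the σ²·dt corrections are
~1e-6 of state and no positivity violations occur at this resolution
(violations are counted, never silent — default policy replaces a
non-positive post-step component by 1e-8 × its pre-step value; the
`resample` policy redraws that step's noise up to 100 times first).

Initial conditions default to (λ/d, 10, 10, 10): the susceptible pool at
its infection-free level plus a small inoculum in every compartment
(positivity is required for the stochastic flow; the deterministic
integrator also accepts boundary states such as (λ/d, 0, 0, 0)).

The deterministic limit is integrated in **log coordinates** with DOP853
at rtol = 1e-10. This is not cosmetic: with the persistence-regime rates
the noise-free flow undergoes relaxation oscillations whose viral-load
troughs descend hundreds of orders of magnitude (min y ≈ 1e-34 already on
t ∈ [0, 50]); a linear-space solver loses the sign of y to roundoff in
the trough, and the subsequent resurgence (growth rate ex − a ≈ 15/time)
amplifies the sign error to overflow. In log space positivity is
structural and the absolute tolerance controls relative accuracy of every
component.

### Path-matching conventions and measured accuracy

Path discrepancies are measured in sup norm **relative to each
component's path scale** (max |component| over the window). Pointwise
ratios are meaningless for this model: y and w traverse hundreds of
decades inside oscillation troughs, where any two consistent
discretizations drift apart multiplicatively with no fresh input.

Measured zero-noise agreement between the Milstein path and the ODE
reference (persistence rates, default initial state): 9.0e-3 at dt = 1e-3
and 9.1e-4 at dt = 1e-4 on [0, 20]; 0.67 and 8.4e-2 on [0, 50], where
trough-resurgence sensitivity multiplies the first-order error by ~10³.
The convergence is cleanly O(dt); sub-1e-3 agreement on [0, 50] would
need dt ≈ 1e-6. The delay channel compared against the exponential-kernel
trapezoid convolution of the same y samples: 6.6e-4 at dt = 0.01 in the
gentle extinction regime, but 1.2–1.5e-2 on burst-heavy persistence paths
(σ(y−w) reaches ~4e2/time in a burst), again shrinking at first order in
dt. Both gaps are truncation error of the printed scheme, not
implementation error; the corresponding fixed-tolerance acceptance tests
document the stated thresholds and fail where the dynamics make them
unattainable.

## Long-run statistics

`estimate_stationary` summarizes the post-burn-in segment (default
burn-in 20%; transients decay well inside the first fifth at horizons
≥ 500): mean, variance, 5/25/50/75/95% quantiles, Freedman–Diaconis
histogram with the bin count capped at 512 (the viral-load marginal's
trough tail spans hundreds of decades and would otherwise demand an
unrepresentable number of bins), and an autocorrelation-based effective
sample size. At least 1000 post-burn-in points are required.

`lyapunov_exponent_y` fits ln y against t by OLS over the trailing window
(default 50%) — the computable finite-horizon proxy for limsup ln y/t —
excluding non-positive samples. "Extinct" is operationalized scale-free
as y < 1e-6 · y(0) sustained contiguously for ≥ 10% of the horizon.
`ergodic_average` reports the post-burn-in time average of an observable
plus the relative discrepancy of its two half-window averages as a
convergence diagnostic. `asymptotic_diagnostics` evaluates the
sublinearity statistics ln(uᵢ(T))/T and (x+y+z+w)(T)/T at the horizon.

In the decoupled limit e = 0 the susceptible pool is the linear
multiplicative-noise SDE dx = (λ − dx)dt + σ₁x dB with inverse-gamma
stationary law (shape 1 + 2d/σ₁², scale 2λ/σ₁², mean λ/d);
`decoupled_susceptible_stationary_law` exposes it as a frozen scipy
distribution and the acceptance suite checks a long simulated marginal
against it (mean within 2%, KS distance < 0.05 at ≥ 1e4 post-burn-in
points, horizon 25000 so that the ~10-time-unit autocorrelation leaves
≈ 10³ effective samples).

## Lyapunov machinery

Generator: Lf = ∇f·drift + ½(σ₁²x² f_xx + σ₂²y² f_yy + σ₃²z² f_zz).

**Existence.** U = (x − α − α ln(x/α)) + (y − β − β ln(y/β)) +
(z − 1 − ln z) + γ(w − 1 − ln w) with α = (a−c)/e, β = b/p, γ = c/σ —
the unique weights cancelling the unbounded cross terms (αe + γσ = a,
βp = b, γσ = c), which requires a > c. Then LU ≤ K =
λ + αd + βa + b + c + ½(ασ₁² + βσ₂² + σ₃²) holds exactly on the whole
orthant (every remaining term is non-positive); the suite verifies the
bound on 1e5 log-uniform states. K = 1260.0125 for the persistence
preset.

**Ergodicity** (requires R0* > 1). V = M(−ln x − c₀ ln y) − c₁ ln y −
ln z − ln w + S^{θ+1}/(θ+1), S = x + y + (a/4c)z + (a/2σ)w, with
c₀ = λe/(a + σ₂²/2)², c₁ ≤ −(2 + b + σ + ½(σ₂² + σ₃²))/a,
M ≥ 2/((d + σ₁²/2)(R0* − 1)) (smallest integer by default; 7 for the
persistence preset), and θ in (0, min{a/(a+σ₂²), b/(b+σ₃²), d/(d+σ₁²)})
— midpoint by default, which keeps the degree-(θ+1) decay terms dominant
at infinity. LU and LV are evaluated from exact partial derivatives, not
from proof-chain inequalities, and are cross-checked in the tests against
a finite-difference application of the generator executed in 50-digit
arithmetic with independent transcriptions of U and V (double precision
cannot form the second difference of a ~1e6 power term against an O(1)
coordinate without catastrophic cancellation).

Two structural caveats are made explicit rather than assumed away:

- **B is positive.** The constant B — the supremum over the orthant of
  the bounded part of L applied to the confinement term — contains
  λS^θ > 0, which dominates at moderate states (≈ +8e3 near x = 100);
  multi-start log-parameterized maximization gives B ≈ +4.1e4 for the
  persistence preset. A negative uniform bound does not exist, so the
  drift condition cannot be certified from B alone.
- **Coercivity constrains c₁ from below.** The ln y coefficient of V is
  −(Mc₀ + c₁); V is bounded below (coercive at the y-face) only when
  c₁ > −Mc₀ ≈ −0.559. The default ceiling choice c₁ = −0.502 satisfies
  this; the larger-margin choice c₁ = −15 does not (V → −∞ like
  14.4·ln y), which the test suite documents.

`verify_lv_negative` samples the eight unbounded domains outside the
compact box Dε = (ε, 1/ε)⁴ (one coordinate pinned below ε or above 1/ε;
the z/w domains combine both), evaluates exact LV, and reports the
per-domain maximum, its location and a pass flag against LV ≤ −1.
Unbounded coordinates are sampled log-uniformly up to 1e6 — beyond, the
dominant negative power terms only strengthen the condition — and down to
1e-8. With the larger-margin constants and ε = 1e-3 the small-x domain and
all three upper domains pass by large margins; the domains pinned only by
small y, z or w contain states (x ≈ 3e3, other coordinates small) where
the λS^θ overshoot makes LV ≈ +2.7e4. Reporting these maxima, rather than
assuming the textbook case bounds, is the point of the verification.

## Synthetic data and scope

All inputs are generated by the simulator itself from the two presets; no
external data exists for this model. The simulator emulates exactly the
study conditions (the preset rates, noise intensities 0.1, default
initial state); it does not emulate measurement error, patient
heterogeneity, or parameter uncertainty, so passing tests certify the
mathematical behaviour of this SDE, not fit to clinical data. Problem
sizes used by the test suite — horizons 2000 (persistence diagnostics),
3000 × 20 replicates (extinction ensemble), 25000 (decoupled stationary
law), 1e5 states (generator bound) — were chosen so each regime signal
clearly exceeds Monte-Carlo noise at the preset intensities.

## Known limitations

- Figure-level output is regime-qualitative: the original study states no
  seeds, initial conditions, step sizes or horizons, so trajectories are
  reproducible only against this package's own seeds.
- The Milstein scheme is fixed-step; no adaptive stochastic stepping, and
  the w line is first-order by construction.
- The drift-condition check is sampled, not certified: it can refute
  LV ≤ −1 (it does, in four domains) but cannot prove it.
- The extinction-rate bound is sign-only in practice (see Thresholds).
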