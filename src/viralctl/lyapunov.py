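"""Lyapunov-function machinery for global existence and ergodicity.

Two coercive functions drive the qualitative theory of the model:

* ``U`` (global existence): a sum of terms u - k - k ln(u/k), whose
  generator value LU is bounded above by a constant K over the whole
  positive orthant.  The weights alpha = (a-c)/e, beta = b/p,
  gamma = c/sigma_delay are chosen so the unbounded cross terms cancel
  exactly (alpha e + gamma sigma = a, beta p = b, gamma sigma = c).

* ``V`` (ergodicity, requires R0* > 1): a weighted combination of
  negative logs and a power-law confinement term
  (1/(theta+1)) (x + y + (a/4c) z + (a/2sigma) w)^(theta+1).  The drift
  condition for a stationary distribution asks LV <= -1 outside a compact
  box D_eps; :func:`verify_lv_negative` probes that condition by sampling
  the eight unbounded complement domains and reporting the empirical
  maximum of the exact LV in each.

The generator of the diffusion acts on a C^2 function f as

    Lf = grad(f) . drift + 1/2 (sigma1^2 x^2 f_xx + sigma2^2 y^2 f_yy
                                + sigma3^2 z^2 f_zz),

since the noise is diagonal and the w channel is noise-free.  LU and LV
are evaluated from exact partial derivatives, not from the chain of
inequalities used in pencil-and-paper proofs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import drift, stochastic_reproduction_number
from .params import ModelParams, validate_params

__all__ = [
    "ExistenceConstants",
    "ErgodicityConstants",
    "RegionSpec",
    "existence_constants",
    "U_value",
    "LU_value",
    "ergodicity_constants",
    "V_value",
    "LV_value",
    "confinement_overshoot",
    "verify_lv_negative",
    "ellipticity_lower_bound",
]


@dataclass(frozen=True)
class ExistenceConstants:
    """Weights of U and its generator bound K (requires a > c)."""

    alpha: float
    beta: float
    gamma: float
    K: float


@dataclass(frozen=True)
class ErgodicityConstants:
    """Constants of V (requires R0* > 1).

    c0 : weight coupling the -ln x and -ln y wells, lambda e/(a+sigma2^2/2)^2.
    c1 : negative weight on -ln y; any value <= -(2+b+sigma+ (sigma2^2
         + sigma3^2)/2)/a is admissible.
    M  : integer weight >= 2/((d+sigma1^2/2)(R0*-1)) so the y-well drift
         dominates in the small-y domain.
    theta : power of the confinement term, in (0, min{a/(a+sigma2^2),
         b/(b+sigma3^2), d/(d+sigma1^2)}) so the degree-(theta+1) decay
         terms dominate the noise cross terms at infinity.
    B  : numerically evaluated supremum of the bounded part of the
         confinement term's generator (see :func:`confinement_overshoot`).
    """

    c0: float
    c1: float
    M: int
    theta: float
    B: float


@dataclass(frozen=True)
class RegionSpec:
    """Sampling geometry for the drift-condition check.

    ``epsilon`` is the box parameter of D_eps = (eps, 1/eps)^4; the eight
    complement domains pin one coordinate below eps, above 1/eps, or (for
    the z/w corner domains) combine both.  Unbounded coordinates are
    sampled log-uniformly down to ``inner_floor`` and up to ``outer``:
    beyond ``outer`` the dominant negative power terms only strengthen
    the condition, and the truncation is reported with the results.
    """

    epsilon: float = 1e-3
    inner_floor: float = 1e-8
    outer: float = 1e6

    def __post_init__(self):
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if not 0.0 < self.inner_floor < self.epsilon:
            raise ValueError("inner_floor must lie below epsilon")
        if self.outer <= 1.0 / self.epsilon:
            raise ValueError("outer must exceed 1/epsilon")


# ---------------------------------------------------------------------------
# Global existence: U, LU, K

def existence_constants(params: ModelParams) -> ExistenceConstants:
    """Weights alpha=(a-c)/e, beta=b/p, gamma=c/sigma and the bound

        K = lambda + alpha d + beta a + b + c
            + (alpha sigma1^2 + beta sigma2^2 + sigma3^2)/2,

    valid whenever a > c (otherwise alpha would be non-positive and U
    would lose coercivity in x)."""
    validate_params(params)
    if params.a <= params.c:
        raise ValueError(
            f"existence constants require a > c (got a={params.a}, "
            f"c={params.c}): alpha=(a-c)/e would be non-positive")
    if params.e <= 0:
        raise ValueError("existence constants require e > 0")
    alpha = (params.a - params.c) / params.e
    beta = params.b / params.p
    gamma = params.c / params.sigma_delay
    K = (params.lambda_ + alpha * params.d + beta * params.a + params.b
         + params.c
         + 0.5 * (alpha * params.sigma1**2 + beta * params.sigma2**2
                  + params.sigma3**2))
    return ExistenceConstants(alpha=alpha, beta=beta, gamma=gamma, K=K)


def _split(state):
    s = np.asarray(state, dtype=float)
    if np.any(s <= 0):
        raise ValueError("Lyapunov functions require strictly positive "
                         "states")
    return s, s[..., 0], s[..., 1], s[..., 2], s[..., 3]


def U_value(state, consts: ExistenceConstants) -> np.ndarray:
    """The existence Lyapunov function; non-negative, zero only at
    (alpha, beta, 1, 1)."""
    _, x, y, z, w = _split(state)
    al, be, ga = consts.alpha, consts.beta, consts.gamma
    val = ((x - al - al * np.log(x / al))
           + (y - be - be * np.log(y / be))
           + (z - 1.0 - np.log(z))
           + ga * (w - 1.0 - np.log(w)))
    return val


def LU_value(state, params: ModelParams,
             consts: ExistenceConstants) -> np.ndarray:
    """Exact generator value LU; satisfies LU <= K on the whole orthant."""
    s, x, y, z, w = _split(state)
    f = drift(s, params)
    al, be, ga = consts.alpha, consts.beta, consts.gamma
    ito = 0.5 * (al * params.sigma1**2 + be * params.sigma2**2
                 + params.sigma3**2)
    return ((1.0 - al / x) * f[..., 0]
            + (1.0 - be / y) * f[..., 1]
            + (1.0 - 1.0 / z) * f[..., 2]
            + ga * (1.0 - 1.0 / w) * f[..., 3]
            + ito)


# ---------------------------------------------------------------------------
# Ergodicity: V, LV, constants

def _weights(params: ModelParams) -> tuple[float, float]:
    """(a/4c, a/2sigma): weights of z and w in the confinement sum."""
    return (params.a / (4.0 * params.c),
            params.a / (2.0 * params.sigma_delay))


def _theta_ceiling(params: ModelParams) -> float:
    return min(params.a / (params.a + params.sigma2**2),
               params.b / (params.b + params.sigma3**2),
               params.d / (params.d + params.sigma1**2))


def confinement_overshoot(state, params: ModelParams,
                          theta: float) -> np.ndarray:
    """Bounded part of the confinement term's generator.

    With S = x + y + (a/4c) z + (a/2sigma) w and
    Q = sigma1^2 x^2 + sigma2^2 y^2 + (a/4c)^2 sigma3^2 z^2, returns

        lambda S^theta + (theta/2) S^(theta-1) Q
        - (1-theta) [d x^(th+1) + (a/2) y^(th+1)
                     + (a/4c)^(th+1) b z^(th+1)
                     + (a/4)(a/2sigma)^theta w^(th+1)],

    i.e. what is left of L applied to S^(theta+1)/(theta+1) after
    reserving a theta-fraction of each degree-(theta+1) decay term.  Its
    supremum over the orthant is the constant B: finite because
    theta < min{a/(a+sigma2^2), b/(b+sigma3^2), d/(d+sigma1^2)} makes the
    negative terms dominate at infinity, but strictly positive, since the
    lambda S^theta term wins at moderate states."""
    _, x, y, z, w = _split(state)
    wz, ww = _weights(params)
    S = x + y + wz * z + ww * w
    Q = (params.sigma1**2 * x**2 + params.sigma2**2 * y**2
         + wz**2 * params.sigma3**2 * z**2)
    one = 1.0 - theta
    return (params.lambda_ * S**theta
            + 0.5 * theta * S**(theta - 1.0) * Q
            - one * (params.d * x**(theta + 1.0)
                     + 0.5 * params.a * y**(theta + 1.0)
                     + wz**(theta + 1.0) * params.b * z**(theta + 1.0)
                     + 0.25 * params.a * ww**theta * w**(theta + 1.0)))


def _maximize_overshoot(params: ModelParams, theta: float, seed: int,
                        n_search: int = 20000) -> float:
    """Multi-start, log-parameterized maximization of the overshoot."""
    rng = np.random.default_rng(seed)
    logs = rng.uniform(np.log(1e-6), np.log(1e6), size=(n_search, 4))
    vals = confinement_overshoot(np.exp(logs), params, theta)
    order = np.argsort(vals)[::-1][:8]

    def neg(u):
        return -float(confinement_overshoot(np.exp(u), params, theta))

    best = float(vals[order[0]])
    for idx in order:
        res = minimize(neg, logs[idx], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 2000})
        best = max(best, -float(res.fun))
    return best


def ergodicity_constants(params: ModelParams, c1: float | None = None,
                         M: int | None = None, theta: float | None = None,
                         seed: int = 0) -> ErgodicityConstants:
    """Constants of the ergodicity Lyapunov function V.

    Defaults: c1 at its admissible ceiling -(2+b+sigma+(sigma2^2+
    sigma3^2)/2)/a; M the smallest integer >= 2/((d+sigma1^2/2)(R0*-1));
    theta the midpoint of its admissible interval; B by numerical
    maximization (deterministic given ``seed``).  Raises when R0* <= 1
    (the persistence hypothesis fails) or when a supplied constant
    violates its admissibility condition.
    """
    validate_params(params)
    r0s = stochastic_reproduction_number(params)
    if r0s <= 1.0:
        raise ValueError(
            f"ergodicity constants require R0* > 1, got R0* = {r0s:.6g}: "
            "the persistence hypothesis fails for this parameter set")
    a_eff = params.a + 0.5 * params.sigma2**2
    d_eff = params.d + 0.5 * params.sigma1**2
    c0 = params.lambda_ * params.e / a_eff**2

    c1_ceiling = -(2.0 + params.b + params.sigma_delay
                   + 0.5 * (params.sigma2**2 + params.sigma3**2)) / params.a
    if c1 is None:
        c1 = c1_ceiling
    elif c1 > c1_ceiling:
        raise ValueError(
            f"c1 must be <= {c1_ceiling:.6g}, got {c1}")

    M_floor = 2.0 / (d_eff * (r0s - 1.0))
    if M is None:
        M = int(math.ceil(M_floor))
    elif M < M_floor:
        raise ValueError(f"M must be >= {M_floor:.6g}, got {M}")

    ceiling = _theta_ceiling(params)
    if theta is None:
        theta = 0.5 * ceiling
    elif not 0.0 < theta < ceiling:
        raise ValueError(
            f"theta must lie in (0, {ceiling:.6g}), got {theta}")

    B = _maximize_overshoot(params, theta, seed)
    return ErgodicityConstants(c0=c0, c1=c1, M=int(M), theta=theta, B=B)


def V_value(state, params: ModelParams,
            consts: ErgodicityConstants) -> np.ndarray:
    """The ergodicity Lyapunov function

        V = M(-ln x - c0 ln y) - c1 ln y - ln z - ln w
            + S^(theta+1)/(theta+1),

    coercive on the open orthant: it blows up at every boundary face and
    at infinity."""
    _, x, y, z, w = _split(state)
    wz, ww = _weights(params)
    S = x + y + wz * z + ww * w
    th = consts.theta
    return (consts.M * (-np.log(x) - consts.c0 * np.log(y))
            - consts.c1 * np.log(y) - np.log(z) - np.log(w)
            + S**(th + 1.0) / (th + 1.0))


def LV_value(state, params: ModelParams,
             consts: ErgodicityConstants) -> np.ndarray:
    """Exact generator value LV from the exact partial derivatives of V
    (no proof-chain inequalities)."""
    s, x, y, z, w = _split(state)
    f = drift(s, params)
    wz, ww = _weights(params)
    th = consts.theta
    S = x + y + wz * z + ww * w
    Sp = S**th
    Spp = th * S**(th - 1.0)
    mc = consts.M * consts.c0 + consts.c1

    Vx = -consts.M / x + Sp
    Vy = -mc / y + Sp
    Vz = -1.0 / z + wz * Sp
    Vw = -1.0 / w + ww * Sp
    Vxx = consts.M / x**2 + Spp
    Vyy = mc / y**2 + Spp
    Vzz = 1.0 / z**2 + wz**2 * Spp

    return (Vx * f[..., 0] + Vy * f[..., 1] + Vz * f[..., 2]
            + Vw * f[..., 3]
            + 0.5 * (params.sigma1**2 * x**2 * Vxx
                     + params.sigma2**2 * y**2 * Vyy
                     + params.sigma3**2 * z**2 * Vzz))


# ---------------------------------------------------------------------------
# Sampled verification of the drift condition

def _domain_boxes(region: RegionSpec) -> dict[str, list[tuple[float, float]]]:
    eps = region.epsilon
    flo = region.inner_floor
    out = region.outer
    inv = 1.0 / eps
    full = (flo, out)
    low = (flo, eps)
    high = (inv, out)
    mid = (eps, inv)
    return {
        "D1": [low, full, full, full],    # x below eps
        "D2": [full, low, full, full],    # y below eps
        "D3": [full, full, low, mid],     # z below eps, w moderate
        "D4": [full, full, mid, low],     # w below eps, z moderate
        "D5": [high, full, full, full],   # x above 1/eps
        "D6": [full, high, full, full],   # y above 1/eps
        "D7": [full, full, high, full],   # z above 1/eps
        "D8": [full, full, full, high],   # w above 1/eps
    }


def verify_lv_negative(params: ModelParams, consts: ErgodicityConstants,
                       region: RegionSpec | None = None,
                       n_samples: int = 2000, seed: int = 0) -> dict:
    """Sampled check of the drift condition LV <= -1 off the compact box.

    Samples ``n_samples`` states log-uniformly in each of the eight
    complement domains (unbounded coordinates truncated at
    ``region.outer``), evaluates the exact LV and reports the per-domain
    maximum, its location, and a pass flag (max <= -1).  Failures are
    reported, not raised: the pencil-and-paper case bounds silently assume
    relations between epsilon and the constants that do not hold uniformly,
    so the honest output is the empirical maximum itself.
    """
    r0s = stochastic_reproduction_number(params)
    if r0s <= 1.0:
        raise ValueError(
            f"drift-condition check requires R0* > 1, got {r0s:.6g}")
    if region is None:
        region = RegionSpec()
    rng = np.random.default_rng(seed)
    report: dict = {
        "epsilon": region.epsilon,
        "outer_truncation": region.outer,
        "n_samples_per_domain": n_samples,
        "theta": consts.theta,
        "c1": consts.c1,
        "M": consts.M,
        "domains": {},
    }
    all_pass = True
    for name, box in _domain_boxes(region).items():
        logs = np.column_stack([
            rng.uniform(np.log(lo), np.log(hi), size=n_samples)
            for lo, hi in box
        ])
        states = np.exp(logs)
        vals = LV_value(states, params, consts)
        imax = int(np.argmax(vals))
        passed = bool(vals[imax] <= -1.0)
        all_pass &= passed
        report["domains"][name] = {
            "max_LV": float(vals[imax]),
            "argmax_state": [float(v) for v in states[imax]],
            "pass": passed,
        }
    report["all_pass"] = bool(all_pass)
    return report


def ellipticity_lower_bound(params: ModelParams,
                            region: RegionSpec | None = None,
                            n_samples: int = 2000, seed: int = 0) -> float:
    """Minimum of min(sigma1^2 x^2, sigma2^2 y^2, sigma3^2 z^2, w^2) over
    sampled states of the compact box D_eps: strictly positive whenever all
    noise intensities are, which is the uniform-ellipticity ingredient of
    the stationary-distribution criterion."""
    if region is None:
        region = RegionSpec()
    rng = np.random.default_rng(seed)
    eps = region.epsilon
    logs = rng.uniform(np.log(eps), np.log(1.0 / eps), size=(n_samples, 4))
    s = np.exp(logs)
    vals = np.min(np.column_stack([
        params.sigma1**2 * s[:, 0]**2,
        params.sigma2**2 * s[:, 1]**2,
        params.sigma3**2 * s[:, 2]**2,
        s[:, 3]**2,
    ]), axis=1)
    return float(vals.min())
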