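"""Numerical integration of the stochastic infection model.

The workhorse is the Milstein scheme for the diagonal multiplicative noise
of the model: each noisy component i with amplitude sigma_i * u gains the
strong-order-1 correction (sigma_i^2 u / 2) dt (xi^2 - 1) on top of
Euler-Maruyama.  The delay channel w carries no noise, so its update is
plain Euler.  An Euler-Maruyama stepper is kept as a cross-check, and the
noise-free limit is integrated with an adaptive ODE solver.

Reproducibility contract: a trajectory is a deterministic function of
(params, config) including the seed.  Noise is drawn from
numpy.random.Generator(PCG64(seed)) in per-step order (xi, eta, zeta);
ensemble replicate r uses seed + r.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import drift
from .params import ModelParams, params_to_dict, validate_params

__all__ = [
    "SimConfig",
    "Trajectory",
    "milstein_step",
    "euler_maruyama_step",
    "simulate",
    "simulate_deterministic",
    "simulate_ensemble",
    "default_initial_state",
]

_CLAMP_FLOOR = 1e-8  # clamped component = floor * pre-step value
_RESAMPLE_MAX_TRIES = 100


def default_initial_state(params: ModelParams) -> np.ndarray:
    """(lambda/d, 10, 10, 10): susceptible pool at its infection-free level
    plus a small positive inoculum in every other compartment."""
    return np.array([params.lambda_ / params.d, 10.0, 10.0, 10.0])


@dataclass(frozen=True)
class SimConfig:
    """Integration configuration.

    dt : step size; t_max : horizon; seed : RNG seed; scheme : "milstein"
    or "euler"; initial_state : strictly positive 4-vector or None for the
    preset-dependent default; positivity_policy : "clamp" replaces a
    non-positive post-step component by 1e-8 x its pre-step value (counted),
    "resample" redraws that step's noise (up to 100 tries, then clamps);
    record_every : thinning factor for the stored path.
    """

    dt: float = 0.01
    t_max: float = 500.0
    seed: int = 0
    scheme: str = "milstein"
    initial_state: Sequence[float] | None = None
    positivity_policy: str = "clamp"
    record_every: int = 10

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_max < self.dt:
            raise ValueError("t_max must be at least one step")
        if self.scheme not in ("milstein", "euler"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.positivity_policy not in ("clamp", "resample"):
            raise ValueError(
                f"unknown positivity_policy {self.positivity_policy!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be a positive integer")
        if self.initial_state is not None:
            s = np.asarray(self.initial_state, dtype=float)
            # boundary states (zero components) are allowed here so the
            # deterministic integrator can start at e.g. the infection-free
            # equilibrium; the stochastic integrator additionally requires
            # strict positivity.
            if s.shape != (4,) or not np.all(s >= 0) or not np.all(
                    np.isfinite(s)):
                raise ValueError(
                    "initial_state must be a non-negative finite 4-vector")


@dataclass
class Trajectory:
    """A recorded path on a uniform grid, with full provenance."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 4), columns x, y, z, w
    params: ModelParams
    config: SimConfig
    scheme: str
    n_positivity_events: int = 0

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def w(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def summary(self) -> dict:
        """JSON-serializable sidecar summary."""
        return {
            "seed": self.config.seed,
            "dt": self.config.dt,
            "t_max": self.config.t_max,
            "scheme": self.scheme,
            "record_every": self.config.record_every,
            "n_positivity_events": self.n_positivity_events,
            "final_state": [float(v) for v in self.final_state],
            "params": params_to_dict(self.params),
        }

    def to_csv(self, path, header_comment: str | None = None) -> None:
        """Write 't,x,y,z,w' rows with 17 significant digits (deterministic
        bytes for a fixed trajectory)."""
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("t,x,y,z,w\n")
            for t, row in zip(self.times, self.states):
                fh.write("%.17g,%.17g,%.17g,%.17g,%.17g\n"
                         % (t, row[0], row[1], row[2], row[3]))

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _deterministic_increment(s, params, dt):
    f = drift(s, params)
    return np.asarray(s, dtype=float) + f * dt


def milstein_step(state, params: ModelParams, dt: float, draws) -> np.ndarray:
    """One Milstein update.  ``state`` (..., 4), ``draws`` (..., 3) standard
    normals in order (xi, eta, zeta).  Returns the raw update; positivity
    policies are applied by :func:`simulate`, not here."""
    s = np.asarray(state, dtype=float)
    g = np.asarray(draws, dtype=float)
    x, y, z, w = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    xi, eta, zeta = g[..., 0], g[..., 1], g[..., 2]
    sqdt = math.sqrt(dt)
    out = np.empty(np.broadcast(s[..., 0], g[..., 0]).shape + (4,))
    out[..., 0] = (x + (params.lambda_ - params.d * x - params.e * x * y) * dt
                   + params.sigma1 * x * sqdt * xi
                   + 0.5 * params.sigma1**2 * x * dt * (xi * xi - 1.0))
    out[..., 1] = (y + (params.e * x * y - params.a * y - params.p * y * z) * dt
                   + params.sigma2 * y * sqdt * eta
                   + 0.5 * params.sigma2**2 * y * dt * (eta * eta - 1.0))
    out[..., 2] = (z + (params.c * w - params.b * z) * dt
                   + params.sigma3 * z * sqdt * zeta
                   + 0.5 * params.sigma3**2 * z * dt * (zeta * zeta - 1.0))
    out[..., 3] = w + params.sigma_delay * (y - w) * dt
    return out


def euler_maruyama_step(state, params: ModelParams, dt: float,
                        draws) -> np.ndarray:
    """One Euler-Maruyama update: Milstein without the (draw^2 - 1) terms."""
    s = np.asarray(state, dtype=float)
    g = np.asarray(draws, dtype=float)
    x, y, z, w = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    xi, eta, zeta = g[..., 0], g[..., 1], g[..., 2]
    sqdt = math.sqrt(dt)
    out = np.empty(np.broadcast(s[..., 0], g[..., 0]).shape + (4,))
    out[..., 0] = (x + (params.lambda_ - params.d * x - params.e * x * y) * dt
                   + params.sigma1 * x * sqdt * xi)
    out[..., 1] = (y + (params.e * x * y - params.a * y - params.p * y * z) * dt
                   + params.sigma2 * y * sqdt * eta)
    out[..., 2] = (z + (params.c * w - params.b * z) * dt
                   + params.sigma3 * z * sqdt * zeta)
    out[..., 3] = w + params.sigma_delay * (y - w) * dt
    return out


def simulate(params: ModelParams, config: SimConfig) -> Trajectory:
    """Integrate the SDE over [0, t_max].

    Deterministic in (params, config): identical inputs give bitwise
    identical trajectories.  Raises ``RuntimeError`` with the step index if
    the state overflows to a non-finite value.
    """
    validate_params(params)
    lam, d, e, a, p, c, b = (params.lambda_, params.d, params.e, params.a,
                             params.p, params.c, params.b)
    sig, s1, s2, s3 = (params.sigma_delay, params.sigma1, params.sigma2,
                       params.sigma3)
    dt = config.dt
    sqdt = math.sqrt(dt)
    milstein = config.scheme == "milstein"
    resample = config.positivity_policy == "resample"

    init = (default_initial_state(params) if config.initial_state is None
            else np.asarray(config.initial_state, dtype=float))
    if not np.all(init > 0):
        raise ValueError("stochastic simulation requires a strictly "
                         "positive initial state")
    x, y, z, w = (float(init[0]), float(init[1]), float(init[2]),
                  float(init[3]))
    n_steps = int(round(config.t_max / dt))
    rec = config.record_every
    n_rec = n_steps // rec
    states = np.empty((n_rec + 1, 4))
    states[0] = (x, y, z, w)

    rng = np.random.default_rng(config.seed)
    n_events = 0
    step = 0
    chunk = 65536
    irec = 1
    while step < n_steps:
        m = min(chunk, n_steps - step)
        draws = rng.standard_normal((m, 3))
        for i in range(m):
            xi = draws[i, 0]
            eta = draws[i, 1]
            zeta = draws[i, 2]
            tries = 0
            while True:
                nx = (x + (lam - d * x - e * x * y) * dt
                      + s1 * x * sqdt * xi)
                ny = (y + (e * x * y - a * y - p * y * z) * dt
                      + s2 * y * sqdt * eta)
                nz = (z + (c * w - b * z) * dt
                      + s3 * z * sqdt * zeta)
                if milstein:
                    nx += 0.5 * s1 * s1 * x * dt * (xi * xi - 1.0)
                    ny += 0.5 * s2 * s2 * y * dt * (eta * eta - 1.0)
                    nz += 0.5 * s3 * s3 * z * dt * (zeta * zeta - 1.0)
                nw = w + sig * (y - w) * dt
                if nx > 0.0 and ny > 0.0 and nz > 0.0 and nw > 0.0:
                    break
                if resample and tries < _RESAMPLE_MAX_TRIES:
                    tries += 1
                    xi, eta, zeta = rng.standard_normal(3)
                    continue
                # clamp: floor each violating component, count each one
                if nx <= 0.0:
                    nx = _CLAMP_FLOOR * x
                    n_events += 1
                if ny <= 0.0:
                    ny = _CLAMP_FLOOR * y
                    n_events += 1
                if nz <= 0.0:
                    nz = _CLAMP_FLOOR * z
                    n_events += 1
                if nw <= 0.0:
                    nw = _CLAMP_FLOOR * w
                    n_events += 1
                break
            x, y, z, w = nx, ny, nz, nw
            if not (math.isfinite(x) and math.isfinite(y)
                    and math.isfinite(z) and math.isfinite(w)):
                raise RuntimeError(
                    f"non-finite state at step {step + i + 1} "
                    f"(t = {(step + i + 1) * dt:g}): {(x, y, z, w)}")
            if (step + i + 1) % rec == 0:
                states[irec] = (x, y, z, w)
                irec += 1
        step += m

    times = np.arange(n_rec + 1) * (dt * rec)
    return Trajectory(times=times, states=states[:irec], params=params,
                      config=config, scheme=config.scheme,
                      n_positivity_events=n_events)


def simulate_deterministic(params: ModelParams,
                           config: SimConfig) -> Trajectory:
    """Integrate the noise-free (sigma_i = 0) limit with an adaptive
    high-order ODE solver on the same recording grid; the seed is ignored.

    Interior initial states are integrated in log coordinates: the model's
    relaxation oscillations drive the viral load through troughs many
    hundreds of orders of magnitude deep, where a linear-space solver loses
    the sign of y to roundoff and the resurgence phase then explodes.  In
    log space positivity is structural and the absolute tolerance controls
    *relative* accuracy of every component.  Boundary initial states (any
    zero component) are integrated in linear coordinates; the boundary
    faces are invariant and dynamically tame.
    """
    validate_params(params)
    init = (default_initial_state(params) if config.initial_state is None
            else np.asarray(config.initial_state, dtype=float))
    n_rec = int(round(config.t_max / config.dt)) // config.record_every
    t_eval = np.arange(n_rec + 1) * (config.dt * config.record_every)

    if np.all(init > 0):
        def rhs(t, u):
            # clip: rejected trial steps may probe log-states far beyond
            # anything the flow visits; keep products of components finite
            s = np.exp(np.clip(u, -745.0, 150.0))
            return drift(s, params) / s

        sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), np.log(init),
                        method="DOP853", t_eval=t_eval, rtol=1e-10,
                        atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        states = np.exp(sol.y.T)
    else:
        def rhs(t, s):
            return drift(s, params)

        scale = np.maximum(np.abs(init), 1.0)
        sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), init,
                        method="DOP853", t_eval=t_eval, rtol=1e-10,
                        atol=1e-12 * scale)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        states = sol.y.T
    return Trajectory(times=sol.t, states=states, params=params,
                      config=config, scheme="ode",
                      n_positivity_events=0)


def simulate_ensemble(params: ModelParams, config: SimConfig,
                      n_reps: int) -> list[Trajectory]:
    """Independent replicates; replicate r uses seed = config.seed + r."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    return [
        simulate(params, dataclasses.replace(config, seed=config.seed + r))
        for r in range(n_reps)
    ]
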