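"""Shared fixtures and the finite-difference generator oracle.

The oracle applies the diffusion generator

    L f = grad(f) . drift + (1/2) sum_i g_i^2 f_ii

to a scalar function by central finite differences, independently of the
closed-form LU/LV implementations it is used to check.  It runs in
50-digit mpmath arithmetic with its own transcription of the model's
drift/diffusion and of the Lyapunov functions: in double precision the
second difference of the confinement power term (magnitude ~1e6) against
a coordinate of order 1 is pure cancellation noise, so a float64 oracle
could never certify 1e-6 agreement.
"""

from __future__ import annotations

import mpmath as mp
import numpy as np
import pytest

import viralctl as v

_DPS = 50


def _mp_state(state):
    return [mp.mpf(float(u)) for u in state]


def mp_drift(s, params):
    x, y, z, w = s
    lam, d, e = mp.mpf(params.lambda_), mp.mpf(params.d), mp.mpf(params.e)
    a, p, c, b = (mp.mpf(params.a), mp.mpf(params.p), mp.mpf(params.c),
                  mp.mpf(params.b))
    sig = mp.mpf(params.sigma_delay)
    return [lam - d * x - e * x * y,
            e * x * y - a * y - p * y * z,
            c * w - b * z,
            sig * (y - w)]


def mp_diffusion(s, params):
    return [mp.mpf(params.sigma1) * s[0], mp.mpf(params.sigma2) * s[1],
            mp.mpf(params.sigma3) * s[2], mp.mpf(0)]


def mp_U(s, consts):
    """Independent transcription of the existence Lyapunov function."""
    x, y, z, w = s
    al, be, ga = (mp.mpf(consts.alpha), mp.mpf(consts.beta),
                  mp.mpf(consts.gamma))
    return ((x - al - al * mp.log(x / al))
            + (y - be - be * mp.log(y / be))
            + (z - 1 - mp.log(z))
            + ga * (w - 1 - mp.log(w)))


def mp_V(s, params, consts):
    """Independent transcription of the ergodicity Lyapunov function."""
    x, y, z, w = s
    a = mp.mpf(params.a)
    wz = a / (4 * mp.mpf(params.c))
    ww = a / (2 * mp.mpf(params.sigma_delay))
    th = mp.mpf(consts.theta)
    M, c0, c1 = mp.mpf(consts.M), mp.mpf(consts.c0), mp.mpf(consts.c1)
    S = x + y + wz * z + ww * w
    return (M * (-mp.log(x) - c0 * mp.log(y)) - c1 * mp.log(y)
            - mp.log(z) - mp.log(w) + S ** (th + 1) / (th + 1))


def fd_generator_apply(fun, state, params, rel_step: str = "1e-10") -> float:
    """High-precision central-difference application of L to ``fun``.

    ``fun`` maps a list of mpmath floats to an mpmath float."""
    with mp.workdps(_DPS):
        s = _mp_state(state)
        f = mp_drift(s, params)
        g = mp_diffusion(s, params)
        step = mp.mpf(rel_step)
        total = mp.mpf(0)
        for i in range(4):
            h = step * s[i]
            sp = list(s)
            sp[i] = s[i] + h
            sm = list(s)
            sm[i] = s[i] - h
            fp, fm, f0 = fun(sp), fun(sm), fun(s)
            fi = (fp - fm) / (2 * h)
            fii = (fp - 2 * f0 + fm) / (h * h)
            total += f[i] * fi + g[i] ** 2 * fii / 2
        return float(total)


@pytest.fixture(scope="session")
def ex1():
    return v.example1()


@pytest.fixture(scope="session")
def ex2():
    return v.example2()


@pytest.fixture(scope="session")
def ex1_long_traj(ex1):
    """One persistence-regime trajectory long enough for stationary and
    ergodic-average checks; shared across tests (read-only)."""
    return v.simulate(ex1, v.SimConfig(dt=0.01, t_max=2000.0, seed=1))


@pytest.fixture(scope="session")
def ex1_fullres_traj(ex1):
    """Short unthinned path for the delay-channel quadrature oracle."""
    return v.simulate(
        ex1, v.SimConfig(dt=0.01, t_max=200.0, seed=3, record_every=1))
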