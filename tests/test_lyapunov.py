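import dataclasses

import numpy as np
import pytest

import viralctl as v
from conftest import fd_generator_apply, mp_U, mp_V


@pytest.fixture(scope="module")
def ec1(ex1):
    return v.existence_constants(ex1)


@pytest.fixture(scope="module")
def cc1(ex1):
    """Ergodicity constants with the larger-margin choices c1=-15, M=7."""
    return v.ergodicity_constants(ex1, c1=-15.0, M=7, seed=0)


def test_existence_constants_values_and_identities(ex1, ec1):
    assert ec1.alpha == pytest.approx(2400.0, rel=1e-14)
    assert ec1.beta == pytest.approx(1.5, rel=1e-14)
    assert ec1.gamma == pytest.approx(1.0, rel=1e-14)
    # K = lambda + alpha d + beta a + b + c + (alpha s1^2 + beta s2^2
    #     + s3^2)/2 = 1000 + 240 + 7.5 + 0.3 + 0.2 + 12.0125
    assert ec1.K == pytest.approx(1260.0125, rel=1e-12)
    assert ec1.alpha * ex1.e + ec1.gamma * ex1.sigma_delay == pytest.approx(
        ex1.a, rel=1e-14)
    assert ec1.beta * ex1.p == pytest.approx(ex1.b, rel=1e-14)
    assert ec1.gamma * ex1.sigma_delay == pytest.approx(ex1.c, rel=1e-14)


def test_existence_constants_require_a_above_c(ex1):
    with pytest.raises(ValueError, match="a > c"):
        v.existence_constants(dataclasses.replace(ex1, c=ex1.a))
    with pytest.raises(ValueError, match="a > c"):
        v.existence_constants(dataclasses.replace(ex1, c=ex1.a + 1.0))


def test_U_minimum_and_positivity(ec1):
    assert v.U_value([ec1.alpha, ec1.beta, 1.0, 1.0], ec1) == 0.0
    # single-bracket arithmetic at x = 2 alpha
    assert v.U_value([2 * ec1.alpha, ec1.beta, 1.0, 1.0], ec1) == (
        pytest.approx(ec1.alpha * (1.0 - np.log(2.0)), rel=1e-12))
    rng = np.random.default_rng(0)
    states = np.exp(rng.uniform(np.log(1e-3), np.log(1e4), size=(500, 4)))
    assert np.all(v.U_value(states, ec1) > 0)
    with pytest.raises(ValueError):
        v.U_value([0.0, 1.0, 1.0, 1.0], ec1)


def test_LU_bounded_by_K_on_samples(ex1, ex2, ec1):
    """The generator of U is uniformly bounded: LU <= K over the sampled
    orthant, for both presets (weights depend only on the shared rates)."""
    rng = np.random.default_rng(1)
    states = np.exp(rng.uniform(np.log(1e-3), np.log(1e4), size=(20000, 4)))
    for params in (ex1, ex2):
        consts = v.existence_constants(params)
        assert np.max(v.LU_value(states, params, consts)) <= consts.K


def test_LU_matches_finite_difference_generator(ex1, ec1):
    rng = np.random.default_rng(2)
    states = np.exp(rng.uniform(np.log(0.5), np.log(2e3), size=(50, 4)))
    for s in states:
        closed = float(v.LU_value(s, ex1, ec1))
        fd = fd_generator_apply(lambda u: mp_U(u, ec1), s, ex1)
        assert abs(closed - fd) / max(1.0, abs(closed)) < 1e-6


def test_ergodicity_constants_defaults(ex1):
    consts = v.ergodicity_constants(ex1, seed=0)
    # c0 = lambda e / (a + s2^2/2)^2 = 2 / 5.005^2
    assert consts.c0 == pytest.approx(2.0 / 5.005**2, rel=1e-12)
    # c1 ceiling -(2 + b + sigma + (s2^2+s3^2)/2)/a = -2.51/5
    assert consts.c1 == pytest.approx(-0.502, rel=1e-12)
    # M floor 2/((d + s1^2/2)(R0*-1)) ~ 6.80 -> smallest integer 7,
    # coinciding with the conventional choice
    assert consts.M == 7
    ceiling = min(5.0 / 5.01, 0.3 / 0.31, 0.1 / 0.11)
    assert consts.theta == pytest.approx(0.5 * ceiling, rel=1e-12)
    assert np.isfinite(consts.B)


def test_ergodicity_constants_admissibility(ex1, ex2):
    with pytest.raises(ValueError, match="R0"):
        v.ergodicity_constants(ex2)
    with pytest.raises(ValueError, match="c1"):
        v.ergodicity_constants(ex1, c1=-0.1)
    with pytest.raises(ValueError, match="M"):
        v.ergodicity_constants(ex1, M=3)
    with pytest.raises(ValueError, match="theta"):
        v.ergodicity_constants(ex1, theta=0.99)
    # the larger-margin choices satisfy both admissibility conditions
    consts = v.ergodicity_constants(ex1, c1=-15.0, M=7, seed=0)
    assert consts.c1 == -15.0 and consts.M == 7


def test_confinement_overshoot_supremum_positive_and_reproducible(ex1):
    """The supremum B of the bounded part of the confinement generator is
    finite but strictly positive: its lambda S^theta term dominates at
    moderate states (e.g. ~ +8e3 near x = 100), so no negative uniform
    bound exists.  The maximization is deterministic given the seed."""
    a = v.ergodicity_constants(ex1, seed=0)
    b = v.ergodicity_constants(ex1, seed=0)
    assert a.B == b.B
    assert a.B > 0
    probe = v.lyapunov.confinement_overshoot(
        np.array([100.0, 1e-6, 1e-6, 1e-6]), ex1, a.theta)
    assert a.B >= probe > 0


def test_V_reference_value(ex1, cc1):
    wz = ex1.a / (4 * ex1.c)
    ww = ex1.a / (2 * ex1.sigma_delay)
    th = cc1.theta
    expected = (1.0 + 1.0 + wz + ww) ** (th + 1) / (th + 1)
    assert v.V_value([1.0, 1.0, 1.0, 1.0], ex1, cc1) == pytest.approx(
        expected, rel=1e-12)


def test_V_coercive_with_default_constants(ex1):
    """With the default constants V blows up along every escape route:
    at infinity (power term), at the x/z/w faces (log wells), and — only
    logarithmically slowly — at the y face, whose ln y coefficient
    -(M c0 + c1) is negative only when c1 > -M c0.  The larger-margin choice
    c1 = -15 violates that and makes V unbounded below in y, so coercivity
    is asserted for the admissible default."""
    cc = v.ergodicity_constants(ex1, seed=0)
    assert cc.M * cc.c0 + cc.c1 > 0  # coercive direction at the y-face
    base = float(v.V_value([1.0, 1.0, 1.0, 1.0], ex1, cc))
    # growth at infinity along random rays
    rng = np.random.default_rng(3)
    for s in np.exp(rng.uniform(np.log(0.5), np.log(5.0), size=(10, 4))):
        vals = [float(v.V_value(s * 10.0**k, ex1, cc)) for k in (1, 3, 5)]
        assert vals[0] < vals[1] < vals[2]
    # blow-up at the x, z, w faces
    for j in (0, 2, 3):
        probe = np.ones(4)
        vals = []
        for exp in (8, 80, 200):
            probe_j = probe.copy()
            probe_j[j] = 10.0 ** -exp
            vals.append(float(v.V_value(probe_j, ex1, cc)))
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > base
    # slow logarithmic blow-up at the y face
    y_vals = [float(v.V_value([1.0, 10.0**-exp, 1.0, 1.0], ex1, cc))
              for exp in (8, 120, 280)]
    assert y_vals[0] < y_vals[1] < y_vals[2]
    # the larger-margin constants lose coercivity in y
    cc_hist = v.ergodicity_constants(ex1, c1=-15.0, M=7, seed=0)
    assert cc_hist.M * cc_hist.c0 + cc_hist.c1 < 0
    y_hist = [float(v.V_value([1.0, 10.0**-exp, 1.0, 1.0], ex1, cc_hist))
              for exp in (8, 120, 280)]
    assert y_hist[0] > y_hist[1] > y_hist[2]


def test_LV_matches_finite_difference_generator(ex1, cc1):
    rng = np.random.default_rng(4)
    states = np.exp(rng.uniform(np.log(0.5), np.log(2e3), size=(50, 4)))
    for s in states:
        closed = float(v.LV_value(s, ex1, cc1))
        fd = fd_generator_apply(lambda u: mp_V(u, ex1, cc1), s, ex1)
        assert abs(closed - fd) / max(1.0, abs(closed)) < 1e-6


def test_LV_diverges_to_minus_infinity_at_small_x(ex1, cc1):
    """The -M lambda / x term dominates as x -> 0+ at fixed (y, z, w)."""
    vals = [float(v.LV_value([x, 5.0, 2.0, 3.0], ex1, cc1))
            for x in (1e-2, 1e-4, 1e-6)]
    assert vals[0] > vals[1] > vals[2]
    assert vals[2] < -1e8


def test_drift_condition_report(ex1, ex2, cc1):
    report = v.verify_lv_negative(ex1, cc1, n_samples=500, seed=0)
    assert set(report["domains"]) == {f"D{i}" for i in range(1, 9)}
    for entry in report["domains"].values():
        assert {"max_LV", "argmax_state", "pass"} <= set(entry)
        assert len(entry["argmax_state"]) == 4
    # the small-x domain is dominated by -M lambda / x and must pass
    assert report["domains"]["D1"]["pass"]
    assert report["domains"]["D1"]["max_LV"] <= -1.0
    with pytest.raises(ValueError, match="R0"):
        v.verify_lv_negative(ex2, cc1, n_samples=10, seed=0)


def test_ellipticity_positive_inside_the_box(ex1):
    assert v.ellipticity_lower_bound(ex1, n_samples=500, seed=0) > 0
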