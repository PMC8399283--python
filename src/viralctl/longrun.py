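"""Long-run behaviour: regime classification, stationary-distribution
summaries, extinction diagnostics and ergodic-average convergence.

The threshold dichotomy: R0* > 1 implies the process admits a unique
ergodic stationary distribution (the disease persists); R0* < 1 implies
the viral load y(t) decays to zero almost surely, with exponential rate
bounded by (a + sigma2^2/2)(R0* - 1).  The reported theoretical bound is
not asserted against empirical slopes — the chain of inequalities behind
it is loose near x = lambda/d — only its sign is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .model import (
    extinction_rate_bound,
    reproduction_number,
    stochastic_reproduction_number,
)
from .params import ModelParams
from .simulate import Trajectory

__all__ = [
    "RegimeReport",
    "StationarySummary",
    "ExtinctionReport",
    "classify_regime",
    "estimate_stationary",
    "lyapunov_exponent_y",
    "ergodic_average",
    "asymptotic_diagnostics",
    "decoupled_susceptible_stationary_law",
]

_COMPONENTS = ("x", "y", "z", "w")
_BOUNDARY_RTOL = 1e-12
_MIN_POINTS = 1000
_EXTINCT_RELATIVE_THRESHOLD = 1e-6
_EXTINCT_SUSTAIN_FRACTION = 0.10


@dataclass(frozen=True)
class RegimeReport:
    """Threshold classification of a parameter set."""

    R0: float
    R0_star: float
    classification: str  # "persistence" | "extinction" | "boundary"
    extinction_rate_bound: float

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "R0_star": self.R0_star,
            "classification": self.classification,
            "extinction_rate_bound": self.extinction_rate_bound,
        }


@dataclass(frozen=True)
class ComponentSummary:
    mean: float
    variance: float
    quantiles: dict[str, float]          # keys "5".."95"
    bin_edges: np.ndarray
    masses: np.ndarray                   # sum to 1

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "variance": self.variance,
            "quantiles": self.quantiles,
            "bin_edges": [float(v) for v in self.bin_edges],
            "masses": [float(v) for v in self.masses],
        }


@dataclass(frozen=True)
class StationarySummary:
    """Post-burn-in marginal summaries of a single long trajectory."""

    components: dict[str, ComponentSummary]
    n_points: int
    effective_sample_size: dict[str, float]
    burn_in_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "burn_in_fraction": self.burn_in_fraction,
            "effective_sample_size": self.effective_sample_size,
            "components": {k: v.to_dict() for k, v in self.components.items()},
        }


@dataclass(frozen=True)
class ExtinctionReport:
    """Trailing-window log-linear fit of the viral load."""

    slope: float                     # d(ln y)/dt over the analysis window
    slope_stderr: float
    extinct: bool
    first_passage_time: float | None
    theoretical_bound: float
    window: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_stderr": self.slope_stderr,
            "extinct": self.extinct,
            "first_passage_time": self.first_passage_time,
            "theoretical_bound": self.theoretical_bound,
            "window": list(self.window),
        }


def classify_regime(params: ModelParams) -> RegimeReport:
    """Pure function of the parameters: thresholds R0* against 1 (declared
    "boundary" within relative tolerance 1e-12)."""
    r0 = reproduction_number(params)
    r0s = stochastic_reproduction_number(params)
    if abs(r0s - 1.0) <= _BOUNDARY_RTOL:
        cls = "boundary"
    elif r0s > 1.0:
        cls = "persistence"
    else:
        cls = "extinction"
    return RegimeReport(R0=r0, R0_star=r0s, classification=cls,
                        extinction_rate_bound=extinction_rate_bound(params))


def _post_burn_in(traj: Trajectory, burn_in_fraction: float) -> slice:
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    n = traj.states.shape[0]
    start = int(np.floor(n * burn_in_fraction))
    kept = n - start
    if kept < _MIN_POINTS:
        raise ValueError(
            f"post-burn-in segment has {kept} recorded points; at least "
            f"{_MIN_POINTS} required — lengthen the run or thin less")
    return slice(start, n)


def _ess(series: np.ndarray) -> float:
    """Effective sample size via the initial positive autocorrelation sum."""
    n = series.size
    v = series - series.mean()
    var = float(v @ v) / n
    if var == 0.0:
        return float(n)
    tau = 1.0
    max_lag = min(n - 1, 1000)
    for k in range(1, max_lag):
        rho = float(v[:-k] @ v[k:]) / ((n - k) * var)
        if rho <= 0.0:
            break
        tau += 2.0 * rho
    return n / tau


def _fd_bin_edges(col: np.ndarray, max_bins: int = 512) -> np.ndarray:
    """Freedman-Diaconis bin edges with a hard cap on the bin count.

    The viral-load marginal is extremely heavy-tailed toward zero (troughs
    span hundreds of decades), so the raw FD rule — range divided by
    2 IQR n^(-1/3) — can demand astronomically many bins; the cap keeps the
    rule deterministic and the histogram representable.
    """
    lo, hi = float(col.min()), float(col.max())
    if lo == hi:
        return np.array([lo - 0.5, hi + 0.5])
    iqr = float(np.percentile(col, 75) - np.percentile(col, 25))
    width = 2.0 * iqr / col.size ** (1.0 / 3.0)
    if width <= 0:
        n_bins = max_bins
    else:
        n_bins = int(min(max_bins, max(1, np.ceil((hi - lo) / width))))
    return np.linspace(lo, hi, n_bins + 1)


def estimate_stationary(traj: Trajectory,
                        burn_in_fraction: float = 0.2) -> StationarySummary:
    """Marginal stationary summaries on the post-burn-in segment.

    Histogram bins follow the deterministic Freedman-Diaconis rule (bin
    count capped at 512); masses are normalized to sum to 1.  For an
    ergodic trajectory these empirical marginals converge to the
    stationary law's marginals.
    """
    sl = _post_burn_in(traj, burn_in_fraction)
    seg = traj.states[sl]
    comps: dict[str, ComponentSummary] = {}
    ess: dict[str, float] = {}
    qlevels = (5, 25, 50, 75, 95)
    for j, name in enumerate(_COMPONENTS):
        col = seg[:, j]
        edges = _fd_bin_edges(col)
        counts, edges = np.histogram(col, bins=edges)
        total = counts.sum()
        masses = (counts / total if total > 0
                  else np.zeros_like(counts, dtype=float))
        q = np.percentile(col, qlevels)
        comps[name] = ComponentSummary(
            mean=float(col.mean()),
            variance=float(col.var(ddof=1)) if col.size > 1 else 0.0,
            quantiles={str(l): float(v) for l, v in zip(qlevels, q)},
            bin_edges=edges,
            masses=masses,
        )
        ess[name] = float(_ess(col))
    return StationarySummary(components=comps, n_points=seg.shape[0],
                             effective_sample_size=ess,
                             burn_in_fraction=burn_in_fraction)


def lyapunov_exponent_y(traj: Trajectory,
                        window_fraction: float = 0.5) -> ExtinctionReport:
    """OLS fit of ln y(t) against t over the trailing window.

    The asymptotic quantity of interest, limsup ln y(t)/t, cannot be
    computed at finite horizon; a trailing-window linear fit is the proxy.
    Clamped (non-positive or floor-level) y values are excluded from the
    fit.  The virus is flagged extinct when y stays below
    1e-6 * y(0) for a contiguous stretch of at least 10% of the horizon.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    t = traj.times
    y = traj.y
    horizon = float(t[-1])
    start = int(np.floor(t.size * (1.0 - window_fraction)))
    tw, yw = t[start:], y[start:]
    ok = yw > 0
    if ok.sum() < 3:
        raise ValueError("analysis window has fewer than 3 usable points "
                         "after excluding non-positive viral loads")
    res = stats.linregress(tw[ok], np.log(yw[ok]))

    thr = _EXTINCT_RELATIVE_THRESHOLD * y[0]
    below = y < thr
    first_passage = float(t[np.argmax(below)]) if below.any() else None
    # longest contiguous below-threshold stretch, in time units
    longest = 0
    run = 0
    for flag in below:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    dt_rec = float(t[1] - t[0]) if t.size > 1 else 0.0
    extinct = longest * dt_rec >= _EXTINCT_SUSTAIN_FRACTION * horizon

    return ExtinctionReport(
        slope=float(res.slope),
        slope_stderr=float(res.stderr),
        extinct=bool(extinct),
        first_passage_time=first_passage,
        theoretical_bound=extinction_rate_bound(traj.params),
        window=(float(tw[0]), float(tw[-1])),
    )


def ergodic_average(traj: Trajectory,
                    observable: Callable[[np.ndarray], np.ndarray],
                    burn_in_fraction: float = 0.2) -> tuple[float, float]:
    """Post-burn-in time average of ``observable(states)`` plus a two-window
    agreement diagnostic.

    ``observable`` maps an (n, 4) state array to n values.  Returns
    (average, relative discrepancy between the two halves of the post-burn-in
    segment); for an ergodic process the discrepancy shrinks as the horizon
    grows.
    """
    sl = _post_burn_in(traj, burn_in_fraction)
    vals = np.asarray(observable(traj.states[sl]), dtype=float)
    half = vals.size // 2
    m1 = float(vals[:half].mean())
    m2 = float(vals[half:].mean())
    denom = 0.5 * (abs(m1) + abs(m2))
    disc = 0.0 if denom == 0.0 else abs(m1 - m2) / denom
    return float(vals.mean()), disc


def asymptotic_diagnostics(traj: Trajectory) -> dict:
    """Finite-horizon sublinearity statistics.

    Returns ln(component(T))/T for each component and the total mass ratio
    (x+y+z+w)(T)/T at the horizon T.  Along almost every path both vanish
    as T grows: no component grows exponentially, and the total population
    grows sublinearly.
    """
    T = float(traj.times[-1])
    if T <= 0:
        raise ValueError("trajectory horizon must be positive")
    final = traj.final_state
    out = {
        f"log_{name}_over_T": float(np.log(final[j]) / T)
        for j, name in enumerate(_COMPONENTS)
    }
    out["total_over_T"] = float(final.sum() / T)
    return out


def decoupled_susceptible_stationary_law(params: ModelParams):
    """Closed-form stationary law of x in the decoupled (e = 0) limit.

    With e = 0 the susceptible pool follows the linear multiplicative-noise
    SDE dx = (lambda - d x) dt + sigma1 x dB, whose stationary density is
    inverse-gamma with shape 1 + 2d/sigma1^2 and scale 2 lambda/sigma1^2
    (stationary mean lambda/d).  Returns a frozen scipy distribution, used
    as an analytic oracle for the simulator's marginals.
    """
    if params.sigma1 <= 0:
        raise ValueError("requires sigma1 > 0 (the noise sets the "
                         "stationary spread)")
    shape = 1.0 + 2.0 * params.d / params.sigma1**2
    scale = 2.0 * params.lambda_ / params.sigma1**2
    return stats.invgamma(shape, scale=scale)
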