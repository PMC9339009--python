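"""Retention-curve fitting: exponential, double-exponential, power law.

Forgetting curves are fitted on the logarithm of the retrieval
probability, matching how retention data are usually displayed and
compared (straight lines on semi-log or log-log axes).  Unweighted least
squares on the transformed data is the default; a binomial weighting
option is available for the semi-log fits.  R-squared is always reported
in the transformed space of the respective model, so an exponential and a
power-law fit of the same curve can be compared on log-probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .consolidation import ForgettingCurve, SimConfig, run_simulation

__all__ = [
    "FitResult",
    "fit_exponential_tail",
    "fit_double_exponential",
    "fit_power_law",
    "capacity_scaling_experiment",
]


@dataclass
class FitResult:
    """Outcome of a retention-curve fit.

    ``params`` holds amplitudes and time constants (time constants in the
    same units as the curve's age axis, i.e. units of tau); for the power
    law it holds the positive decay exponent ``slope``.
    """

    model: str
    params: dict
    r_squared: float
    fit_range: tuple[float, float]
    n_points: int
    flags: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {"model": self.model, "params": self.params,
                "r_squared": self.r_squared, "fit_range": self.fit_range,
                "n_points": self.n_points, "flags": self.flags}


def _select(curve: ForgettingCurve, age_range, min_points: int,
            min_successes: float = 0.0):
    """Populated bins inside the age range.

    ``min_successes`` drops bins whose expected success count is too small
    for log p to be meaningful: deep-tail bins with zero successes cannot
    enter a log fit at all, and keeping only their nonzero neighbours
    would bias the tail upward (survivor selection).
    """
    lo, hi = age_range
    p = curve.retrieval_prob
    m = (np.isfinite(p) & (p > 0) & (curve.age_bins >= lo)
         & (curve.age_bins <= hi)
         & (p * curve.n_samples >= min_successes))
    if m.sum() < min_points:
        raise ValueError(
            f"need at least {min_points} populated bins with nonzero "
            f"probability in age range {age_range}, found {int(m.sum())}")
    return curve.age_bins[m], p[m], curve.n_samples[m]


def _r_squared(y, y_hat, w=None) -> float:
    w = np.ones_like(y) if w is None else w
    ss_res = float(np.sum(w * (y - y_hat) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _binomial_weights(p, n):
    # var(log p_hat) ~ (1 - p) / (n p); weight is the inverse variance
    return n * p / np.maximum(1.0 - p, 1e-12)


def fit_exponential_tail(curve: ForgettingCurve,
                         age_range: Optional[tuple[float, float]] = None,
                         weighted: bool = False) -> FitResult:
    """Exponential tail p(t) = c exp(-t / tau_c), fitted as log p vs age.

    The default range starts at 5 tau, past the fast unconsolidated
    transient, and runs to the oldest populated bin.
    """
    if age_range is None:
        age_range = (5.0, float(np.inf))
    t, p, n = _select(curve, age_range, min_points=10, min_successes=4)
    y = np.log(p)
    w = _binomial_weights(p, n) if weighted else None
    slope, intercept = np.polyfit(t, y, 1, w=None if w is None
                                  else np.sqrt(w))
    flags = []
    if slope >= -1e-10:
        flags.append("nondecaying: infinite time constant")
        tau_c = float("inf")
    else:
        tau_c = -1.0 / slope
    r2 = _r_squared(y, slope * t + intercept, w)
    return FitResult(model="exponential",
                     params={"tau_c": float(tau_c),
                             "amplitude": float(np.exp(intercept))},
                     r_squared=r2, fit_range=(float(t[0]), float(t[-1])),
                     n_points=t.size, flags=flags)


def fit_double_exponential(curve: ForgettingCurve,
                           age_range: Optional[tuple[float, float]] = None,
                           n_starts: int = 8) -> FitResult:
    """p(t) = c1 exp(-t/tau1) + c2 exp(-t/tau2), tau1 < tau2.

    Nonlinear least squares on log p with multi-start initialization over
    a grid of (tau1, tau2) decades; positivity is enforced by optimizing
    log-parameters.  Captures the fast drop of unconsolidated memories
    (time scale ~ tau) plus the slow consolidated tail.
    """
    if age_range is None:
        age_range = (0.0, float(np.inf))
    t, p, _ = _select(curve, age_range, min_points=15, min_successes=4)
    y = np.log(p)

    def resid(q):
        c1, t1, c2, t2 = np.exp(q)
        model = c1 * np.exp(-t / t1) + c2 * np.exp(-t / t2)
        return np.log(np.maximum(model, 1e-300)) - y

    t_span = max(t[-1], 2.0)
    starts = []
    rng = np.random.default_rng(0)
    base_t1 = [0.5, 1.0, 2.0]
    base_t2 = [0.3 * t_span, 0.6 * t_span, 10.0, 30.0]
    for t1 in base_t1:
        for t2 in base_t2:
            if t2 > t1:
                starts.append((0.5, t1, 0.5, t2))
    while len(starts) < n_starts:
        starts.append((rng.uniform(0.2, 1.0), rng.uniform(0.3, 3.0),
                       rng.uniform(0.2, 1.0), rng.uniform(5.0, t_span)))
    best = None
    for s in starts[:max(n_starts, 6)]:
        try:
            sol = least_squares(resid, np.log(np.asarray(s)),
                                method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("double-exponential fit failed to converge "
                           "from all starting points")
    c1, t1, c2, t2 = np.exp(best.x)
    if t1 > t2:
        c1, t1, c2, t2 = c2, t2, c1, t1
    flags = []
    if t2 / t1 < 1.5 or c1 < 1e-3 or c2 < 1e-3:
        flags.append("components merged or degenerate amplitude")
    y_hat = np.log(c1 * np.exp(-t / t1) + c2 * np.exp(-t / t2))
    return FitResult(model="double_exponential",
                     params={"c1": float(c1), "tau1": float(t1),
                             "c2": float(c2), "tau2": float(t2)},
                     r_squared=_r_squared(y, y_hat),
                     fit_range=(float(t[0]), float(t[-1])),
                     n_points=t.size, flags=flags)


def fit_power_law(curve: ForgettingCurve,
                  age_range: Optional[tuple[float, float]] = None
                  ) -> FitResult:
    """Power law p(t) = c t^{-slope}, fitted as log p vs log age."""
    if age_range is None:
        age_range = (0.0, float(np.inf))
    t, p, _ = _select(curve, age_range, min_points=5, min_successes=4)
    pos = t > 0
    t, p = t[pos], p[pos]
    if t.size < 5:
        raise ValueError("need at least 5 bins at positive age")
    x, y = np.log(t), np.log(p)
    slope, intercept = np.polyfit(x, y, 1)
    return FitResult(model="power_law",
                     params={"slope": float(-slope),
                             "amplitude": float(np.exp(intercept))},
                     r_squared=_r_squared(y, slope * x + intercept),
                     fit_range=(float(t[0]), float(t[-1])),
                     n_points=t.size)


@dataclass
class CapacityScalingResult:
    N_values: np.ndarray
    capacities: np.ndarray
    exponent: float
    analytic_exponent: float
    failures: dict


def capacity_scaling_experiment(N_grid, cfg_template: SimConfig, basin,
                                ) -> CapacityScalingResult:
    """Equilibrium capacity vs network size and its log-log exponent.

    Runs the consolidation simulator for each N (all other parameters
    fixed; the critical ratio a(f) depends only on f) and fits
    log10(capacity) against log10(N).  The analytic comparison value is
    the exponent lam tau / (2 + lam tau).
    """
    from dataclasses import replace as dc_replace
    N_grid = list(N_grid)
    if len(N_grid) < 4 or max(N_grid) / min(N_grid) < 8 - 1e-9:
        raise ValueError("N grid must have >= 4 values spanning at least "
                         "a factor of 8")
    caps, oks, failures = [], [], {}
    for N in N_grid:
        cfg = dc_replace(cfg_template, N=int(N))
        try:
            res = run_simulation(cfg, basin)
            caps.append(res.summary.capacity)
            oks.append(N)
        except Exception as exc:  # isolate per-N failures
            failures[N] = repr(exc)
    if len(oks) < 3:
        raise RuntimeError(f"too many per-N failures: {failures}")
    caps_arr = np.asarray(caps, dtype=float)
    expo = float(np.polyfit(np.log10(oks), np.log10(caps_arr), 1)[0])
    lt = cfg_template.lam * cfg_template.tau
    return CapacityScalingResult(N_values=np.asarray(oks, dtype=float),
                                 capacities=caps_arr, exponent=expo,
                                 analytic_exponent=lt / (2.0 + lt),
                                 failures=failures)
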