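"""Mean-field stability analysis of sparse binary attractor networks.

A memory pattern stored with efficacy ``A`` in a network whose cross-talk
(interference) noise has standard deviation ``Delta`` is a stable attractor
only when the ratio ``A/Delta`` exceeds a critical value ``a(f)`` that
depends solely on the coding sparseness ``f``.  This module computes, from
the one-dimensional overlap map of the mean-field theory:

* the fixed points of the overlap dynamics (zero, unstable, stable),
* the critical ratio ``a(f)`` at which the nonzero fixed points merge
  (saddle-node bifurcation),
* the normalized basin-of-attraction function ``F(A/A_c)`` that drives the
  stochastic rehearsal rates of the consolidation model.

Two single-neuron conventions are supported.  In ``fixed_activity`` mode the
firing threshold is adjusted at every update so that exactly a fraction
``f`` of the neurons is active (the overlap map then depends only on
``A/Delta`` and ``f``).  In ``fixed_threshold`` mode the threshold ``theta``
is held fixed and the population activity is solved self-consistently; this
is the regime used to study structural perturbations, where over-activation
at high noise can destroy all attractors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "StabilityParams",
    "OverlapFixedPoints",
    "BasinTable",
    "gauss_tail",
    "gauss_tail_inv",
    "overlap_map",
    "overlap_fixed_points",
    "basin_size_raw",
    "critical_point",
    "critical_ratio",
    "critical_ratio_approx",
    "build_basin_table",
]


def gauss_tail(x):
    """Upper tail of the standard Gaussian, H(x) = P(Z > x).

    Strictly decreasing, H(0) = 1/2, H(x) -> 0 as x -> +inf.
    """
    return norm.sf(x)


def gauss_tail_inv(p):
    """Inverse of :func:`gauss_tail`: the x with P(Z > x) = p."""
    return norm.isf(p)


@dataclass(frozen=True)
class StabilityParams:
    """Parameters of the mean-field stability problem.

    Parameters
    ----------
    f
        Coding sparseness, the fraction of neurons active in a memory
        pattern.  Must lie in (0, 0.5).
    mode
        ``"fixed_activity"`` (threshold adjusted so activity equals ``f``)
        or ``"fixed_threshold"`` (fixed ``theta``, activity self-consistent).
    theta
        Firing threshold; only used in ``fixed_threshold`` mode.
    overlap_retrieval_cut
        Overlap above which a retrieval attempt is declared successful.
    """

    f: float = 0.01
    mode: str = "fixed_activity"
    theta: float = 0.36
    overlap_retrieval_cut: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 0.5:
            raise ValueError(f"sparseness f must be in (0, 0.5), got {self.f}")
        if self.mode not in ("fixed_activity", "fixed_threshold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.overlap_retrieval_cut < 1.0:
            raise ValueError("overlap_retrieval_cut must be in (0, 1)")


@dataclass(frozen=True)
class OverlapFixedPoints:
    """Fixed points of the overlap map at a given efficacy-to-noise ratio.

    ``m_zero`` is the quiescent fixed point at zero overlap (always present
    in fixed-activity mode); ``zero_stable`` records whether it is stable —
    at very large ``A/Delta`` the zero state itself destabilizes and the
    basin of the retrieval state extends all the way down to zero overlap.
    ``m_unstable``/``m_stable`` are the nonzero pair when it exists.
    """

    m_zero: float
    m_unstable: Optional[float]
    m_stable: Optional[float]
    zero_stable: bool = True

    def __post_init__(self) -> None:
        if self.m_unstable is not None and self.m_stable is not None:
            if not (0.0 < self.m_unstable <= self.m_stable <= 1.0 + 1e-12):
                raise ValueError("expected 0 < m_unstable <= m_stable <= 1")


# Dense scan grid for bracketing roots of the overlap map.  The unstable
# fixed point scales like 1/ratio, so the grid must resolve overlaps far
# below the uniform spacing: prepend a logarithmic ramp near zero.
_M_GRID = np.unique(
    np.concatenate(
        [np.logspace(-7.0, np.log10(0.05), 200), np.linspace(0.0, 1.0, 2000)]
    )
)


def overlap_map(m, ratio, params: StabilityParams, delta: Optional[float] = None):
    """One step of the mean-field overlap dynamics, m' = G(m, A/Delta).

    In fixed-activity mode

        G(m, r) = H(H^{-1}(f (1-m)) - r m) - f (1-m),

    where the first term is the conditional activation probability f+ of
    neurons belonging to the pattern and f- = f (1-m) follows from the
    global activity constraint.  In fixed-threshold mode f+ and f- are
    evaluated at the fixed threshold ``params.theta`` with the population
    activity (and hence the effective noise) solved self-consistently;
    ``delta`` (the interference noise in activity-f units) is then required
    because the map no longer depends on ``A/Delta`` alone.
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any((m_arr < 0.0) | (m_arr > 1.0)):
        raise ValueError("overlap m must lie in [0, 1]")
    if np.any(np.asarray(ratio) < 0.0):
        raise ValueError("efficacy-to-noise ratio must be nonnegative")
    if params.mode == "fixed_activity":
        q = params.f * (1.0 - m_arr)
        out = norm.sf(norm.isf(q) - np.asarray(ratio) * m_arr) - q
        return out if out.ndim else float(out)
    if delta is None:
        raise ValueError("fixed_threshold mode requires the noise level delta")
    out = _fixed_threshold_map(m_arr, np.asarray(ratio) * delta, delta, params)
    return out if out.ndim else float(out)


def _fixed_threshold_map(m, A, delta, params: StabilityParams,
                         max_iter: int = 400, tol: float = 1e-13):
    """f+ - f- at fixed threshold with self-consistent population activity.

    The interference noise scales with the square root of the presynaptic
    activity: if the network settles at activity q instead of f, the
    effective noise is delta*sqrt(q/f).  The activity follows
    q = f f+ + (1-f) f- and is iterated (damped) to a fixed point.
    """
    f, theta = params.f, params.theta
    m = np.asarray(m, dtype=float)
    A = np.broadcast_to(np.asarray(A, dtype=float), m.shape).copy()
    q = np.full_like(m, f)
    fp = np.zeros_like(m)
    fm = np.zeros_like(m)
    for _ in range(max_iter):
        d_eff = delta * np.sqrt(np.maximum(q, 1e-300) / f)
        with np.errstate(divide="ignore", over="ignore"):
            fp = norm.sf((theta - A * (1.0 - f) * m) / d_eff)
            fm = norm.sf((theta + A * f * m) / d_eff)
        q_new = f * fp + (1.0 - f) * fm
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = 0.5 * q + 0.5 * q_new
    return fp - fm


def _map_residual(m, ratio, params, delta=None):
    return overlap_map(m, ratio, params, delta=delta) - np.asarray(m, dtype=float)


def overlap_fixed_points(ratio, params: StabilityParams,
                         delta: Optional[float] = None) -> OverlapFixedPoints:
    """All fixed points of the overlap map at a given ``A/Delta``.

    Roots are bracketed on a dense overlap grid and refined by bisection;
    a root is classified stable when the residual G(m) - m crosses zero
    downwards (slope of the map below one).
    """
    g = _map_residual(_M_GRID, ratio, params, delta)
    sign = np.sign(g)
    crossings = np.where(sign[:-1] * sign[1:] < 0)[0]
    roots: list[tuple[float, bool]] = []
    for i in crossings:
        a, b = _M_GRID[i], _M_GRID[i + 1]
        ga = g[i]
        for _ in range(60):
            c = 0.5 * (a + b)
            gc = float(_map_residual(c, ratio, params, delta))
            if gc * ga <= 0:
                b = c
            else:
                a, ga = c, gc
        root = 0.5 * (a + b)
        stable = bool(g[i] > 0 > g[i + 1])
        roots.append((root, stable))
    eps = 1e-8
    zero_stable = bool(_map_residual(eps, ratio, params, delta) < 0.0)
    stable_roots = [r for r, s in roots if s]
    unstable_roots = [r for r, s in roots if not s]
    m_stable = max(stable_roots) if stable_roots else None
    m_unstable = None
    if m_stable is not None:
        below = [u for u in unstable_roots if u < m_stable]
        if below:
            m_unstable = max(below)
    return OverlapFixedPoints(
        m_zero=0.0, m_unstable=m_unstable, m_stable=m_stable,
        zero_stable=zero_stable,
    )


def basin_size_raw(ratio, params: StabilityParams,
                   delta: Optional[float] = None) -> float:
    """Basin-of-attraction width M_s - M_us (zero when no attractor exists).

    When the zero state itself is unstable there is no interior unstable
    fixed point and the basin extends down to zero overlap, so the width
    is simply M_s.
    """
    fps = overlap_fixed_points(ratio, params, delta)
    if fps.m_stable is None:
        return 0.0
    if fps.m_unstable is not None:
        return fps.m_stable - fps.m_unstable
    return fps.m_stable if not fps.zero_stable else 0.0


def critical_point(params: StabilityParams,
                   bracket: tuple[float, float] = (1.0, 20.0),
                   rtol: float = 1e-7) -> tuple[float, float]:
    """Saddle-node of the overlap map: (critical ratio a(f), merge overlap).

    Bisects on ``A/Delta`` for the smallest ratio at which a stable nonzero
    fixed point exists, and returns the overlap at which the stable and
    unstable branches merge.
    """
    if params.mode != "fixed_activity":
        raise ValueError("critical_point is defined for fixed_activity mode")
    lo, hi = bracket
    if basin_size_raw(hi, params) <= 0.0:
        raise RuntimeError("no stable retrieval state at the upper bracket; "
                           "increase the bracket")
    if basin_size_raw(lo, params) > 0.0:
        raise RuntimeError("stable retrieval state already at the lower "
                           "bracket; decrease the bracket")
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if basin_size_raw(mid, params) > 0.0:
            hi = mid
        else:
            lo = mid
    fps = overlap_fixed_points(hi, params)
    if fps.m_unstable is not None:
        merge = 0.5 * (fps.m_stable + fps.m_unstable)
    else:
        merge = fps.m_stable
    return hi, float(merge)


def critical_ratio(params: StabilityParams) -> float:
    """Critical efficacy-to-noise ratio a(f) (A_c = a(f) * Delta)."""
    return critical_point(params)[0]


def critical_ratio_approx(f: float) -> float:
    """Closed-form approximation a(f) ~ 1.44 sqrt(2 log(1.9/f)).

    Valid in the sparse regime; evaluates to ~4.67 at f = 0.01 and
    vanishes when the logarithm's argument reaches one.
    """
    if not 0.0 < f <= 1.9:
        raise ValueError("approximation requires 0 < f <= 1.9")
    return 1.44 * float(np.sqrt(2.0 * np.log(1.9 / f)))


@dataclass
class BasinTable:
    """Tabulated normalized basin-size function F(x), x = A/A_c.

    ``F`` is zero below x = 1 (memories weaker than the critical efficacy
    are not attractors), rises steeply just above threshold and saturates;
    it is normalized by its large-ratio asymptote (evaluated at x = 50) so
    that ``lambda * F`` is a proper rate with ceiling ``lambda``.  The raw
    (unnormalized) basin widths are kept alongside.
    """

    x_grid: np.ndarray
    F_values: np.ndarray
    a_f: float
    f: float
    mode: str = "fixed_activity"
    theta: Optional[float] = None
    raw_widths: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.F_values = np.asarray(self.F_values, dtype=float)
        if np.any(np.diff(self.F_values) < -1e-12):
            raise ValueError("F must be nondecreasing in x")

    def __call__(self, x):
        """Piecewise-linear interpolation of F; 0 below support, 1 above."""
        return np.interp(x, self.x_grid, self.F_values, left=0.0, right=1.0)

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV (x, F) plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"x": self.x_grid, "F": self.F_values}).to_csv(
            path, index=False
        )
        meta = {"f": self.f, "a_f": self.a_f, "mode": self.mode,
                "theta": self.theta}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BasinTable":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(x_grid=df["x"].to_numpy(), F_values=df["F"].to_numpy(),
                   a_f=meta["a_f"], f=meta["f"], mode=meta["mode"],
                   theta=meta.get("theta"))


def build_basin_table(params: StabilityParams, n_grid: int = 400,
                      x_max: float = 50.0) -> BasinTable:
    """Compute the normalized basin function F on a log-spaced A/A_c grid.

    The grid spans [1, x_max] with ``n_grid`` logarithmic points (plus an
    exact zero segment below 1), which resolves the steep rise of F just
    above the critical efficacy.  The normalization point is the basin
    width at ``x_max`` where F has long saturated.
    """
    if params.mode != "fixed_activity":
        raise ValueError("basin tables are built in fixed_activity mode; "
                         "fixed-threshold stability uses the A_c(Delta) map")
    if x_max < 10.0:
        raise ValueError("grid must cover at least [0, 10] in A/A_c")
    a_f, _ = critical_point(params)
    xs = np.concatenate([[0.0, 1.0 - 1e-9],
                         np.logspace(0.0, np.log10(x_max), n_grid)])
    widths = np.array([basin_size_raw(x * a_f, params) if x >= 1.0 else 0.0
                       for x in xs])
    # enforce monotonicity against root-finder jitter near the saddle-node
    widths = np.maximum.accumulate(widths)
    norm_width = widths[-1]
    if norm_width <= 0:
        raise RuntimeError("basin width vanished at the normalization point")
    return BasinTable(x_grid=xs, F_values=widths / norm_width, a_f=a_f,
                      f=params.f, mode=params.mode, raw_widths=widths)
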