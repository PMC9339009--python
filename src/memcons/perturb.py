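"""Structural perturbations of the memory circuit and amnesia curves.

Two kinds of damage are modeled on top of the consolidation dynamics,
both evaluated in fixed-threshold mode (a perturbed circuit cannot be
assumed to keep its activity perfectly regulated):

* **Additive synaptic noise** — white noise with diffusion coefficient D
  injected into every synapse from an onset time.  Its integrated effect
  is an extra field-variance term that saturates over ~tau, transiently
  raising the critical efficacy and suppressing rehearsals; memories
  encoded near the onset are hit hardest (temporally graded retro- and
  anterograde amnesia).
* **Random synaptic silencing (dilution)** — a fraction p of synapses is
  zeroed.  Signals scale by (1-p) and the interference noise by
  sqrt(1-p), so the signal-to-noise ratio degrades by sqrt(1-p) and the
  deficit spreads over all memory ages.

With a fixed threshold the critical efficacy is no longer proportional
to the noise: it has a floor at small Delta (the field must clear theta)
and diverges above a critical noise level where the network
over-activates.  The map A_c(Delta; theta) is tabulated once from the
self-consistent mean-field retrieval problem and interpolated during
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .consolidation import SimConfig, SimResult, run_simulation
from .meanfield import BasinTable, StabilityParams, _fixed_threshold_map

__all__ = [
    "PerturbationSpec",
    "ThresholdModel",
    "effective_noise_additive",
    "apply_dilution_meanfield",
    "dilution_full_network",
    "critical_efficacy_fixed_threshold",
    "perturbed_run",
    "optimize_threshold",
    "PerturbedRunResult",
]

DEFAULT_PROBE_DELAYS = (5.0, 10.0, 20.0, 40.0)  # units of tau after onset


@dataclass(frozen=True)
class PerturbationSpec:
    """Specification of a structural perturbation.

    ``kind`` is ``"additive_noise"``, ``"dilution"`` or ``"none"``; ``D``
    is the diffusion coefficient of the synaptic noise, ``p`` the silenced
    synapse fraction, and the onset/offset times delimit a (possibly
    transient) damage window.  ``theta`` is the firing threshold in effect.
    """

    kind: str = "none"
    D: float = 0.0
    p: float = 0.0
    t_onset: float = 0.0
    t_offset: Optional[float] = None
    theta: float = 0.36

    def __post_init__(self) -> None:
        if self.kind not in ("additive_noise", "dilution", "none"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.D < 0:
            raise ValueError("diffusion coefficient D must be nonnegative")
        if not 0.0 <= self.p < 1.0:
            raise ValueError("silenced fraction p must be in [0, 1)")
        if self.t_offset is not None and self.t_offset <= self.t_onset:
            raise ValueError("t_offset must exceed t_onset")

    def window(self, t: float) -> bool:
        """Whether the damage is active at time t."""
        if t < self.t_onset:
            return False
        return self.t_offset is None or t < self.t_offset


def effective_noise_additive(delta_sq_base: float, D: float, tau: float,
                             N: int, t: float, t_onset: float,
                             f: float = 1.0) -> float:
    """Total field variance with the accumulated synaptic-noise term.

    The Ornstein-Uhlenbeck accumulation of white synaptic noise saturates
    at variance tau D^2 / (2N) with time constant tau/2:

        Delta^2(t) = Delta_mem^2 + f * (tau D^2 / 2N) (1 - e^{-2(t-t0)/tau})

    The factor ``f`` accounts for only the active presynaptic units
    transmitting the noise, keeping the term commensurate with the
    activity-weighted interference variance.
    """
    if t < t_onset:
        return delta_sq_base
    add = f * tau * D ** 2 / (2.0 * N) * \
        (1.0 - np.exp(-2.0 * (t - t_onset) / tau))
    return delta_sq_base + add


def apply_dilution_meanfield(efficacies, delta: float,
                             p: float) -> tuple[np.ndarray, float]:
    """Mean-field effect of silencing a fraction p of synapses.

    Signals (effective efficacies) scale by (1-p); the noise variance by
    (1-p), i.e. Delta by sqrt(1-p).
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("p must be in [0, 1)")
    return (1.0 - p) * np.asarray(efficacies, dtype=float), \
        float(np.sqrt(1.0 - p) * delta)


def dilution_full_network(conn, p: float, seed: int = 0,
                          symmetric: bool = True):
    """Apply a Bernoulli(1-p) silencing mask to a connectivity matrix.

    The mask is symmetric by default (a dead synapse removes the coupling
    in both directions), keeping the perturbed matrix symmetric like the
    intact one.
    """
    from .network import Connectivity
    rng = np.random.default_rng(seed)
    N = conn.J.shape[0]
    keep = rng.random((N, N)) >= p
    if symmetric:
        upper = np.triu(keep, 1)
        keep = upper | upper.T
        np.fill_diagonal(keep, True)
    return Connectivity(J=conn.J * keep, f=conn.f,
                        dilution_mask=keep.astype(np.int8))


@dataclass
class ThresholdModel:
    """Tabulated critical efficacy A_c(Delta) at a fixed threshold theta.

    ``a_c_of_delta`` is non-linear: a floor ~theta/(1-f) at small noise,
    a rise with Delta, and a divergence at ``delta_critical`` beyond
    which the over-activated network supports no stable retrieval (the
    interpolator returns infinity there).
    """

    theta: float
    f: float
    delta_grid: np.ndarray
    a_c_values: np.ndarray          # np.inf above delta_critical
    delta_critical: float

    def __call__(self, delta: float) -> float:
        if delta >= self.delta_critical:
            return float("inf")
        return float(np.interp(delta, self.delta_grid, self.a_c_values))


_M_GRID_FT = np.linspace(0.0, 1.0, 256)


def _stable_retrieval(A: float, delta: float,
                      params: StabilityParams) -> bool:
    """Whether a stable overlap fixed point >= the retrieval cut exists.

    Evaluates the fixed-threshold map on a vectorized overlap grid and
    looks for a downward zero crossing of G(m) - m at high overlap; the
    root location only needs grid precision here.
    """
    g = _fixed_threshold_map(_M_GRID_FT, A, delta, params,
                             max_iter=150, tol=1e-10) - _M_GRID_FT
    s = np.sign(g)
    # a strong attractor can sit at the boundary m ~ 1 where f+ saturates
    # to 1 and f- underflows, making g exactly 0: count such transitions
    down = np.where((s[:-1] > 0) & (s[1:] <= 0))[0]
    if down.size == 0:
        return False
    denom = g[down] - g[down + 1]
    roots = _M_GRID_FT[down] + g[down] / denom \
        * (_M_GRID_FT[1] - _M_GRID_FT[0])
    return bool(np.any(roots >= params.overlap_retrieval_cut))


def critical_efficacy_fixed_threshold(theta: float, f: float,
                                      delta_grid=None,
                                      a_max: float = 30.0,
                                      overlap_cut: float = 0.85,
                                      ) -> ThresholdModel:
    """Tabulate the minimal stable efficacy A_c over a noise grid.

    For each Delta the fixed-threshold mean-field retrieval problem is
    solved (self-consistent activity) and A_c(Delta) is the smallest
    efficacy with a stable retrieval state at overlap >= ``overlap_cut``.
    Where no efficacy up to ``a_max`` stabilizes retrieval, A_c is
    recorded as infinity; ``delta_critical`` is the first such Delta.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    params = StabilityParams(f=f, mode="fixed_threshold", theta=theta,
                             overlap_retrieval_cut=overlap_cut)
    if delta_grid is None:
        delta_grid = np.linspace(1e-3, 0.6 * theta, 200)
    delta_grid = np.asarray(delta_grid, dtype=float)
    a_c = np.empty_like(delta_grid)
    for i, d in enumerate(delta_grid):
        if not _stable_retrieval(a_max, d, params):
            a_c[i] = np.inf
            continue
        lo = theta * 0.5  # below the floor theta/(1-f) nothing is stable
        hi = a_max
        if _stable_retrieval(lo, d, params):
            hi = lo
        else:
            while hi - lo > 1e-4 * max(hi, 1.0):
                mid = 0.5 * (lo + hi)
                if _stable_retrieval(mid, d, params):
                    hi = mid
                else:
                    lo = mid
        a_c[i] = hi
    finite = np.isfinite(a_c)
    if not finite.any():
        raise RuntimeError("no stable retrieval anywhere on the noise grid; "
                           "check theta")
    if finite.all():
        delta_critical = float(delta_grid[-1]) * 1.0000001
    else:
        delta_critical = float(delta_grid[~finite][0])
    return ThresholdModel(theta=theta, f=f, delta_grid=delta_grid[finite],
                          a_c_values=a_c[finite],
                          delta_critical=delta_critical)


@dataclass
class PerturbedRunResult:
    control: SimResult
    perturbed: SimResult
    capacity_ratio: float
    probe_delays: tuple            # units of tau after onset
    spec: PerturbationSpec


def _make_criticality(tmodel: ThresholdModel, spec: PerturbationSpec,
                      cfg: SimConfig):
    """Effective A_c(Delta_mem, t) combining threshold map and damage.

    Dilution scales the signal by (1-p) and the noise by sqrt(1-p); the
    effective critical efficacy in un-scaled units is therefore
    A_c(sqrt(1-p) Delta) / (1-p).  Additive noise enters Delta directly.
    """
    tau, N, f = cfg.tau, cfg.N, cfg.f

    def crit(delta_mem: float, t: float) -> float:
        d_sq = delta_mem ** 2
        scale = 1.0
        if spec.kind == "dilution" and spec.window(t):
            d_sq *= (1.0 - spec.p)
            scale = 1.0 - spec.p
        if spec.kind == "additive_noise" and t >= spec.t_onset:
            t_eff = t if spec.window(t) else spec.t_offset
            d_sq = effective_noise_additive(d_sq, spec.D, tau, N,
                                            t_eff, spec.t_onset, f=f)
            if spec.t_offset is not None and t >= spec.t_offset:
                # accumulated noise variance decays away after the window
                d_sq = delta_mem ** 2 + \
                    (d_sq - delta_mem ** 2) * \
                    np.exp(-2.0 * (t - spec.t_offset) / tau)
        return tmodel(float(np.sqrt(d_sq))) / scale

    return crit


def perturbed_run(cfg: SimConfig, spec: PerturbationSpec,
                  tmodel: ThresholdModel, basin: BasinTable,
                  probe_delays=DEFAULT_PROBE_DELAYS,
                  ratio_window: tuple[float, float] = (20.0, 40.0),
                  ) -> PerturbedRunResult:
    """Control vs perturbed consolidation runs with matched seeds.

    Both runs use fixed-threshold criticality; the perturbation switches
    on at ``spec.t_onset`` (which should lie well after equilibration).
    Forgetting curves are probed at the given delays after onset, and the
    capacity ratio is averaged over snapshots in ``ratio_window`` (units
    of tau) after onset.
    """
    control_spec = PerturbationSpec(kind="none", theta=spec.theta,
                                    t_onset=spec.t_onset)
    probes = tuple(spec.t_onset + d * cfg.tau for d in probe_delays)
    t_meas = spec.t_onset + ratio_window[0] * cfg.tau
    t_meas_end = spec.t_onset + ratio_window[1] * cfg.tau
    if cfg.total_time < t_meas_end:
        raise ValueError("total time too short for the capacity window")
    results = []
    for sp in (control_spec, spec):
        crit = _make_criticality(tmodel, sp, cfg)
        results.append(run_simulation(cfg, basin, criticality=crit,
                                      probe_times=probes,
                                      t_measure_start=t_meas))
    control, pert = results
    ratio = pert.summary.capacity / control.summary.capacity \
        if control.summary.capacity > 0 else float("nan")
    return PerturbedRunResult(control=control, perturbed=pert,
                              capacity_ratio=float(ratio),
                              probe_delays=tuple(probe_delays), spec=spec)


def mixed_term_diagnostic(N: int = 400, n_mem: int = 40, D: float = 0.5,
                          tau: float = 50.0, f: float = 0.05,
                          T: float = 100.0, dt: float = 0.5,
                          seed: int = 0) -> float:
    """Relative size of the efficacy-noise cross term in the field variance.

    The additive-noise analysis treats the memory interference and the
    accumulated synaptic noise as independent contributions to the local
    field variance, dropping the mixed covariance (efficacies depend on
    the noise history only through the global rehearsal gating).  This
    diagnostic simulates a small network with an Ornstein-Uhlenbeck noise
    matrix coupled to decaying/rehearsed efficacies and returns the
    average |cross| / total field-variance ratio at probe patterns.
    """
    rng = np.random.default_rng(seed)
    from .network import build_connectivity, generate_patterns
    mem = generate_patterns(n_mem, N, f, rng)
    A = np.ones(n_mem)
    Jn = np.zeros((N, N))
    lam, b = 0.1, 0.3
    t = 0.0
    while t < T:
        # OU noise on the symmetric synaptic matrix
        g = rng.standard_normal((N, N))
        g = (g + g.T) / np.sqrt(2.0)
        Jn += -Jn * dt / tau + D * np.sqrt(dt) * g / N
        # efficacies: decay plus rehearsals gated by the total noise
        noise_var = float(np.mean(Jn ** 2)) * f * N
        delta_tot = np.sqrt((f / N) * np.sum(A ** 2) + noise_var)
        elig = A >= 4.0 * delta_tot
        A *= np.exp(-dt / tau)
        A[elig & (rng.random(n_mem) < lam * dt)] += b
        t += dt
    Jm = build_connectivity(mem, A).J
    ratios = []
    X = mem.patterns.astype(float)
    for l in range(n_mem):
        sig = X[l]
        hm = Jm @ sig - A[l] * (1 - f) * sig  # remove the signal term
        hn = Jn @ sig
        vm, vn = np.var(hm), np.var(hn)
        cross = 2.0 * np.mean((hm - hm.mean()) * (hn - hn.mean()))
        ratios.append(abs(cross) / (vm + vn + abs(cross)))
    return float(np.mean(ratios))


def optimize_threshold(cfg: SimConfig, spec: PerturbationSpec,
                       basin: BasinTable, theta_grid=None,
                       f: Optional[float] = None,
                       ratio_window: tuple[float, float] = (10.0, 20.0),
                       ) -> tuple[float, dict]:
    """Capacity-maximizing firing threshold under a given perturbation.

    Grid search with common random numbers (every theta reuses the same
    seeds); neural adaptation lowering theta partially compensates the
    efficacy loss from dilution by lowering the retrieval floor A_c.
    Returns the best theta and the capacity per theta.
    """
    if theta_grid is None:
        theta_grid = np.arange(0.20, 0.501, 0.01)
    f = f if f is not None else cfg.f
    t_meas = spec.t_onset + ratio_window[0] * cfg.tau
    caps = {}
    for theta in np.asarray(theta_grid, dtype=float):
        tm = critical_efficacy_fixed_threshold(theta, f,
                                               delta_grid=np.linspace(
                                                   1e-3, 0.6 * theta, 60))
        sp = replace(spec, theta=float(theta))
        crit = _make_criticality(tm, sp, cfg)
        res = run_simulation(cfg, basin, criticality=crit,
                             t_measure_start=t_meas)
        caps[float(theta)] = res.summary.capacity
    best = max(caps, key=caps.get)
    return best, caps
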