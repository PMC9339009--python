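"""Mean-field stochastic simulator of memory consolidation.

A new memory arrives at every integer time with initial efficacy A(0)
(unit inter-arrival time sets the time unit).  Each efficacy decays
exponentially with the synaptic decay time ``tau`` and receives increments
``b`` at stochastic rehearsal events.  Rehearsals form an inhomogeneous
Poisson process with rate ``lam * F(A / A_c)``, where ``F`` is the
normalized basin-of-attraction function computed by
:mod:`memcons.meanfield` and ``A_c = a(f) * Delta`` is the critical
efficacy set by the self-consistent interference noise

    Delta^2 = (f / N) * sum_n A_n^2 .

Memories with ``A > A_c`` are retrievable; the forgetting curve is the
probability of retrieval as a function of memory age once the system has
equilibrated.  The module also provides the closed-form pure-forgetting
analytics (the no-rehearsal limit), the consolidation fixed point
``A_fp = b lam tau F(A_fp / A_c)``, and the capacity approximations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .meanfield import BasinTable

__all__ = [
    "SimConfig",
    "EfficacyEnsemble",
    "ForgettingCurve",
    "EfficacyHistogram",
    "SimSummary",
    "SimResult",
    "interference_noise",
    "rehearsal_rate",
    "simulate_step",
    "run_simulation",
    "efficacy_fixed_point",
    "pure_forgetting_analytics",
    "consolidation_time",
    "ConsolidationTime",
    "capacity",
    "consolidation_probability",
    "capacity_approximation",
]

_TRUNC_EFFICACY = 1e-6   # drop memories below this fraction of A_c ...
_TRUNC_AGE = 10.0        # ... once older than this many tau
_COMPACT_EVERY = 256     # steps between truncation sweeps


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a consolidation run.

    Times are in units of the memory inter-arrival interval.  ``lam`` is
    the maximal rehearsal rate per unit time; the dimensionless products
    ``lam * tau`` (mean rehearsals per decay time) and ``b * lam * tau``
    (the consolidation fixed point scale) are the parameters that organize
    the model's phase diagram.

    ``A0_dist`` specifies the initial-efficacy distribution as a tuple:
    ``("constant", v)``, ``("exponential", mean)``, or ``("bernoulli", a0)``
    in which half of the memories start at 1 and half at ``a0``.
    """

    N: int = 8000
    f: float = 0.01
    tau: float = 160.0
    lam: float = 5.0 / 160.0
    b: float = 0.3
    dt: Optional[float] = None
    T: Optional[float] = None
    n_realizations: int = 10
    seed: int = 0
    A0_dist: tuple = ("constant", 1.0)
    bin_width: Optional[float] = None
    snapshot_every: Optional[float] = None
    eq_window: Optional[float] = None
    eq_rtol: float = 0.02
    keep_memory_records: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 < self.b < 1.0:
            raise ValueError("rehearsal increment b must satisfy 0 < b < 1")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.A0_dist[0] not in ("constant", "exponential", "bernoulli"):
            raise ValueError(f"unknown A0 distribution {self.A0_dist[0]!r}")
        if self.lam > 0 and self.step * self.lam > 0.1 + 1e-12:
            raise ValueError("dt * lam must not exceed 0.1 (thinning bias)")

    @property
    def lam_tau(self) -> float:
        return self.lam * self.tau

    @property
    def step(self) -> float:
        """Integration step; defaults to 0.05/lam (tau/50 when lam = 0)."""
        if self.dt is not None:
            return self.dt
        return 0.05 / self.lam if self.lam > 0 else self.tau / 50.0

    @property
    def total_time(self) -> float:
        return self.T if self.T is not None else 400.0 * self.tau

    @classmethod
    def from_lam_tau(cls, lam_tau: float, **kwargs) -> "SimConfig":
        tau = kwargs.get("tau", cls.tau)
        return cls(lam=lam_tau / tau, **kwargs)


def interference_noise(efficacies: np.ndarray, f: float, N: int) -> float:
    """Interference noise Delta = sqrt((f/N) * sum A^2)."""
    a = np.asarray(efficacies, dtype=float)
    return float(np.sqrt((f / N) * np.dot(a, a)))


def rehearsal_rate(A, a_c: float, lam: float, basin: BasinTable):
    """Poisson rehearsal rate lam * F(A / A_c) per unit time.

    In the startup limit (no interference yet, ``a_c == 0``) every extant
    memory has a maximal basin and the rate saturates at ``lam``.
    """
    A = np.asarray(A, dtype=float)
    if a_c <= 0.0:
        out = np.where(A > 0, lam, 0.0)
    else:
        out = lam * basin(A / a_c)
    return out if out.ndim else float(out)


@dataclass
class EfficacyEnsemble:
    """Dynamic state of the mean-field simulator (active memories only).

    Memories whose efficacy has decayed far below ``A_c`` are dropped from
    the active arrays (their noise contribution is negligible); bookkeeping
    arrays indexed by global memory id live in the driver.
    """

    efficacies: np.ndarray
    birth_times: np.ndarray
    ids: np.ndarray
    delta: float
    a_c: float
    time: float
    n_total: int = 0

    @classmethod
    def empty(cls) -> "EfficacyEnsemble":
        return cls(efficacies=np.empty(0), birth_times=np.empty(0),
                   ids=np.empty(0, dtype=np.int64), delta=0.0, a_c=0.0,
                   time=0.0)

    def recompute_noise(self, f: float, N: int) -> float:
        return interference_noise(self.efficacies, f, N)


def _cohort_bin_totals(t: float, first_birth: float, n_total: int,
                       bin_w: float, n_bins: int) -> np.ndarray:
    """Number of cohort memories per age bin at observation time ``t``.

    Memories are born one per integer time; the cohort comprises births in
    ``[first_birth, t]``.  Counting from the birth schedule rather than the
    active arrays keeps long-forgotten (truncated) memories in the
    denominator of the forgetting curve.
    """
    lo_born = int(np.ceil(first_birth))
    hi_born = n_total - 1
    if hi_born < lo_born:
        return np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * bin_w          # age bin edges
    # age in [edges[k], edges[k+1]) means birth in (t - edges[k+1],
    # t - edges[k]]; integers in (A, B] number floor(B) - floor(A)
    upper = np.floor(np.minimum(t - edges[:-1], hi_born))
    lower = np.maximum(np.floor(t - edges[1:]), lo_born - 1.0)
    return np.maximum(upper - lower, 0.0)


def _default_criticality(basin: BasinTable) -> Callable[[float, float], float]:
    a_f = basin.a_f
    return lambda delta, t: a_f * delta


def _sample_A0(dist: tuple, n: int, ids: np.ndarray, rng) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        return np.full(n, float(dist[1]))
    if kind == "exponential":
        return rng.exponential(float(dist[1]), size=n)
    # bernoulli: alternate deterministically so both cohorts are equally
    # represented at every age (the global id fixes the cohort)
    a0 = float(dist[1])
    return np.where(ids % 2 == 0, 1.0, a0)


def simulate_step(state: EfficacyEnsemble, cfg: SimConfig, basin: BasinTable,
                  rng: np.random.Generator,
                  criticality: Optional[Callable[[float, float], float]] = None,
                  ) -> tuple[EfficacyEnsemble, np.ndarray, np.ndarray]:
    """Advance the ensemble by one integration step ``cfg.step``.

    Order of events: exact multiplicative decay, rehearsal draws by Poisson
    thinning against the critical efficacy from the *previous* step, then
    insertion of new memories at the integer times inside the step, and
    finally the noise/criticality update.  Returns the new state plus the
    (local) indices of rehearsed memories and the global ids of insertions.
    """
    if criticality is None:
        criticality = _default_criticality(basin)
    dt = cfg.step
    t_new = state.time + dt
    A = state.efficacies
    A *= np.exp(-dt / cfg.tau)
    # rehearsals (Poisson thinning at probability lam * F * dt)
    if cfg.lam > 0 and A.size:
        if state.a_c > 0.0:
            eligible = np.where(A >= state.a_c)[0]
        else:
            eligible = np.where(A > 0.0)[0]
        if eligible.size:
            prob = rehearsal_rate(A[eligible], state.a_c, cfg.lam, basin) * dt
            hits = eligible[rng.random(eligible.size) < prob]
            A[hits] += cfg.b
        else:
            hits = np.empty(0, dtype=np.intp)
    else:
        hits = np.empty(0, dtype=np.intp)
    # new memories: one per integer time; memory l (the next is n_total)
    # enters once t reaches l
    last = int(np.floor(t_new))
    if last >= state.n_total:
        births = np.arange(state.n_total, last + 1, dtype=np.int64)
        a0 = _sample_A0(cfg.A0_dist, births.size, births, rng)
        # decay exactly from the birth instant to the end of the step so
        # that the multiplicative update reproduces exp(-(t-l)/tau)
        a_init = a0 * np.exp(-(t_new - births) / cfg.tau)
        A = np.concatenate([A, a_init])
        birth_times = np.concatenate([state.birth_times, births.astype(float)])
        ids = np.concatenate([state.ids, births])
        n_total = last + 1
    else:
        births = np.empty(0, dtype=np.int64)
        birth_times, ids, n_total = state.birth_times, state.ids, state.n_total
    delta = interference_noise(A, cfg.f, cfg.N)
    a_c = criticality(delta, t_new)
    new_state = EfficacyEnsemble(efficacies=A, birth_times=birth_times,
                                 ids=ids, delta=delta, a_c=a_c, time=t_new,
                                 n_total=n_total)
    return new_state, hits, births


@dataclass
class ForgettingCurve:
    """Retrieval probability vs memory age (ages in units of tau)."""

    age_bins: np.ndarray          # bin centers, units of tau
    retrieval_prob: np.ndarray    # NaN where a bin has no samples
    n_samples: np.ndarray
    tau: float = 1.0
    bin_width: float = 0.5        # units of tau

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age_tau": self.age_bins, "prob": self.retrieval_prob,
                      "n": self.n_samples}).to_csv(path, index=False)

    @classmethod
    def from_counts(cls, cnt, tot, tau, bin_width) -> "ForgettingCurve":
        cnt = np.asarray(cnt, dtype=float)
        tot = np.asarray(tot, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, cnt / np.maximum(tot, 1.0), np.nan)
        centers = (np.arange(cnt.size) + 0.5) * (bin_width / tau)
        return cls(age_bins=centers, retrieval_prob=p, n_samples=tot,
                   tau=tau, bin_width=bin_width / tau)


@dataclass
class EfficacyHistogram:
    """Equilibrium distribution of memory efficacies (log-spaced bins)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def density(self) -> np.ndarray:
        w = np.diff(self.bin_edges)
        tot = self.counts.sum()
        return self.counts / (w * max(tot, 1.0))

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def sub_critical_slope(self, a_c: float, lo_frac: float = 1e-3) -> float:
        """Log-log slope of p(A) on the forgotten branch (A < A_c).

        The decaying pool has p(A) = tau / A, i.e. a slope of -1.
        """
        c, d = self.centers, self.density
        m = (c > lo_frac * a_c) & (c < 0.5 * a_c) & (d > 0)
        if m.sum() < 4:
            raise ValueError("too few populated bins below A_c for a slope fit")
        slope = np.polyfit(np.log(c[m]), np.log(d[m]), 1)[0]
        return float(slope)

    def consolidated_mode(self, a_c: float) -> float:
        """Location of the density mode above A_c (the consolidated pool)."""
        c, d = self.centers, self.density
        m = c > a_c
        if not m.any() or d[m].max() == 0:
            raise ValueError("no consolidated mode above A_c")
        return float(c[m][np.argmax(d[m])])


@dataclass
class SimSummary:
    """Equilibrium observables of a consolidation run."""

    capacity: float
    p_c: Optional[float]
    tau_c: Optional[float]
    a_fp: float
    a_c_eq: float

    def to_dict(self) -> dict:
        return {"capacity": self.capacity, "p_c": self.p_c,
                "tau_c": self.tau_c, "a_fp": self.a_fp,
                "a_c_eq": self.a_c_eq}


@dataclass
class SimResult:
    """Aggregate output of :func:`run_simulation`."""

    config: SimConfig
    summary: SimSummary
    curve: ForgettingCurve
    a_c_times: np.ndarray            # sample times (time units)
    a_c_mean: np.ndarray             # mean over realizations
    histogram: EfficacyHistogram
    t_equilibrium: np.ndarray        # per realization
    capacity_samples: np.ndarray     # per realization
    a_c_eq_samples: np.ndarray       # per realization
    records: Optional[pd.DataFrame]  # per-memory birth/A0/max efficacy/lifetime
    probes: dict = field(default_factory=dict)  # time -> (cnt, tot) age hists
    equilibrated: bool = True


def _run_realization(cfg: SimConfig, basin: BasinTable,
                     rng: np.random.Generator,
                     criticality: Callable[[float, float], float],
                     probe_times: Sequence[float],
                     hist_edges: np.ndarray,
                     t_measure_start: Optional[float]) -> dict:
    dt = cfg.step
    T = cfg.total_time
    tau = cfg.tau
    bin_w = cfg.bin_width if cfg.bin_width is not None else tau / 2.0
    snap_dt = cfg.snapshot_every if cfg.snapshot_every is not None else tau / 2.0
    eq_win = cfg.eq_window if cfg.eq_window is not None else 10.0 * tau
    n_bins = int(np.ceil(T / bin_w)) + 1
    cnt = np.zeros(n_bins)
    tot = np.zeros(n_bins)
    hist_counts = np.zeros(hist_edges.size - 1)
    n_mem_max = int(np.floor(T)) + 2
    max_eff = np.zeros(n_mem_max)
    a0_all = np.zeros(n_mem_max)
    last_above = np.full(n_mem_max, np.nan)
    sample_times: list[float] = []
    a_c_series: list[float] = []
    caps: list[float] = []
    ac_eq: list[float] = []
    state = EfficacyEnsemble.empty()
    next_sample = 0.0
    next_snap = np.inf
    measure_begin: Optional[float] = None
    t_eq: Optional[float] = None
    win_sum, win_n, win_end, prev_win_mean = 0.0, 0, eq_win, None
    probes_left = sorted(probe_times)
    probe_out: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    step_i = 0
    while state.time < T - 1e-9:
        state, hits, births = simulate_step(state, cfg, basin, rng,
                                            criticality)
        t = state.time
        if hits.size:
            gid = state.ids[hits]
            np.maximum.at(max_eff, gid, state.efficacies[hits])
        if births.size:
            a0 = state.efficacies[-births.size:] * np.exp(
                (t - births) / tau)  # undo the partial-step decay
            a0_all[births] = a0
            np.maximum.at(max_eff, births, a0)
        if state.a_c > 0.0 and state.efficacies.size:
            above = state.efficacies > state.a_c
            if above.any():
                last_above[state.ids[above]] = t
        # equilibrium detection: consecutive window means of A_c within rtol
        win_sum += state.a_c
        win_n += 1
        if t >= win_end and t_eq is None:
            wm = win_sum / max(win_n, 1)
            if prev_win_mean is not None and prev_win_mean > 0 and \
                    abs(wm - prev_win_mean) < cfg.eq_rtol * prev_win_mean:
                t_eq = t
                if t_measure_start is None:
                    next_snap = t
            prev_win_mean = wm
            win_sum, win_n = 0.0, 0
            win_end += eq_win
        if t_measure_start is not None and next_snap == np.inf and \
                t >= t_measure_start:
            next_snap = t
        if t >= next_sample:
            sample_times.append(t)
            a_c_series.append(state.a_c)
            next_sample += snap_dt
        if t >= next_snap:
            if measure_begin is None:
                measure_begin = t
            A, ids = state.efficacies, state.ids
            ret = A > state.a_c
            caps.append(float(ret.sum()))
            ac_eq.append(state.a_c)
            # the forgetting curve pools only cohorts born at equilibrium;
            # earlier cohorts consolidated under a lower A_c and would
            # inflate retention at old ages.  Denominators come from the
            # birth schedule so that truncated (long-forgotten) memories
            # still count as non-retrievable.
            tot += _cohort_bin_totals(t, measure_begin, state.n_total,
                                      bin_w, n_bins)
            cm = ret & (state.birth_times >= measure_begin)
            if cm.any():
                ages = t - state.birth_times[cm]
                bi = np.minimum((ages / bin_w).astype(int), n_bins - 1)
                np.add.at(cnt, bi, 1.0)
            pos = A > 0
            hist_counts += np.histogram(A[pos], bins=hist_edges)[0]
            next_snap += snap_dt
        while probes_left and t >= probes_left[0]:
            pt = probes_left.pop(0)
            ptot = _cohort_bin_totals(t, 0.0, state.n_total, bin_w, n_bins)
            pc = np.zeros(n_bins)
            retrievable = state.efficacies > state.a_c
            if retrievable.any():
                ages = t - state.birth_times[retrievable]
                bi = np.minimum((ages / bin_w).astype(int), n_bins - 1)
                np.add.at(pc, bi, 1.0)
            probe_out[pt] = (pc, ptot)
        step_i += 1
        if step_i % _COMPACT_EVERY == 0 and state.efficacies.size:
            A = state.efficacies
            old = (t - state.birth_times) > _TRUNC_AGE * tau
            dead = old & (A < _TRUNC_EFFICACY * max(state.a_c, 1e-300))
            if dead.any():
                keep = ~dead
                state = replace(state, efficacies=A[keep],
                                birth_times=state.birth_times[keep],
                                ids=state.ids[keep])
    n_total = state.n_total
    return {
        "cnt": cnt, "tot": tot, "hist": hist_counts,
        "sample_times": np.asarray(sample_times),
        "a_c_series": np.asarray(a_c_series),
        "caps": np.asarray(caps), "ac_eq": np.asarray(ac_eq),
        "t_eq": t_eq, "probes": probe_out,
        "birth": np.arange(n_total, dtype=float),
        "a0": a0_all[:n_total], "max_eff": max_eff[:n_total],
        "last_above": last_above[:n_total],
        "final_time": state.time,
    }


def run_simulation(cfg: SimConfig, basin: BasinTable,
                   criticality: Optional[Callable[[float, float], float]] = None,
                   probe_times: Sequence[float] = (),
                   t_measure_start: Optional[float] = None) -> SimResult:
    """Simulate ``cfg.n_realizations`` independent runs and pool observables.

    Each realization uses a child RNG spawned from ``cfg.seed``, so results
    are bitwise reproducible.  Forgetting-curve, capacity, histogram and
    consolidation statistics are accumulated only after the critical
    efficacy has equilibrated (consecutive 10-tau window means within
    ``eq_rtol``), or from ``t_measure_start`` if given.
    """
    if criticality is None:
        criticality = _default_criticality(basin)
    tau = cfg.tau
    bin_w = cfg.bin_width if cfg.bin_width is not None else tau / 2.0
    a_scale = max(cfg.b * cfg.lam * cfg.tau, 1.0)
    hist_edges = np.logspace(-5, np.log10(10.0 * a_scale), 121)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_realizations)
    outs = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        outs.append(_run_realization(cfg, basin, rng, criticality,
                                     probe_times, hist_edges,
                                     t_measure_start))
    equilibrated = all(o["t_eq"] is not None for o in outs)
    if not equilibrated and t_measure_start is None:
        warnings.warn("critical efficacy did not equilibrate within T in at "
                      "least one realization; summary statistics cover only "
                      "realizations that equilibrated", stacklevel=2)
    cnt = np.sum([o["cnt"] for o in outs], axis=0)
    tot = np.sum([o["tot"] for o in outs], axis=0)
    curve = ForgettingCurve.from_counts(cnt, tot, tau, bin_w)
    hist = EfficacyHistogram(bin_edges=hist_edges,
                             counts=np.sum([o["hist"] for o in outs], axis=0))
    n_t = min(o["sample_times"].size for o in outs)
    a_c_times = outs[0]["sample_times"][:n_t]
    a_c_mean = np.mean([o["a_c_series"][:n_t] for o in outs], axis=0)
    caps = np.array([o["caps"].mean() if o["caps"].size else np.nan
                     for o in outs])
    ac_eqs = np.array([o["ac_eq"].mean() if o["ac_eq"].size else np.nan
                       for o in outs])
    t_eqs = np.array([o["t_eq"] if o["t_eq"] is not None else np.nan
                      for o in outs])
    a_c_eq = float(np.nanmean(ac_eqs))
    a_fp = efficacy_fixed_point(a_c_eq, cfg.b, cfg.lam, cfg.tau, basin)
    records = None
    p_c = None
    frames = []
    for k, o in enumerate(outs):
        te = o["t_eq"] if o["t_eq"] is not None else t_measure_start
        if te is None:
            continue
        df = pd.DataFrame({"birth": o["birth"], "A0": o["a0"],
                           "max_eff": o["max_eff"],
                           "lifetime": o["last_above"] - o["birth"]})
        df["realization"] = k
        df["post_eq"] = (df["birth"] >= te) & \
            (df["birth"] <= o["final_time"] - 5.0 * tau)
        frames.append(df)
    if frames:
        records = pd.concat(frames, ignore_index=True)
        if a_fp > a_c_eq:
            p_c = consolidation_probability(records, a_fp, a_c_eq)
        if not cfg.keep_memory_records:
            records = None
    probes = {}
    for pt in probe_times:
        pcs = [o["probes"][pt] for o in outs if pt in o["probes"]]
        if pcs:
            probes[pt] = (np.sum([p[0] for p in pcs], axis=0),
                          np.sum([p[1] for p in pcs], axis=0))
    summary = SimSummary(capacity=float(np.nanmean(caps)), p_c=p_c,
                         tau_c=None, a_fp=a_fp, a_c_eq=a_c_eq)
    return SimResult(config=cfg, summary=summary, curve=curve,
                     a_c_times=a_c_times, a_c_mean=a_c_mean, histogram=hist,
                     t_equilibrium=t_eqs, capacity_samples=caps,
                     a_c_eq_samples=ac_eqs, records=records, probes=probes,
                     equilibrated=equilibrated)


def efficacy_fixed_point(a_c: float, b: float, lam: float, tau: float,
                         basin: BasinTable, max_iter: int = 500,
                         tol: float = 1e-12) -> float:
    """Largest solution of A = b lam tau F(A / A_c) (0 if only trivial).

    Fixed-point iteration from the ceiling b lam tau converges onto the
    upper stable solution when it exists; when the rehearsal drive cannot
    lift any efficacy above A_c the iteration collapses into the F = 0
    region and the zero solution is returned.
    """
    drive = b * lam * tau
    if a_c <= 0.0:
        return drive
    A = drive
    for _ in range(max_iter):
        A_new = drive * float(basin(A / a_c))
        if abs(A_new - A) < tol * max(A, 1.0):
            A = A_new
            break
        A = A_new
    return A if A > a_c else 0.0


def pure_forgetting_analytics(N: int, f: float, tau: float,
                              a_f: float) -> tuple[float, float]:
    """Pure-forgetting (no rehearsal) scales: (tau0, catastrophic age t0).

    ``tau0 = 2 N / (f a(f)^2)`` is the decay time at which the critical
    efficacy reaches the encoding strength and nothing is retrievable;
    below it, memories older than ``t0 = (tau/2) log(tau0/tau)`` are lost.
    ``t0`` is also the pure-forgetting capacity (one memory per time unit).
    """
    tau0 = 2.0 * N / (f * a_f ** 2)
    if tau >= tau0:
        return tau0, 0.0
    return tau0, 0.5 * tau * float(np.log(tau0 / tau))


def capacity(obj) -> float:
    """Number of retrievable memories (A > A_c), time averaged.

    Accepts an :class:`EfficacyEnsemble` (instantaneous count), an array of
    per-snapshot counts, or a :class:`SimResult`.
    """
    if isinstance(obj, SimResult):
        return obj.summary.capacity
    if isinstance(obj, EfficacyEnsemble):
        return float(np.sum(obj.efficacies > obj.a_c))
    return float(np.mean(np.asarray(obj, dtype=float)))


def consolidation_probability(records: pd.DataFrame, a_fp: float,
                              a_c: float, band: float = 0.8,
                              cohort_a0: Optional[float] = None) -> float:
    """Fraction of memories whose efficacy ever reached the consolidated band.

    A memory counts as consolidated when its peak efficacy exceeded
    ``A_c + band * (A_fp - A_c)`` (reaching exactly A_fp is ill-defined
    under rehearsal fluctuations).  Only post-equilibrium cohorts with at
    least 5 tau of subsequent simulated time are counted.  ``cohort_a0``
    restricts the estimate to memories with that initial efficacy.
    """
    if a_fp <= a_c:
        raise ValueError("consolidation probability undefined when "
                         "A_fp <= A_c")
    df = records[records["post_eq"]]
    if cohort_a0 is not None:
        df = df[np.isclose(df["A0"], cohort_a0)]
    if len(df) == 0:
        return float("nan")
    thresh = a_c + band * (a_fp - a_c)
    return float((df["max_eff"] > thresh).mean())


@dataclass
class ConsolidationTime:
    """Slow time constant of the forgetting curve (units of tau)."""

    tau_c: Optional[float]
    fit: Optional[object]
    pure_forgetting: bool = False


def consolidation_time(curve: ForgettingCurve, model: str = "exponential",
                       age_range=None) -> ConsolidationTime:
    """Consolidation time tau_c from the forgetting curve's slow tail.

    With moderate rehearsal drive (b lam tau ~ 1) the tail is a single
    exponential; with strong drive a double exponential separates the fast
    unconsolidated drop (~tau) from the slow consolidated tail.  A
    step-like curve (the no-rehearsal limit) has no exponential tail and
    is flagged as pure forgetting instead of being fitted.
    """
    from .fits import fit_double_exponential, fit_exponential_tail
    p = curve.retrieval_prob
    graded = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if graded.sum() < 10:
        return ConsolidationTime(tau_c=None, fit=None, pure_forgetting=True)
    if model == "exponential":
        fit = fit_exponential_tail(curve, age_range)
        return ConsolidationTime(tau_c=fit.params["tau_c"], fit=fit)
    if model == "double_exponential":
        fit = fit_double_exponential(curve, age_range)
        return ConsolidationTime(tau_c=fit.params["tau2"], fit=fit)
    raise ValueError(f"unknown tail model {model!r}")


@dataclass(frozen=True)
class CapacityApproximation:
    a_c: float
    capacity: float
    n_scaling_exponent: float


def capacity_approximation(N: int, f: float, tau: float, lam: float,
                           b: float, a_f: float, p_c: float,
                           tau_c: float) -> CapacityApproximation:
    """Closed-form equilibrium estimates in the p_c ~ 1 regime.

    ``tau_c`` must be given in the same time units as ``tau`` (memory
    arrivals), not in units of tau.

    The critical efficacy follows from attributing the interference to the
    consolidated pool (p_c tau_c memories near b lam tau):

        A_c ~ sqrt(f a(f)^2 p_c tau_c / N) * b lam tau

    and self-consistency of the consolidated lifetime yields

        capacity ~ tau_c ~ tau^{1/(1 + lam tau / 2)}
                   * (N / (f a(f)^2))^{lam tau / (2 + lam tau)}

    whose N-scaling exponent lam tau / (2 + lam tau) approaches one for
    frequent rehearsals.
    """
    lt = lam * tau
    a_c = float(np.sqrt(f * a_f ** 2 * p_c * tau_c / N) * b * lt)
    expo = lt / (2.0 + lt)
    cap = float(tau ** (1.0 / (1.0 + 0.5 * lt)) *
                (N / (f * a_f ** 2)) ** expo)
    return CapacityApproximation(a_c=a_c, capacity=cap,
                                 n_scaling_exponent=expo)
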