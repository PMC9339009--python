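"""Full binary recurrent-network simulation of sparse attractor memories.

Patterns are i.i.d. Bernoulli(f) binary vectors; the connectivity is the
efficacy-weighted sum of centered Hebbian outer products,

    J_ij = 1/(N f (1-f)) * sum_l A_l (xi_i^l - f)(xi_j^l - f),   J_ii = 0.

Network states are binary.  In fixed-activity mode the f*N neurons with
the largest local fields fire at every (synchronous) update, emulating a
threshold adjusted by global inhibition; in fixed-threshold mode each
neuron fires when its field exceeds a fixed theta.  A memory counts as
retrieved when, started from the pattern, the dynamics settle at an
overlap of at least 0.85 with it; the basin of attraction is probed by
activity-conserving random flips of the initial state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .consolidation import ForgettingCurve

__all__ = [
    "MemorySet",
    "Connectivity",
    "NetworkState",
    "generate_patterns",
    "build_connectivity",
    "step_fixed_activity",
    "step_fixed_threshold",
    "overlap",
    "test_retrieval",
    "measure_basin_size",
    "network_forgetting_curve",
]


@dataclass
class MemorySet:
    """Stored binary patterns (T x N, entries 0/1) at sparseness f."""

    patterns: np.ndarray
    f: float

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.patterns.shape[1]


@dataclass
class Connectivity:
    """Symmetric synaptic matrix with optional dilution mask applied."""

    J: np.ndarray
    f: float
    dilution_mask: Optional[np.ndarray] = None


@dataclass
class NetworkState:
    """Binary activation vector."""

    sigma: np.ndarray

    @property
    def activity(self) -> float:
        return float(self.sigma.mean())


def generate_patterns(T: int, N: int, f: float,
                      seed: int | np.random.Generator = 0) -> MemorySet:
    """T i.i.d. Bernoulli(f) patterns of N binary neurons."""
    if T < 1 or N < 1:
        raise ValueError("need at least one pattern and one neuron")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    patterns = (rng.random((T, N)) < f).astype(np.int8)
    return MemorySet(patterns=patterns, f=f)


def build_connectivity(memories: MemorySet,
                       efficacies: np.ndarray) -> Connectivity:
    """Efficacy-weighted centered Hebbian matrix with zero diagonal."""
    A = np.asarray(efficacies, dtype=float)
    if A.shape != (memories.n_patterns,):
        raise ValueError(
            f"need one efficacy per pattern: {A.shape} vs "
            f"{memories.n_patterns} patterns")
    f, N = memories.f, memories.n_neurons
    X = memories.patterns.astype(float) - f
    J = (X.T * A) @ X / (N * f * (1.0 - f))
    np.fill_diagonal(J, 0.0)
    return Connectivity(J=J, f=f)


def local_fields(state: NetworkState, conn: Connectivity) -> np.ndarray:
    return conn.J @ state.sigma.astype(float)


def step_fixed_activity(state: NetworkState, conn: Connectivity, f: float,
                        rng: np.random.Generator) -> NetworkState:
    """Synchronous update firing the round(fN) neurons with largest fields.

    Ties (e.g. a zero matrix) are broken uniformly at random with the
    run's generator so results stay reproducible.
    """
    h = local_fields(state, conn)
    N = h.size
    k = int(round(f * N))
    order = np.lexsort((rng.random(N), -h))
    sigma = np.zeros(N, dtype=np.int8)
    sigma[order[:k]] = 1
    return NetworkState(sigma=sigma)


def step_fixed_threshold(state: NetworkState, conn: Connectivity,
                         theta: float) -> NetworkState:
    """Synchronous update sigma_i <- Theta(h_i - theta)."""
    h = local_fields(state, conn)
    return NetworkState(sigma=(h > theta).astype(np.int8))


def overlap(state: NetworkState, pattern: np.ndarray, f: float) -> float:
    """Centered overlap M = f+ - f-.

    ``f+`` is the fraction of pattern-active units that are active in the
    state, ``f-`` the fraction of pattern-inactive units active.  This is
    the conditional-rate form of (1/(N f (1-f))) sum (xi - f) sigma — the
    two coincide when the pattern's active count is exactly f N, and the
    conditional form stays exact (self-overlap one) under the binomial
    fluctuations of finite patterns.
    """
    xi = np.asarray(pattern)
    sigma = state.sigma
    if xi.shape != sigma.shape:
        raise ValueError("pattern and state dimensions differ")
    on = xi > 0
    n_on = int(on.sum())
    if n_on == 0 or n_on == xi.size:
        raise ValueError("pattern must have both active and inactive units")
    f_plus = float(sigma[on].mean())
    f_minus = float(sigma[~on].mean())
    return f_plus - f_minus


def _iterate(state: NetworkState, conn: Connectivity, mode: str, f: float,
             theta: float, rng: np.random.Generator,
             max_sweeps: int = 50) -> tuple[NetworkState, bool]:
    """Run synchronous updates until a period-1 or period-2 cycle.

    Symmetric synchronous dynamics can settle on 2-cycles; the returned
    state is the cycle member reached last (callers score both members
    when needed).  Returns (state, converged).
    """
    prev = state.sigma.tobytes()
    prev2 = None
    for _ in range(max_sweeps):
        if mode == "fixed_activity":
            state = step_fixed_activity(state, conn, f, rng)
        else:
            state = step_fixed_threshold(state, conn, theta)
        cur = state.sigma.tobytes()
        if cur == prev or cur == prev2:
            return state, True
        prev2, prev = prev, cur
    return state, False


def test_retrieval(pattern: np.ndarray, conn: Connectivity,
                   dynamics_mode: str = "fixed_activity",
                   theta: float = 0.36,
                   rng: int | np.random.Generator = 0,
                   overlap_cut: float = 0.85,
                   init: Optional[np.ndarray] = None,
                   max_sweeps: int = 50) -> tuple[bool, float, bool]:
    """Initialize at the pattern (or ``init``), relax, test the overlap.

    Returns (retrievable, final overlap, converged).  For a period-2
    cycle the better of the two cycle states is scored.  Non-convergence
    is flagged with the last overlap rather than raised.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    sigma0 = np.asarray(init if init is not None else pattern, dtype=np.int8)
    state, converged = _iterate(NetworkState(sigma=sigma0.copy()), conn,
                                dynamics_mode, conn.f, theta, rng,
                                max_sweeps)
    m = overlap(state, pattern, conn.f)
    # score the partner state of a possible 2-cycle as well
    if dynamics_mode == "fixed_activity":
        nxt = step_fixed_activity(state, conn, conn.f, rng)
    else:
        nxt = step_fixed_threshold(state, conn, theta)
    m = max(m, overlap(nxt, pattern, conn.f))
    return bool(m >= overlap_cut), float(m), converged


def _flip_state(pattern: np.ndarray, k: int,
                rng: np.random.Generator) -> np.ndarray:
    """Deactivate k active units and activate k inactive ones."""
    on = np.flatnonzero(pattern)
    off = np.flatnonzero(pattern == 0)
    sigma = np.asarray(pattern, dtype=np.int8).copy()
    sigma[rng.choice(on, size=k, replace=False)] = 0
    sigma[rng.choice(off, size=k, replace=False)] = 1
    return sigma


def measure_basin_size(pattern: np.ndarray, conn: Connectivity,
                       dynamics_mode: str = "fixed_activity",
                       theta: float = 0.36,
                       seed: int | np.random.Generator = 0,
                       n_flip_realizations: int = 5,
                       overlap_cut: float = 0.85) -> float:
    """Normalized basin size of a stored pattern, in [0, 1].

    Flips k active units off and k inactive units on (activity
    conserved, so 2k units change state), relaxes the dynamics, and finds
    the largest k for which the pattern is still recovered at overlap
    >= 0.85.  The result is the flipped-unit count 2 k_max over its
    maximum 2 f N, averaged over flip realizations; a dominant memory
    scores close to one.  A pattern that is not even stable at k = 0 has
    basin 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pattern = np.asarray(pattern)
    fN = int(pattern.sum())
    if fN == 0:
        return 0.0
    ok0, _, _ = test_retrieval(pattern, conn, dynamics_mode, theta, rng,
                               overlap_cut)
    if not ok0:
        return 0.0

    def recovers(k: int) -> bool:
        sigma = _flip_state(pattern, k, rng)
        ok, _, _ = test_retrieval(pattern, conn, dynamics_mode, theta, rng,
                                  overlap_cut, init=sigma)
        return ok

    kmax_total = 0
    coarse = max(1, fN // 20)
    for _ in range(n_flip_realizations):
        # coarse ascent then bisection between last success and first fail
        k_ok, k_bad = 0, None
        k = coarse
        while k <= fN:
            if recovers(k):
                k_ok = k
                k += coarse
            else:
                k_bad = k
                break
        if k_bad is not None:
            while k_bad - k_ok > 1:
                mid = (k_ok + k_bad) // 2
                if recovers(mid):
                    k_ok = mid
                else:
                    k_bad = mid
        else:
            k_ok = fN
        kmax_total += k_ok
    # 2*k units flipped out of the maximal 2*f*N
    return kmax_total / (n_flip_realizations * float(fN))


def network_forgetting_curve(efficacies: np.ndarray, ages: np.ndarray,
                             N: int, f: float, tau: float,
                             seed: int = 0,
                             dynamics_mode: str = "fixed_activity",
                             theta: float = 0.36,
                             bin_width: Optional[float] = None,
                             max_tested: int = 400,
                             efficacy_floor: float = 1e-4,
                             max_patterns: int = 20000,
                             ) -> tuple[ForgettingCurve, pd.DataFrame]:
    """Retrieval curve measured on an actual network built from efficacies.

    Generates fresh random patterns for the given efficacy snapshot
    (typically produced by the mean-field simulator at equilibrium),
    builds the connectivity matrix, and tests retrieval of up to
    ``max_tested`` memories spread over the age range.  Efficacies below
    ``efficacy_floor`` contribute negligibly to the interference and are
    excluded from the matrix to bound memory use; the pattern count is
    capped at ``max_patterns``.

    Returns the binned curve and a per-memory table
    (memory_id, age, efficacy, overlap, retrievable).
    """
    efficacies = np.asarray(efficacies, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = efficacies >= efficacy_floor
    if keep.sum() > max_patterns:
        raise MemoryError(
            f"{int(keep.sum())} patterns above the efficacy floor exceed "
            f"the configured cap {max_patterns}; raise the floor")
    A = efficacies[keep]
    age_kept = ages[keep]
    rng = np.random.default_rng(seed)
    mem = generate_patterns(A.size, N, f, rng)
    conn = build_connectivity(mem, A)
    bw = bin_width if bin_width is not None else tau / 2.0
    order = np.argsort(age_kept)
    if order.size > max_tested:
        sel = order[np.linspace(0, order.size - 1, max_tested).astype(int)]
    else:
        sel = order
    rows = []
    for i in sel:
        ok, m, _ = test_retrieval(mem.patterns[i], conn, dynamics_mode,
                                  theta, rng)
        rows.append((int(i), age_kept[i], A[i], m, ok))
    table = pd.DataFrame(rows, columns=["memory_id", "age", "efficacy",
                                        "overlap", "retrievable"])
    n_bins = int(np.ceil(age_kept.max() / bw)) + 1 if age_kept.size else 1
    cnt = np.zeros(n_bins)
    tot = np.zeros(n_bins)
    bi = np.minimum((table["age"].to_numpy() / bw).astype(int), n_bins - 1)
    np.add.at(tot, bi, 1.0)
    np.add.at(cnt, bi, table["retrievable"].to_numpy().astype(float))
    curve = ForgettingCurve.from_counts(cnt, tot, tau, bw)
    return curve, table
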