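"""Full binary-network dynamics: patterns, fields, retrieval, basins."""

import numpy as np
import pytest

import memcons as mc
from memcons import network as nw


@pytest.fixture(scope="module")
def loaded_net():
    """A network holding many memories with graded efficacies."""
    rng = np.random.default_rng(11)
    N, f, T = 2000, 0.01, 150
    A = rng.uniform(0.5, 1.5, size=T)
    mem = nw.generate_patterns(T, N, f, rng)
    conn = nw.build_connectivity(mem, A)
    return mem, conn, A


class TestPatterns:
    def test_zero_sparseness_gives_silence(self):
        mem = nw.generate_patterns(5, 100, 0.0, 0)
        assert mem.patterns.sum() == 0

    def test_active_counts_binomial(self):
        mem = nw.generate_patterns(200, 8000, 0.01, 1)
        counts = mem.patterns.sum(axis=1)
        assert counts.mean() == pytest.approx(80, rel=0.05)
        sd = np.sqrt(8000 * 0.01 * 0.99)
        assert np.all(np.abs(counts - 80) < 5 * sd)

    def test_pattern_pair_overlaps_near_zero(self):
        # centered overlaps of unrelated patterns scatter as ~1/sqrt(N f)
        rng = np.random.default_rng(2)
        N, f = 4000, 0.01
        mem = nw.generate_patterns(200, N, f, rng)
        X = mem.patterns.astype(float)
        ms = []
        for _ in range(500):
            i, j = rng.choice(200, 2, replace=False)
            ms.append(nw.overlap(nw.NetworkState(sigma=mem.patterns[i]),
                                 X[j], f))
        ms = np.asarray(ms)
        assert abs(ms.mean()) < 0.02
        # binomial oracle: var(f+) + var(f-) at independent activity f
        sd = np.sqrt(f * (1 - f) * (1 / (N * f) + 1 / (N * (1 - f))))
        assert np.std(ms) == pytest.approx(sd, rel=0.2)

    def test_requires_positive_dimensions(self):
        with pytest.raises(ValueError):
            nw.generate_patterns(0, 10, 0.1, 0)


class TestConnectivity:
    def test_zero_efficacies_zero_matrix(self):
        mem = nw.generate_patterns(3, 50, 0.1, 0)
        conn = nw.build_connectivity(mem, np.zeros(3))
        assert np.all(conn.J == 0)

    def test_symmetric_zero_diagonal(self, loaded_net):
        _, conn, _ = loaded_net
        assert np.allclose(conn.J, conn.J.T)
        assert np.all(np.diag(conn.J) == 0)

    def test_single_memory_signal_term(self):
        # field on pattern-active neurons is ~ A (1-f) when overlap is 1;
        # for a finite pattern the exact value carries the realized
        # active count n_act: A (1-f) (n_act - 1) / (f N)
        rng = np.random.default_rng(3)
        N, f, A = 4000, 0.05, 0.8
        mem = nw.generate_patterns(1, N, f, rng)
        conn = nw.build_connectivity(mem, np.array([A]))
        state = nw.NetworkState(sigma=mem.patterns[0])
        h = nw.local_fields(state, conn)
        on = mem.patterns[0] == 1
        n_act = int(on.sum())
        exact = A * (1 - f) * (n_act - 1) / (f * N)
        assert h[on].mean() == pytest.approx(exact, rel=1e-9)
        assert exact == pytest.approx(A * (1 - f), rel=0.1)

    def test_dimension_mismatch_raises(self):
        mem = nw.generate_patterns(3, 50, 0.1, 0)
        with pytest.raises(ValueError):
            nw.build_connectivity(mem, np.ones(4))

    def test_field_statistics_match_meanfield(self, loaded_net):
        # empirical mean/variance of the cross-talk field at stored
        # patterns vs the analytic signal A(1-f) and noise (f/N) sum A^2
        mem, conn, A = loaded_net
        N, f = mem.n_neurons, mem.f
        X = mem.patterns.astype(float)
        means, varis, sigs, cond_ratio, deltas, ns = [], [], [], [], [], []
        for l in range(0, 100, 5):
            state = nw.NetworkState(sigma=mem.patterns[l])
            h = nw.local_fields(state, conn)
            on = mem.patterns[l] == 1
            n_act = int(on.sum())
            means.append(h[on].mean())
            varis.append(h[~on].var())
            # realized-count signal: A (1-f)(n_act - 1)/(f N)
            sigs.append(A[l] * (1 - f) * (n_act - 1) / (f * N))
            deltas.append((f / N) * (np.sum(A ** 2) - A[l] ** 2))
            ns.append(n_act)
            # exact conditional variance given each memory's realized
            # projection S_n onto the probe state
            S = (X - f) @ X[l]
            var_i = X[:, ~on].var(axis=1)
            var_cond = float(np.sum(np.delete(A ** 2 * S ** 2 * var_i, l))
                             / (N * f * (1 - f)) ** 2)
            cond_ratio.append(h[~on].var() / var_cond)
        means, sigs = np.asarray(means), np.asarray(sigs)
        varis, deltas = np.asarray(varis), np.asarray(deltas)
        z = (means - sigs) / np.sqrt(deltas / np.asarray(ns))
        assert np.abs(z.mean()) < 3 / np.sqrt(len(z))  # pooled z < 3 sd
        # sharp check: exact conditional variance; scale check: Eq-30
        # form with realization scatter from the sparse coincidences
        assert np.mean(cond_ratio) == pytest.approx(1.0, abs=0.05)
        assert 0.6 < varis.mean() / deltas.mean() < 1.4


class TestDynamics:
    def test_fixed_activity_conserves_count(self, loaded_net):
        mem, conn, _ = loaded_net
        rng = np.random.default_rng(0)
        N, f = mem.n_neurons, mem.f
        state = nw.NetworkState(sigma=mem.patterns[0])
        for _ in range(5):
            state = nw.step_fixed_activity(state, conn, f, rng)
            assert state.sigma.sum() == round(f * N)

    def test_fixed_activity_degenerate_ties(self):
        # a zero matrix still yields exactly fN active units
        mem = nw.generate_patterns(1, 200, 0.05, 0)
        conn = nw.build_connectivity(mem, np.zeros(1))
        rng = np.random.default_rng(0)
        state = nw.step_fixed_activity(
            nw.NetworkState(sigma=mem.patterns[0]), conn, 0.05, rng)
        assert state.sigma.sum() == 10

    def test_fixed_threshold_silences_at_high_theta(self, loaded_net):
        mem, conn, _ = loaded_net
        state = nw.NetworkState(sigma=mem.patterns[0])
        out = nw.step_fixed_threshold(state, conn, theta=1e6)
        assert out.sigma.sum() == 0


class TestOverlap:
    def test_self_overlap_is_one(self):
        mem = nw.generate_patterns(1, 500, 0.05, 0)
        xi = mem.patterns[0]
        assert nw.overlap(nw.NetworkState(sigma=xi), xi, 0.05) == \
            pytest.approx(1.0)

    def test_anticorrelated_state_negative(self):
        # hand-constructed 20-neuron example: active units moved entirely
        # off the pattern support
        xi = np.zeros(20, dtype=np.int8)
        xi[:5] = 1
        sigma = np.zeros(20, dtype=np.int8)
        sigma[5:10] = 1
        f = 0.25
        m = nw.overlap(nw.NetworkState(sigma=sigma), xi, f)
        # direct evaluation: f+ = 0/5, f- = 5/15
        assert m == pytest.approx(0.0 - 5.0 / 15.0)
        assert m < 0


class TestRetrievalAndBasin:
    def test_single_memory_is_retrievable(self):
        mem = nw.generate_patterns(1, 1000, 0.05, 1)
        conn = nw.build_connectivity(mem, np.array([1.0]))
        ok, m, _ = nw.test_retrieval(mem.patterns[0], conn)
        assert ok and m > 0.85

    def test_weak_memory_below_criticality_lost(self, loaded_net, basin):
        mem, conn, A = loaded_net
        N, f = mem.n_neurons, mem.f
        delta = np.sqrt((f / N) * np.sum(A ** 2))
        a_c = basin.a_f * delta
        # rebuild with one memory forced well under the critical efficacy
        A2 = A.copy()
        A2[0] = 0.5 * a_c
        conn2 = nw.build_connectivity(mem, A2)
        ok, m, _ = nw.test_retrieval(mem.patterns[0], conn2)
        assert not ok

    def test_dominant_memory_basin_near_one(self):
        mem = nw.generate_patterns(1, 1000, 0.05, 1)
        conn = nw.build_connectivity(mem, np.array([1.0]))
        b = nw.measure_basin_size(mem.patterns[0], conn, seed=2)
        assert b > 0.85

    def test_unstable_pattern_basin_zero(self, loaded_net, basin):
        mem, conn, A = loaded_net
        N, f = mem.n_neurons, mem.f
        delta = np.sqrt((f / N) * np.sum(A ** 2))
        A2 = A.copy()
        A2[1] = 0.3 * basin.a_f * delta
        conn2 = nw.build_connectivity(mem, A2)
        assert nw.measure_basin_size(mem.patterns[1], conn2, seed=3) == 0.0

    def test_basin_monotone_in_efficacy(self, basin):
        # raising one memory's efficacy (others fixed) cannot shrink its
        # basin beyond flip-sampling noise
        rng = np.random.default_rng(7)
        N, f, T = 2000, 0.01, 120
        mem = nw.generate_patterns(T, N, f, rng)
        A = np.full(T, 1.0)
        delta = np.sqrt((f / N) * np.sum(A ** 2))
        a_c = basin.a_f * delta
        sizes = []
        for x in (1.3, 2.5, 6.0):
            A2 = A.copy()
            A2[0] = x * a_c
            conn = nw.build_connectivity(mem, A2)
            sizes.append(nw.measure_basin_size(mem.patterns[0], conn,
                                               seed=5))
        assert sizes[0] <= sizes[1] + 0.1
        assert sizes[1] <= sizes[2] + 0.1
        assert sizes[2] > sizes[0]


class TestNetworkForgettingCurve:
    def test_all_zero_efficacies(self):
        with pytest.raises(ValueError):
            # everything below the floor: no patterns to build
            nw.network_forgetting_curve(np.zeros(10) + 1e-9,
                                        np.arange(10.0), 500, 0.02, 5.0)

    def test_pattern_cap_enforced(self):
        with pytest.raises(MemoryError):
            nw.network_forgetting_curve(np.ones(100), np.arange(100.0),
                                        500, 0.02, 5.0, max_patterns=50)
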