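"""Stochastic efficacy simulator: dynamics, noise bookkeeping, observables."""

import numpy as np
import pytest
from scipy import stats

import memcons as mc
from memcons.consolidation import EfficacyEnsemble, _cohort_bin_totals


class TestInterferenceNoise:
    def test_trivial_values(self):
        assert mc.interference_noise(np.zeros(5), 0.01, 100) == 0.0
        assert mc.interference_noise(np.array([1.0]), 0.01, 100) == \
            pytest.approx(0.01)

    def test_pure_forgetting_equilibrium_level(self, basin):
        # with no rehearsals the squared noise settles at ~ f tau / (2 N)
        cfg = mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.0, b=0.3,
                           T=200.0, n_realizations=1, seed=0)
        state = EfficacyEnsemble.empty()
        rng = np.random.default_rng(0)
        while state.time < cfg.total_time:
            state, _, _ = mc.simulate_step(state, cfg, basin, rng)
        expected = cfg.f * cfg.tau / (2 * cfg.N)
        assert state.delta ** 2 == pytest.approx(expected, rel=0.10)


class TestRehearsalRate:
    def test_below_and_at_threshold(self, basin):
        lam = 0.25
        assert mc.rehearsal_rate(0.2, 0.4, lam, basin) == 0.0
        assert mc.rehearsal_rate(0.4, 0.4, lam, basin) < 0.01 * lam

    def test_saturates_at_lambda(self, basin):
        lam = 0.25
        assert mc.rehearsal_rate(40.0, 0.4, lam, basin) == \
            pytest.approx(lam, rel=1e-6)

    def test_startup_limit_without_interference(self, basin):
        # before any noise exists every extant memory rehearses maximally
        assert mc.rehearsal_rate(0.5, 0.0, 0.25, basin) == 0.25
        assert mc.rehearsal_rate(0.0, 0.0, 0.25, basin) == 0.0


class TestStepDynamics:
    def test_pure_decay_is_exact(self, basin):
        cfg = mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.0, b=0.3,
                           T=100.0, n_realizations=1, seed=0)
        state = EfficacyEnsemble.empty()
        rng = np.random.default_rng(0)
        for _ in range(250):
            state, _, _ = mc.simulate_step(state, cfg, basin, rng)
        expected = np.exp(-(state.time - state.birth_times) / cfg.tau)
        assert np.max(np.abs(state.efficacies - expected)) < 1e-12

    def test_noise_conservation_incremental_vs_recomputed(self, basin):
        # maintain delta^2 incrementally outside the simulator and compare
        cfg = mc.SimConfig(N=500, f=0.02, tau=15.0, lam=0.2, b=0.3,
                           T=400.0, n_realizations=1, seed=7)
        state = EfficacyEnsemble.empty()
        rng = np.random.default_rng(7)
        shadow = 0.0
        scale = cfg.f / cfg.N
        dec2 = np.exp(-2 * cfg.step / cfg.tau)
        while state.time < cfg.total_time:
            prev = state.efficacies.copy()
            state, hits, births = mc.simulate_step(state, cfg, basin, rng)
            shadow *= dec2
            if hits.size:
                old = prev[hits] * np.exp(-cfg.step / cfg.tau)
                shadow += scale * float(np.sum((old + cfg.b) ** 2
                                               - old ** 2))
            if births.size:
                shadow += scale * float(
                    np.sum(state.efficacies[-births.size:] ** 2))
            assert state.delta ** 2 == pytest.approx(
                shadow, rel=1e-9, abs=1e-300)

    def test_rehearsal_counts_match_poisson_oracle(self, basin):
        # memories pinned far above threshold rehearse at the full rate
        # lam; windowed counts must match a homogeneous Poisson process
        lam, dt = 0.2, 0.05  # lam * dt = 0.01 per step
        cfg = mc.SimConfig(N=10 ** 12, f=0.01, tau=1e9, lam=lam, b=0.3,
                           dt=dt, T=800.0, n_realizations=1, seed=3)
        state = EfficacyEnsemble.empty()
        rng = np.random.default_rng(3)
        n_track, t_start, window = 100, 150.0, 25.0
        counts = {}
        while state.time < cfg.total_time:
            state, hits, _ = mc.simulate_step(state, cfg, basin, rng)
            if state.time > t_start and hits.size:
                gids = state.ids[hits]
                w = int((state.time - t_start) / window)
                for g in gids[gids < n_track]:
                    counts[(g, w)] = counts.get((g, w), 0) + 1
        n_windows = int((cfg.total_time - t_start) / window)
        obs = np.array([counts.get((g, w), 0) for g in range(n_track)
                        for w in range(n_windows)])
        assert obs.sum() > 10_000
        mean = lam * window
        kmax = int(stats.poisson.ppf(0.999, mean))
        edges = np.arange(kmax + 2)
        hist = np.array([(obs == k).sum() for k in edges[:-1]])
        hist[-1] += (obs > kmax).sum()
        pmf = stats.poisson.pmf(edges[:-1], mean)
        pmf[-1] += stats.poisson.sf(kmax, mean)
        keep = pmf * obs.size >= 5
        chi2, p = stats.chisquare(hist[keep],
                                  pmf[keep] / pmf[keep].sum() *
                                  hist[keep].sum())
        assert p > 0.01

    def test_insertion_schedule_one_per_unit_time(self, basin):
        cfg = mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.25, b=0.3,
                           T=50.0, n_realizations=1, seed=0)
        state = EfficacyEnsemble.empty()
        rng = np.random.default_rng(0)
        while state.time < cfg.total_time:
            state, _, _ = mc.simulate_step(state, cfg, basin, rng)
        assert state.n_total == int(np.floor(state.time)) + 1
        assert np.array_equal(np.sort(state.ids), np.arange(state.n_total))


class TestCohortBinTotals:
    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = rng.uniform(50, 200)
            first = rng.uniform(0, 40)
            n_total = int(np.floor(t)) + 1
            bw = rng.uniform(1.5, 12.0)
            n_bins = int(np.ceil(t / bw)) + 1
            got = _cohort_bin_totals(t, first, n_total, bw, n_bins)
            births = np.arange(int(np.ceil(first)), n_total)
            ages = t - births
            expected = np.histogram(
                ages, bins=np.arange(n_bins + 1) * bw)[0]
            assert np.array_equal(got[:len(expected)], expected)


class TestRunSimulation:
    def test_bitwise_determinism(self, small_cfg, basin):
        r1 = mc.run_simulation(small_cfg, basin)
        r2 = mc.run_simulation(small_cfg, basin)
        assert np.array_equal(r1.a_c_mean, r2.a_c_mean)
        assert np.array_equal(r1.curve.n_samples, r2.curve.n_samples)
        nz = np.nan_to_num(r1.curve.retrieval_prob)
        assert np.array_equal(nz, np.nan_to_num(r2.curve.retrieval_prob))
        assert r1.summary.capacity == r2.summary.capacity

    def test_equilibrates_and_reports(self, small_run):
        assert small_run.equilibrated
        assert np.all(np.isfinite(small_run.t_equilibrium))
        s = small_run.summary
        assert s.capacity > 0
        assert 0.0 <= s.p_c <= 1.0
        assert s.a_fp > s.a_c_eq > 0

    def test_forgetting_curve_monotone_within_noise(self, small_run):
        c = small_run.curve
        ok = np.isfinite(c.retrieval_prob) & (c.n_samples >= 200)
        p, n = c.retrieval_prob[ok], c.n_samples[ok]
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        # nonincreasing up to 3 binomial standard errors per bin
        viol = p[1:] - p[:-1] - 3 * (se[1:] + se[:-1])
        assert np.all(viol <= 0)

    def test_young_memories_retrievable(self, small_run):
        c = small_run.curve
        assert c.retrieval_prob[0] > 0.9

    def test_histogram_has_two_modes(self, small_run):
        h = small_run.histogram
        s = small_run.summary
        mode = h.consolidated_mode(s.a_c_eq)
        assert mode == pytest.approx(s.a_fp, rel=0.35)
        slope = h.sub_critical_slope(s.a_c_eq)
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_pure_forgetting_histogram_single_branch(self, basin):
        cfg = mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.0, b=0.3,
                           T=1500.0, n_realizations=1, seed=5)
        res = mc.run_simulation(cfg, basin)
        slope = res.histogram.sub_critical_slope(res.summary.a_c_eq)
        assert slope == pytest.approx(-1.0, abs=0.2)
        # nothing consolidates without rehearsals
        assert res.summary.a_fp == 0.0

    def test_pure_forgetting_step_curve(self, basin):
        cfg = mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.0, b=0.3,
                           T=1500.0, n_realizations=1, seed=5)
        res = mc.run_simulation(cfg, basin)
        _, t0 = mc.pure_forgetting_analytics(cfg.N, cfg.f, cfg.tau,
                                             basin.a_f)
        c = res.curve
        ages_t = c.age_bins * cfg.tau
        ok = np.isfinite(c.retrieval_prob) & (c.n_samples > 0)
        young = ok & (ages_t < t0 - cfg.tau)
        old = ok & (ages_t > t0 + cfg.tau)
        assert np.all(c.retrieval_prob[young] > 0.98)
        assert np.all(c.retrieval_prob[old] < 0.02)
        ct = mc.consolidation_time(c)
        assert ct.pure_forgetting

    def test_exponential_a0_distribution(self, basin):
        cfg = mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.25, b=0.3,
                           T=1500.0, n_realizations=1, seed=9,
                           A0_dist=("exponential", 1.0))
        res = mc.run_simulation(cfg, basin)
        a0 = res.records["A0"].to_numpy()
        assert a0.mean() == pytest.approx(1.0, rel=0.15)
        assert (a0 > 2.0).mean() > 0.05  # genuinely spread out


class TestFixedPointAndAnalytics:
    def test_efficacy_fixed_point_regimes(self, basin):
        # weak drive below threshold leaves only the zero solution
        assert mc.efficacy_fixed_point(2.0, 0.3, 5 / 160, 160, basin) == 0.0
        # saturated drive lands just under b lam tau
        a = mc.efficacy_fixed_point(0.05, 0.3, 5 / 160, 160, basin)
        assert a == pytest.approx(1.5, rel=0.05)
        # no interference: the ceiling itself
        assert mc.efficacy_fixed_point(0.0, 0.3, 5 / 160, 160, basin) == \
            pytest.approx(1.5)

    def test_pure_forgetting_analytics_limits(self):
        tau0, t0 = mc.pure_forgetting_analytics(8000, 0.01, 2240, 4.65)
        assert tau0 == pytest.approx(2 * 8000 / (0.01 * 4.65 ** 2))
        assert t0 > 0
        # at tau = tau0 nothing is retrievable
        _, t0b = mc.pure_forgetting_analytics(8000, 0.01, tau0, 4.65)
        assert t0b == 0.0

    def test_capacity_approximation_exponent(self):
        approx = mc.capacity_approximation(8000, 0.01, 160, 5 / 160, 0.3,
                                           4.65, 1.0, 20.0)
        assert approx.n_scaling_exponent == pytest.approx(5 / 7)
        huge = mc.capacity_approximation(8000, 0.01, 160, 1000 / 160,
                                         0.3, 4.65, 1.0, 20.0)
        assert huge.n_scaling_exponent > 0.99

    def test_consolidation_probability_cohorts(self, basin):
        # half the memories encoded below the critical efficacy never
        # consolidate; the strong cohort is barely affected
        cfg = mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.25, b=0.3,
                           T=2000.0, n_realizations=2, seed=21,
                           A0_dist=("bernoulli", 0.05))
        res = mc.run_simulation(cfg, basin)
        s = res.summary
        weak = mc.consolidation_probability(res.records, s.a_fp, s.a_c_eq,
                                            cohort_a0=0.05)
        strong = mc.consolidation_probability(res.records, s.a_fp,
                                              s.a_c_eq, cohort_a0=1.0)
        assert weak < 0.02
        assert strong > 0.7


class TestConfigValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            mc.SimConfig(b=1.5)
        with pytest.raises(ValueError):
            mc.SimConfig(tau=-1.0)
        with pytest.raises(ValueError):
            mc.SimConfig(lam=1.0, dt=0.5)  # dt*lam > 0.1
        with pytest.raises(ValueError):
            mc.SimConfig(A0_dist=("uniform", 1.0))

    def test_default_step_and_duration(self):
        cfg = mc.SimConfig(tau=160.0, lam=5 / 160)
        assert cfg.step == pytest.approx(0.05 / cfg.lam)
        assert cfg.total_time == pytest.approx(400 * 160.0)
        assert cfg.lam_tau == pytest.approx(5.0)
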