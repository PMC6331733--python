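"""Markov state model construction, kinetics and validation."""

import warnings

import numpy as np
import pytest

import unbindkin as uk
from unbindkin import msm

KBT = 0.59616


def sample_chain(T, n_steps, seed, start=0):
    """Discrete trajectory from a transition matrix."""
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    out = np.empty(n_steps, dtype=int)
    s = start
    cum = np.cumsum(T, axis=1)
    u = rng.random(n_steps)
    for i in range(n_steps):
        s = int(np.searchsorted(cum[s], u[i]))
        out[i] = s
    return out


def chain_to_series(dtraj, levels=(3.0, 8.0, 24.0), jitter=0.05, seed=0):
    rng = np.random.default_rng(seed)
    return np.asarray(levels)[dtraj] + jitter * rng.standard_normal(dtraj.size)


@pytest.fixture(scope="module")
def three_state_data():
    T = np.array([[0.95, 0.05, 0.0],
                  [0.10, 0.80, 0.10],
                  [0.0, 0.05, 0.95]])
    dtrajs = [sample_chain(T, 20_000, seed=s, start=s % 3) for s in range(5)]
    series = [chain_to_series(d, seed=s) for s, d in enumerate(dtrajs)]
    ens = msm.FeaturizedEnsemble(series, frame_interval=1.0, min_length_ns=0)
    cl = msm.cluster(ens, n_clusters=3, seed=0)
    return T, ens, cl


class TestCluster:
    def test_two_point_masses(self):
        ens = msm.FeaturizedEnsemble([np.array([1.0] * 500 + [9.0] * 500)],
                                     frame_interval=1.0, min_length_ns=0)
        cl = msm.cluster(ens, n_clusters=2, seed=0)
        assert np.allclose(np.sort(cl.centers), [1.0, 9.0], atol=1e-6)

    def test_single_cluster_is_mean(self):
        data = np.linspace(0, 10, 1000)
        ens = msm.FeaturizedEnsemble([data], frame_interval=1.0,
                                     min_length_ns=0)
        cl = msm.cluster(ens, n_clusters=1, seed=0)
        # mini-batch updates leave a small stochastic residual around the mean
        assert cl.centers[0] == pytest.approx(data.mean(), rel=0.02)

    def test_minibatch_close_to_full_batch(self, dw_swarm):
        """Mini-batch inertia within 5% of full-batch k-means."""
        from sklearn.cluster import KMeans
        data = np.concatenate(dw_swarm.series).reshape(-1, 1)
        cl = msm.cluster(dw_swarm, n_clusters=50, seed=0)
        d = np.abs(data - cl.centers[None, :])
        inertia_mb = float((d.min(axis=1) ** 2).sum())
        km = KMeans(n_clusters=50, random_state=0, n_init=3).fit(data)
        assert inertia_mb <= 1.05 * km.inertia_

    def test_short_trajectories_filtered(self):
        ens = msm.FeaturizedEnsemble([np.zeros(5), np.zeros(4000)],
                                     frame_interval=0.01, min_length_ns=20.0)
        assert len(ens) == 1 and ens.n_excluded == 1


class TestTransitionMatrix:
    def test_alternating_two_state(self):
        series = [np.array([1.0, 9.0] * 50)]
        ens = msm.FeaturizedEnsemble(series, frame_interval=1.0,
                                     min_length_ns=0)
        cl = msm.cluster(ens, n_clusters=2, seed=0)
        m = msm.estimate_transition_matrix(ens, cl, lag=1.0, mode="mle")
        assert np.allclose(m.transition_matrix, [[0, 1], [1, 0]], atol=1e-12)

    def test_generative_recovery(self, three_state_data):
        T, ens, cl = three_state_data
        m = msm.estimate_transition_matrix(ens, cl, lag=1.0, mode="mle")
        assert np.abs(m.transition_matrix - T).max() < 0.02

    def test_lag_two_approximates_squared_matrix(self, three_state_data):
        T, ens, cl = three_state_data
        m2 = msm.estimate_transition_matrix(ens, cl, lag=2.0, mode="mle")
        assert np.abs(m2.transition_matrix - T @ T).max() < 0.03

    def test_row_stochastic_and_stationary_fixed_point(self, dw_msm):
        T = dw_msm.transition_matrix
        pi = dw_msm.stationary
        assert np.abs(T.sum(axis=1) - 1.0).max() < 1e-10
        assert np.abs(pi @ T - pi).max() < 1e-10
        assert np.all(dw_msm.count_matrix >= 0)


class TestMacrostates:
    def test_threshold_mapping(self, three_state_data):
        _, ens, cl = three_state_data
        m = msm.estimate_transition_matrix(ens, cl, lag=1.0)
        m = msm.define_macrostates(m, (5.0, 20.0))
        assert list(m.macrostates) == [0, 1, 2]

    def test_empty_macrostate_rejected(self, three_state_data):
        _, ens, cl = three_state_data
        m = msm.estimate_transition_matrix(ens, cl, lag=1.0)
        with pytest.raises(msm.MsmError):
            msm.define_macrostates(m, (0.1, 0.2))

    def test_inverted_boundaries_rejected(self, dw_msm):
        with pytest.raises(ValueError):
            msm.define_macrostates(dw_msm, (15.0, 5.0))


class TestMfpt:
    def test_two_state_closed_form(self):
        """T = [[1-a, a], [b, 1-b]] at lag D: MFPT(1->2) = D/a."""
        a, b, lag = 0.2, 0.4, 2.0
        dtraj = sample_chain(np.array([[1 - a, a], [b, 1 - b]]), 200_000,
                             seed=1)
        series = [chain_to_series(dtraj, levels=(3.0, 24.0), seed=1)]
        ens = msm.FeaturizedEnsemble(series, frame_interval=lag,
                                     min_length_ns=0)
        cl = msm.cluster(ens, n_clusters=2, seed=0)
        m = msm.estimate_transition_matrix(ens, cl, lag=lag, mode="mle")
        m.macrostates = np.array([0, 2])  # no tunnel state in a 2-state model
        with pytest.raises(msm.MsmError):
            msm.mfpt(m, 0, 1)  # empty target macrostate
        assert msm.mfpt(m, 0, 2) == pytest.approx(lag / a, rel=0.05)

    def test_immediate_absorption_equals_lag(self):
        m = msm.MarkovModel(lag_ns=3.0, frame_interval=1.0,
                            count_matrix=np.ones((2, 2)),
                            transition_matrix=np.array([[0.0, 1.0],
                                                        [0.5, 0.5]]),
                            stationary=np.array([1 / 3, 2 / 3]),
                            centers=np.array([3.0, 24.0]),
                            active=np.arange(2), dtrajs=[],
                            macrostates=np.array([0, 2]))
        assert msm.mfpt(m, 0, 2) == pytest.approx(3.0)

    def test_against_simulation_oracle(self):
        """Linear-system MFPT on a symmetric random walk vs brute-force
        first-passage counting (3 sigma of the simulation error)."""
        T = np.array([[0.8, 0.2, 0.0],
                      [0.2, 0.6, 0.2],
                      [0.0, 0.2, 0.8]])
        m = msm.MarkovModel(lag_ns=1.0, frame_interval=1.0,
                            count_matrix=np.ones((3, 3)),
                            transition_matrix=T,
                            stationary=msm._stationary(T),
                            centers=np.array([3.0, 12.0, 24.0]),
                            active=np.arange(3), dtrajs=[],
                            macrostates=np.array([0, 1, 2]))
        got = msm.mfpt(m, 0, 2)
        dtraj = sample_chain(T, 400_000, seed=9, start=0)
        fpts, t0, state = [], 0, 0
        for i, s in enumerate(dtraj):
            if state != 2 and s == 2:
                fpts.append(i - t0)
                state = 2
            elif state == 2 and s == 0:
                t0 = i
                state = 0
        fpts = np.array(fpts[1:], dtype=float)
        se = fpts.std() / np.sqrt(len(fpts))
        assert abs(got - fpts.mean()) < 3 * se


class TestKinetics:
    def test_affinity_identity(self, dw_msm):
        est = msm.kinetics(dw_msm, concentration=0.05)
        assert est.koff_over_kon * est.k_on == pytest.approx(est.k_off,
                                                             rel=1e-12)

    def test_designed_population_ratio_gives_dg(self):
        """pi_bound/pi_unbound = e^2 by construction => dG = -2 kBT."""
        p_u = 1.0 / (1.0 + np.e**2)
        pi = np.array([1 - p_u, p_u])
        a = 0.01
        b = a * pi[0] / pi[1]
        m = msm.MarkovModel(lag_ns=1.0, frame_interval=1.0,
                            count_matrix=np.ones((2, 2)),
                            transition_matrix=np.array([[1 - a, a],
                                                        [b, 1 - b]]),
                            stationary=pi, centers=np.array([3.0, 24.0]),
                            active=np.arange(2), dtrajs=[],
                            macrostates=np.array([0, 2]))
        est = msm.kinetics(m, concentration=1.0)
        from unbindkin.units import kbt
        assert est.dG == pytest.approx(-2 * kbt(300.0), rel=1e-9)

    def test_missing_concentration_rejected(self, dw_msm):
        with pytest.raises(ValueError):
            msm.kinetics(dw_msm, concentration=0.0)

    def test_koff_within_factor_three_of_oracle(self, doublewell, dw_msm):
        est = msm.kinetics(dw_msm, concentration=0.05)
        oracle_ns = uk.mfpt_oracle_1d(doublewell, 8.0, 20.0) / 1000.0
        assert oracle_ns / 3 < est.tau_off < 3 * oracle_ns


class TestChapmanKolmogorov:
    def test_markovian_data_small_deviation(self, three_state_data):
        _, ens, cl = three_state_data
        m = msm.estimate_transition_matrix(ens, cl, lag=1.0, mode="mle")
        m = msm.define_macrostates(m, (5.0, 20.0))
        ck = msm.chapman_kolmogorov(m, (1, 2, 3, 4, 5))
        for curves in ck.values():
            assert max(curves["deviation"]) < 0.02

    def test_k_equal_one_is_exact_for_mle(self, three_state_data):
        _, ens, cl = three_state_data
        m = msm.estimate_transition_matrix(ens, cl, lag=1.0, mode="mle")
        m = msm.define_macrostates(m, (5.0, 20.0))
        ck = msm.chapman_kolmogorov(m, (1,))
        for curves in ck.values():
            assert curves["deviation"][0] < 1e-12

    def test_long_memory_data_fails(self):
        """Strongly non-Markovian series (regime switching slower than any
        microstate dynamics) shows large CK deviations."""
        rng = np.random.default_rng(2)
        blocks = []
        levels = [3.0, 13.0, 24.0]
        level = 3.0
        for _ in range(400):
            # heavy-tailed dwell times create long memory at the frame scale
            dwell = int(rng.pareto(0.8) * 20) + 5
            blocks.append(np.full(dwell, level)
                          + 0.4 * rng.standard_normal(dwell))
            level = rng.choice([v for v in levels if v != level])
        series = np.concatenate(blocks)
        ens = msm.FeaturizedEnsemble([series], frame_interval=1.0,
                                     min_length_ns=0)
        cl = msm.cluster(ens, n_clusters=20, seed=0)
        m = msm.estimate_transition_matrix(ens, cl, lag=1.0)
        m = msm.define_macrostates(m, (10.0, 18.0))
        ck = msm.chapman_kolmogorov(m, (30, 100))
        worst = max(max(c["deviation"]) for c in ck.values())
        assert worst > 0.1


class TestBootstrap:
    def test_identical_trajectories_zero_sd(self):
        base = np.concatenate([np.full(300, 3.0), np.full(300, 12.0),
                               np.full(300, 24.0)] * 3)
        rng = np.random.default_rng(0)
        noisy = base + 0.01 * rng.standard_normal(base.size)
        ens = msm.FeaturizedEnsemble([noisy.copy() for _ in range(6)],
                                     frame_interval=1.0, min_length_ns=0)
        cl = msm.cluster(ens, n_clusters=3, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sds = msm.bootstrap_msm(ens, cl, concentration=1.0, lag=1.0,
                                    boundaries=(5.0, 20.0), n_boot=20, seed=3)
        assert sds["k_off"] == pytest.approx(0.0, abs=1e-9)

    def test_seed_reproducibility(self, dw_swarm):
        cl = msm.cluster(dw_swarm, n_clusters=50, seed=1)
        kw = dict(concentration=0.05, lag=0.02, boundaries=(10.0, 19.5),
                  n_boot=15, seed=8)
        a = msm.bootstrap_msm(dw_swarm, cl, **kw)
        b = msm.bootstrap_msm(dw_swarm, cl, **kw)
        assert a == b
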