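import numpy as np
import pytest

import driftlab as dl
from driftlab.drift import initial_partition_labels
from driftlab.network import ENGAGED, INACTIVE, SATURATED


def brute_force_gamma(cur, delta, alpha):
    """Independent oracle: line search over a gamma grid refined to 1e-6.

    Walks gamma upward from 0 and stops at the first grid point where any
    current leaves [0, alpha]; a second pass refines the last admissible
    coarse point at 1e-6 resolution.
    """
    g0 = 0.0
    for step in (1e-3, 1e-6):
        gs = g0 + np.arange(0, 1002) * step
        gs = gs[gs <= 1.0 + 1e-15]
        v = cur[None, :] + gs[:, None] * delta[None, :]
        ok = np.all((v >= -1e-12) & (v <= alpha + 1e-12), axis=1)
        bad = np.flatnonzero(~ok)
        g0 = gs[-1] if bad.size == 0 else gs[max(bad[0] - 1, 0)]
    return min(g0, 1.0)


class TestRescaleToThreshold:
    def test_single_crosser_lands_exactly_at_zero(self):
        gamma, lo, hi = dl.rescale_to_threshold(
            np.array([2.0, 2.0]), np.array([-3.0, 3.0]), np.zeros(2), 5.0
        )
        assert gamma == pytest.approx(2 / 3, abs=1e-12)
        assert list(lo) == [0] and list(hi) == []

    def test_interior_step_is_unscaled(self):
        gamma, lo, hi = dl.rescale_to_threshold(
            np.array([2.0, 3.0]), np.array([0.5, -0.5]), np.zeros(2), 5.0
        )
        assert gamma == 1.0 and lo.size == 0 and hi.size == 0

    def test_simultaneous_ties_all_transition(self):
        # both neurons reach a bound exactly at gamma = 1
        gamma, lo, hi = dl.rescale_to_threshold(
            np.array([2.0, 3.0]), np.array([-2.0, 2.0]), np.zeros(2), 5.0
        )
        assert gamma == 1.0
        assert list(lo) == [0] and list(hi) == [1]

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 8)
            cur = rng.uniform(0.0, 5.0, n)
            delta = rng.normal(0, 2.0, n)
            gamma, lo, hi = dl.rescale_to_threshold(cur, delta, np.zeros(n), 5.0)
            expected = brute_force_gamma(cur, delta, 5.0)
            assert gamma == pytest.approx(expected, abs=2e-6)
            out = cur + gamma * delta
            assert np.all(out >= -1e-12) and np.all(out <= 5.0 + 1e-12)
            for p in lo:
                assert out[p] == pytest.approx(0.0, abs=1e-12)
            for p in hi:
                assert out[p] == pytest.approx(5.0, abs=1e-12)


class TestDriftStep:
    def _toy_state(self, toy):
        cfg, task, frame = toy
        eta = np.array([[2.0, 0.3], [2.0, -0.4]])
        return cfg, task, dl.EtaState(eta=eta, frame=frame, learned={0})

    def test_toy_stays_on_solution_line(self, toy):
        cfg, task, state = self._toy_state(toy)
        labels = initial_partition_labels(state, cfg.alpha)
        dcfg = dl.DriftConfig(sigma=0.3, n_steps=1)
        rng = np.random.default_rng(0)
        for _ in range(200):
            state, labels, rec = dl.drift_step(
                state, labels, task, dcfg, rng, alpha=cfg.alpha
            )
            y = dl.phi(state.eta[:, 0], cfg.alpha)
            assert task.W @ y == pytest.approx(4.0, abs=1e-10)

    def test_inactive_crossing_clamps_to_threshold_and_engages(self, toy):
        cfg, task, frame = toy
        # neuron 0 inactive just below threshold: any positive proposal crosses
        eta = np.array([[-1e-9, 0.0], [2.0, 0.0]])
        state = dl.EtaState(eta=eta, frame=frame, learned={0})
        labels = initial_partition_labels(state, cfg.alpha)
        assert labels[0, 0] == INACTIVE
        dcfg = dl.DriftConfig(sigma=1.0, n_steps=1)
        rng = np.random.default_rng(1)
        for _ in range(50):
            state, labels, rec = dl.drift_step(
                state, labels, task, dcfg, rng, alpha=cfg.alpha
            )
            if any(t[:2] == (0, 0) and t[2] == INACTIVE for t in rec.transitions):
                assert state.eta[0, 0] == 0.0  # exactly at -b
                assert labels[0, 0] == ENGAGED
                break
        else:
            pytest.fail("no threshold crossing observed in 50 sigma=1 steps")

    def test_empty_kernel_freezes_engaged_block(self, toy):
        cfg, task, frame = toy
        # one engaged neuron, Nz=1: kernel is zero-dimensional
        eta = np.array([[4.0, 0.0], [-3.0, 0.0]])
        state = dl.EtaState(eta=eta, frame=frame, learned={0})
        labels = initial_partition_labels(state, cfg.alpha)
        assert labels[0, 0] == ENGAGED and labels[1, 0] == INACTIVE
        dcfg = dl.DriftConfig(sigma=0.01, n_steps=1)
        state2, labels2, _ = dl.drift_step(
            state, labels, task, dcfg, np.random.default_rng(2), alpha=cfg.alpha
        )
        assert state2.eta[0, 0] == 4.0

    def test_unlearned_condition_columns_drift_freely(self, toy):
        cfg, task, state = self._toy_state(toy)
        labels = initial_partition_labels(state, cfg.alpha)
        dcfg = dl.DriftConfig(sigma=0.3, n_steps=1, constrained=frozenset({0}))
        before = state.eta[:, 1].copy()
        state2, _, _ = dl.drift_step(
            state, labels, task, dcfg, np.random.default_rng(3), alpha=cfg.alpha
        )
        assert np.all(state2.eta[:, 1] != before)


class TestNormBound:
    def test_within_bound_accepted(self, toy):
        _, _, frame = toy
        prev = dl.EtaState(eta=np.zeros((2, 2)), frame=frame)
        cand = dl.EtaState(eta=np.full((2, 2), 0.1), frame=frame)
        out = dl.enforce_norm_bound(cand, prev, frame, Umax=100.0)
        np.testing.assert_array_equal(out.eta, cand.eta)

    def test_offending_row_reverted_others_kept(self, toy):
        _, _, frame = toy
        prev = dl.EtaState(eta=np.zeros((2, 2)), frame=frame)
        cand_eta = np.array([[50.0, 50.0], [0.1, 0.1]])
        cand = dl.EtaState(eta=cand_eta, frame=frame)
        norms = np.linalg.norm(cand_eta @ frame.Xinv, axis=1)
        Umax = float(norms[0] / 1.01)  # row 0 at 1.01 x bound
        assert norms[1] < Umax
        out = dl.enforce_norm_bound(cand, prev, frame, Umax=Umax)
        np.testing.assert_array_equal(out.eta[0], prev.eta[0])
        np.testing.assert_array_equal(out.eta[1], cand.eta[1])

    def test_unbounded_is_identity(self, toy):
        _, _, frame = toy
        prev = dl.EtaState(eta=np.zeros((2, 2)), frame=frame)
        cand = dl.EtaState(eta=np.full((2, 2), 1e6), frame=frame)
        out = dl.enforce_norm_bound(cand, prev, frame, Umax=None)
        np.testing.assert_array_equal(out.eta, cand.eta)

    def test_bound_respected_along_run(self, methods_task, methods_net, learned_state):
        dcfg = dl.DriftConfig(sigma=0.05, Umax=10.0, n_steps=2000, record_every=100, seed=5)
        traj = dl.run_drift(learned_state, methods_task, dcfg, alpha=methods_net.alpha)
        start_ok = traj.row_norms[0] <= 10.0
        # rows that started inside the bound must stay inside it
        assert np.all(traj.row_norms[:, start_ok] <= 10.0 + 1e-9)
        assert traj.conservation.max() <= 1e-6 * max(1.0, np.abs(methods_task.Z).max())


class TestRunDrift:
    def test_zero_steps_returns_input_snapshot(self, methods_task, methods_net, learned_state):
        dcfg = dl.DriftConfig(n_steps=0)
        traj = dl.run_drift(learned_state, methods_task, dcfg, alpha=methods_net.alpha)
        assert traj.times.tolist() == [0]
        np.testing.assert_array_equal(traj.eta_snapshots[0], learned_state.eta)

    def test_set_consistency_after_steps(self, methods_task, methods_net, learned_state):
        dcfg = dl.DriftConfig(sigma=0.05, n_steps=500, record_every=500, seed=6)
        traj = dl.run_drift(learned_state, methods_task, dcfg, alpha=methods_net.alpha)
        eta = traj.eta_snapshots[-1]
        cur = eta[:, list(traj.constrained)]
        state = dl.EtaState(eta=eta, frame=learned_state.frame, learned=learned_state.learned)
        labels = initial_partition_labels(state, methods_net.alpha)[:, list(traj.constrained)]
        # currents must lie on the correct side of the thresholds for each label
        assert np.all(cur[labels == INACTIVE] <= 0.0)
        assert np.all(cur[labels == SATURATED] >= methods_net.alpha)
        assert np.all(
            (cur[labels == ENGAGED] > 0.0) & (cur[labels == ENGAGED] < methods_net.alpha)
        )

    def test_fractions_sum_to_one_at_every_record(
        self, methods_task, methods_net, learned_state
    ):
        dcfg = dl.DriftConfig(sigma=0.05, n_steps=300, record_every=50, seed=7)
        traj = dl.run_drift(learned_state, methods_task, dcfg, alpha=methods_net.alpha)
        np.testing.assert_allclose(traj.engagement_fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_equal_variance_contract_during_drift(
        self, methods_task, methods_net, learned_state
    ):
        dcfg = dl.DriftConfig(sigma=0.05, Umax=350.0, n_steps=2000, record_every=500, seed=8)
        traj = dl.run_drift(
            learned_state, methods_task, dcfg, alpha=methods_net.alpha, track_dU=True
        )
        s, _, n = traj.dU_stats
        assert abs(s / n) < 0.05 * 0.25  # near zero mean
        assert traj.dU_pooled_sd == pytest.approx(0.05, rel=0.25)

    def test_reproducible_given_seed(self, methods_task, methods_net, learned_state):
        dcfg = dl.DriftConfig(sigma=0.05, n_steps=200, record_every=100, seed=9)
        a = dl.run_drift(learned_state, methods_task, dcfg, alpha=methods_net.alpha)
        b = dl.run_drift(learned_state, methods_task, dcfg, alpha=methods_net.alpha)
        np.testing.assert_array_equal(a.eta_snapshots, b.eta_snapshots)
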