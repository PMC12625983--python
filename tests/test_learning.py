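import numpy as np
import pytest

import driftlab as dl
from driftlab.learning import LearnConfig, learnability_protocol
from driftlab.network import ENGAGED


def numeric_gradient(f, x, h=1e-6):
    """Central finite differences, the independent oracle for the analytic gradients."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        g[idx] = (f(xp) - f(xm)) / (2 * h)
    return g


class TestAllocate:
    def test_allocated_column_centers_in_engaged_regime(self, methods_task):
        frame = dl.build_extended_basis(methods_task.X)
        state = dl.EtaState(eta=np.zeros((12, 15)), frame=frame)
        lc = LearnConfig()
        out = dl.allocate(state, 2, lc, np.random.default_rng(0), alpha=5.0)
        assert np.all(np.abs(out.eta[:, 2] - 2.5) < 1.0)  # ~N(2.5, 0.1)
        assert np.std(out.eta[:, 2]) < 0.5

    def test_other_columns_bitwise_unchanged(self, methods_task):
        frame = dl.build_extended_basis(methods_task.X)
        eta0 = np.random.default_rng(1).normal(0, 3, (12, 15))
        state = dl.EtaState(eta=eta0.copy(), frame=frame)
        out = dl.allocate(state, 4, LearnConfig(), np.random.default_rng(2), alpha=5.0)
        mask = np.ones(15, dtype=bool)
        mask[4] = False
        np.testing.assert_array_equal(out.eta[:, mask], eta0[:, mask])

    def test_allocation_makes_column_fully_engaged(self, methods_task, methods_net):
        frame = dl.build_extended_basis(methods_task.X)
        state = dl.EtaState(eta=np.random.default_rng(3).normal(0, 40, (12, 15)), frame=frame)
        out = dl.allocate(state, 0, LearnConfig(), np.random.default_rng(4), alpha=5.0)
        labels = dl.initial_partition_labels(out, methods_net.alpha)
        assert np.all(labels[:, 0] == ENGAGED)


class TestGradients:
    def test_U_gradient_matches_finite_differences(self, methods_net):
        # small-scale instance with every current in the linear regime
        rng = np.random.default_rng(5)
        cfg = dl.NetworkConfig(Nx=4, Ny=3, Nz=1, P=2, alpha=5.0)
        X = rng.normal(0, 0.3, (4, 2))
        W = rng.normal(0, 1, (1, 3))
        Z = rng.normal(0, 1, (1, 2))
        task = dl.TaskSpec(X=X, W=W, Z=Z)
        # weights chosen so every current sits strictly inside the linear regime
        C_target = rng.uniform(1.0, 4.0, (3, 2))
        U = C_target @ np.linalg.pinv(X)
        from driftlab.learning import _loss_and_grad_U

        def loss(Umat):
            C = Umat @ X
            return float(np.sum((W @ dl.phi(C, 5.0) - Z) ** 2))

        _, grad, _ = _loss_and_grad_U(U, np.zeros(3), task, [0, 1], 5.0)
        num = numeric_gradient(loss, U)
        assert np.max(np.abs(grad - num)) / max(np.max(np.abs(num)), 1e-12) < 1e-6

    def test_eta_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        W = rng.normal(0, 1, (1, 6))
        z = np.array([1.3])
        col = rng.uniform(1.0, 4.0, 6)  # interior currents

        def loss(c):
            return float(np.sum((W @ dl.phi(c, 5.0) - z) ** 2))

        err = W @ dl.phi(col, 5.0) - z
        grad = 2.0 * (W.T @ err) * dl.phi_derivative(col, 5.0)
        num = numeric_gradient(loss, col)
        assert np.max(np.abs(grad - num)) / np.max(np.abs(num)) < 1e-6


class TestLearnU:
    def test_zero_error_leaves_weights_unchanged(self, methods_net, methods_task):
        # start exactly at the teacher's weights: zero loss, zero gradient
        ws = dl.WeightState(U=methods_task.T.copy())
        out, rep = dl.learn_gd_U(ws, methods_task, list(range(8)), LearnConfig(), alpha=5.0)
        assert rep.converged and rep.steps_used == 0
        np.testing.assert_array_equal(out.U, methods_task.T)

    def test_fully_disengaged_condition_cannot_learn(self, methods_net, methods_task):
        # huge weights: every neuron saturated or silent, gradient identically zero
        ws = dl.WeightState(U=np.random.default_rng(7).normal(0, 100, (12, 15)))
        out, rep = dl.learn_gd_U(
            ws, methods_task, [0], LearnConfig(max_steps=50), alpha=5.0
        )
        if not rep.converged:  # target met by chance is astronomically unlikely
            np.testing.assert_array_equal(out.U, ws.U)
        assert not rep.converged

    def test_methods_scale_adaptive_learning_converges(self, methods_net, methods_task):
        rng = np.random.default_rng(8)
        ws = dl.WeightState(U=rng.normal(0, 0.1, (12, 15)))
        frame = dl.build_extended_basis(methods_task.X)
        state = dl.to_eta(ws.U, frame)
        lc = LearnConfig(optimizer="adaptive_gd")
        for mu in range(8):
            state = dl.allocate(state, mu, lc, rng, alpha=5.0)
        ws = dl.WeightState(U=dl.from_eta(state))
        out, rep = dl.learn_gd_U(ws, methods_task, list(range(8)), lc, alpha=5.0)
        assert rep.converged
        assert rep.final_rms <= rep.tol


class TestLearnEta:
    def test_toy_converges_from_allocation_point(self, toy):
        cfg, task, frame = toy
        state = dl.EtaState(eta=np.array([[4.0, 0.0], [4.0, 0.0]]), frame=frame)
        lc = LearnConfig(lr=0.01, max_steps=100_000, tol=1e-6)
        out, rep = dl.learn_gd_eta(state, task, 0, lc, alpha=cfg.alpha)
        assert rep.converged
        np.testing.assert_allclose(out.eta[:, 0], [2.0, 2.0], atol=1e-4)

    def test_locality_other_columns_exactly_zero_change(self, methods_task):
        frame = dl.build_extended_basis(methods_task.X)
        rng = np.random.default_rng(9)
        eta0 = rng.normal(0, 2, (12, 15))
        state = dl.EtaState(eta=eta0.copy(), frame=frame)
        state = dl.allocate(state, 3, LearnConfig(), rng, alpha=5.0)
        eta_before = state.eta.copy()
        out, _ = dl.learn_gd_eta(
            state, methods_task, 3, LearnConfig(optimizer="adaptive_gd"), alpha=5.0
        )
        mask = np.ones(15, dtype=bool)
        mask[3] = False
        assert np.max(np.abs(out.eta[:, mask] - eta_before[:, mask])) == 0.0

    def test_disengaged_start_is_a_local_optimum(self, toy):
        cfg, task, frame = toy
        state = dl.EtaState(eta=np.array([[-1.0, 0.0], [-1.0, 0.0]]), frame=frame)
        out, rep = dl.learn_gd_eta(state, task, 0, LearnConfig(max_steps=100), alpha=cfg.alpha)
        assert not rep.converged
        np.testing.assert_array_equal(out.eta[:, 0], [-1.0, -1.0])


class TestContinualEtaLearning:
    def test_sequential_eta_learning_is_interference_free(self, methods_net, methods_task):
        # adding all P mappings in eta-coordinates keeps every stored mapping at tol
        frame = dl.build_extended_basis(methods_task.X)
        rng = np.random.default_rng(10)
        state = dl.to_eta(rng.normal(0, 0.1, (12, 15)), frame)
        lc = LearnConfig(optimizer="adaptive_gd")
        for mu in range(8):
            state = dl.allocate(state, mu, lc, rng, alpha=5.0)
            state, rep = dl.learn_gd_eta(state, methods_task, mu, lc, alpha=5.0)
            assert rep.converged
        cur = state.eta[:, :8]
        err = methods_task.W @ dl.phi(cur, 5.0) - methods_task.Z
        rms_z = np.sqrt(np.mean(methods_task.Z**2))
        assert np.sqrt(np.mean(err**2)) <= 1e-3 * rms_z

    def test_toy_full_sequence_hits_both_targets(self):
        t = dl.toy_fig4()
        np.testing.assert_allclose(t["final_readouts"], [4.0, 2.0], atol=1e-3)
        assert t["col1_max_change_during_learn2"] == 0.0


class TestLearnabilityProtocol:
    def test_empty_grid_rejected(self, methods_net):
        with pytest.raises(ValueError):
            learnability_protocol(methods_net, [], False, 1)

    def test_p_zero_equivalent_zero_mappings(self):
        # trivially, a one-condition protocol that fails immediately learns 0
        cfg = dl.NetworkConfig(Nx=4, Ny=3, Nz=1, P=1, alpha=5.0)
        rep = learnability_protocol(
            cfg, [500.0], False, 2, learn_cfg=LearnConfig(optimizer="adaptive_gd", max_steps=50)
        )
        assert rep.counts.shape == (1, 2)
        assert np.all(rep.counts >= 0)

    def test_small_vs_huge_init(self):
        cfg = dl.NetworkConfig(Nx=8, Ny=6, Nz=1, P=4, alpha=5.0)
        rep = learnability_protocol(cfg, [0.25, 50.0], False, 3, seed=2)
        assert rep.mean_counts[0] >= rep.mean_counts[1]
        assert rep.counts.min() >= 0 and rep.counts.max() <= 4
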