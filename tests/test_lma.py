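"""The Levenberg-Marquardt core: step mechanics, stopping, BPTT Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fingercount.lma import (FunctionModel, LMAConfig, LMAState,
                             bptt_jacobian, finite_difference_jacobian,
                             lma_step, train)
from fingercount.rnn import SequenceMemoryNet


def linear_model(A, b):
    """Residuals e = A x - b (Jacobian constant A)."""
    A = np.atleast_2d(np.asarray(A, float))
    b = np.atleast_1d(np.asarray(b, float))
    return FunctionModel(lambda x: A @ x - b, lambda x: A)


def reference_lm(residuals, jacobian, x, config, n_steps):
    """Textbook LM with the same mu schedule, written independently."""
    mu = config.mu_init
    path = [x.copy()]
    for _ in range(n_steps):
        e = residuals(x)
        J = jacobian(x)
        perf = np.mean(e ** 2)
        while True:
            dx = np.linalg.solve(J.T @ J + mu * np.eye(x.size), J.T @ e)
            cand = x - dx
            if np.mean(residuals(cand) ** 2) < perf:
                x = cand
                mu *= config.mu_decrease
                break
            mu *= config.mu_increase
            if mu > config.mu_max:
                return path
        path.append(x.copy())
    return path


class TestLmaStep:
    def test_linear_residual_converges(self):
        """e(x) = x - 3 from x=0: damped steps land on 3 within a few epochs."""
        model = linear_model([[1.0]], [3.0])
        state, trace = train(model, np.zeros(1))
        assert state.stop_reason == "grad_tol"
        assert state.epoch <= 5
        assert abs(state.params[0] - 3.0) < 1e-6

    def test_zero_residuals_keep_params(self):
        model = linear_model([[1.0]], [0.0])
        state, trace = train(model, np.zeros(1))
        assert state.perf == 0.0
        np.testing.assert_array_equal(state.params, np.zeros(1))
        assert trace == []

    def test_step_refuses_after_stop(self):
        model = linear_model([[1.0]], [3.0])
        state = LMAState(params=np.zeros(1), mu=1e-3, stop_reason="grad_tol")
        with pytest.raises(RuntimeError):
            lma_step(model, state, LMAConfig())

    def test_rosenbrock_matches_reference(self):
        """Same accepted-step trajectory as an independent textbook LM."""
        def res(x):
            return np.array([10 * (x[1] - x[0] ** 2), 1 - x[0]])

        def jac(x):
            return np.array([[-20 * x[0], 10.0], [-1.0, 0.0]])

        config = LMAConfig(max_epochs=30)
        x0 = np.array([-1.2, 1.0])
        expected = reference_lm(res, jac, x0.copy(), config, 30)
        state = LMAState(params=x0.copy(), mu=config.mu_init)
        model = FunctionModel(res, jac)
        state.perf = np.mean(res(x0) ** 2)
        for step_expected in expected[1:]:
            lma_step(model, state, config)
            np.testing.assert_allclose(state.params, step_expected, atol=1e-8)

    def test_mu_overflow_reported(self):
        """A residual that cannot decrease drives mu past its cap."""
        model = FunctionModel(lambda x: np.array([1.0]),
                              lambda x: np.array([[0.0]]))
        state = LMAState(params=np.zeros(1), mu=1e-3, perf=1.0)
        out = lma_step(model, state, LMAConfig())
        assert out.stop_reason == "mu_overflow"


class TestTrain:
    def test_max_epochs_cap(self):
        model = linear_model([[1.0]], [3.0])
        state, trace = train(model, np.zeros(1), LMAConfig(max_epochs=1))
        assert state.epoch == 1
        assert len(trace) == 1

    def test_quadratic_bowl_matches_normal_equations(self):
        """A x = b recovered to the direct least-squares solution."""
        rng = np.random.default_rng(42)
        while True:
            A = rng.normal(size=(5, 5))
            if np.linalg.cond(A) < 100:
                break
        b = rng.normal(size=5)
        state, _ = train(linear_model(A, b), np.zeros(5),
                         LMAConfig(max_epochs=100, grad_tol=1e-13))
        expected = np.linalg.lstsq(A, b, rcond=None)[0]
        np.testing.assert_allclose(state.params, expected, atol=1e-8)

    def test_nonfinite_init_rejected(self):
        with pytest.raises((ValueError, FloatingPointError)):
            train(linear_model([[1.0]], [3.0]), np.array([np.nan]))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_descent(self, seed):
        """Accepted-epoch performances are strictly decreasing."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 4))
        b = rng.normal(size=6)

        def res(x):  # mildly nonlinear residuals
            y = A @ x
            return y + 0.1 * y ** 2 - b

        def jac(x):
            return A + 0.2 * np.diag(A @ x) @ A

        state, trace = train(FunctionModel(res, jac), rng.normal(size=4),
                             LMAConfig(max_epochs=25))
        perfs = [t["perf"] for t in trace]
        assert all(p2 < p1 for p1, p2 in zip(perfs, perfs[1:]))

    def test_mu_schedule_discipline(self):
        """mu shrinks x0.1 on acceptance, grows x10 per rejection, caps at 1e10."""
        mus = []
        config = LMAConfig(max_epochs=15)

        def res(x):
            return np.array([np.exp(x[0]) - 2.0, x[0] ** 2])

        def jac(x):
            return np.array([[np.exp(x[0])], [2 * x[0]]])

        model = FunctionModel(res, jac)
        state = LMAState(params=np.array([3.0]), mu=config.mu_init)
        state.perf = np.mean(res(state.params) ** 2)
        for _ in range(10):
            mu_before = state.mu
            lma_step(model, state, config)
            if state.stop_reason is not None:
                break
            # mu_after = mu_before * 10^r * 0.1 for r >= 0 rejections
            ratio = state.mu / (mu_before * config.mu_decrease)
            r = np.log10(ratio)
            assert r >= -1e-9 and abs(r - round(r)) < 1e-9
            assert state.mu <= config.mu_max
            mus.append(state.mu)
        assert mus  # at least one accepted step observed


class TestLimitBehaviour:
    def test_small_mu_is_gauss_newton(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 3))
        b = rng.normal(size=6)
        x = rng.normal(size=3)
        e = A @ x - b
        gn = np.linalg.solve(A.T @ A, A.T @ e)
        damped = np.linalg.solve(A.T @ A + 1e-14 * np.eye(3), A.T @ e)
        np.testing.assert_allclose(damped, gn, rtol=1e-8)

    def test_large_mu_is_gradient_direction(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(6, 3))
        b = rng.normal(size=6)
        x = rng.normal(size=3)
        e = A @ x - b
        g = A.T @ e
        damped = np.linalg.solve(A.T @ A + 1e9 * np.eye(3), g)
        cos = damped @ g / (np.linalg.norm(damped) * np.linalg.norm(g))
        assert cos > 1 - 1e-6


class TestBpttJacobian:
    def test_single_unit_hand_derivation(self):
        """1 hidden unit, 1 step: y = w_out (w_in u + w_rec h0), chain rule."""
        net = SequenceMemoryNet(w_in=np.array([[0.3]]),
                                w_rec=np.array([[0.7]]),
                                w_out=np.array([[-1.1]]),
                                context0=np.zeros(1))
        u, h0 = 0.5, np.array([2.0])
        J = bptt_jacobian(net, np.array([[u]]), h0)
        expected = np.array([[-1.1 * u, -1.1 * h0[0],
                              0.3 * u + 0.7 * h0[0]]])
        np.testing.assert_allclose(J, expected, rtol=1e-12)

    def test_length_one_equals_feedforward(self):
        rng = np.random.default_rng(3)
        net = SequenceMemoryNet(w_in=rng.normal(size=(3, 2)),
                                w_rec=rng.normal(size=(3, 3)),
                                w_out=rng.normal(size=(2, 3)),
                                context0=np.zeros(2))
        u = rng.normal(size=(1, 2))
        h0 = rng.normal(size=3)
        J = bptt_jacobian(net, u, h0)

        def ff(params):
            net.set_params(params)
            h, y = net.step(h0, u[0])
            return y

        J_fd = finite_difference_jacobian(lambda p: ff(p), net.get_params())
        np.testing.assert_allclose(J, J_fd, atol=1e-7)

    def test_matches_finite_differences_through_time(self):
        """Random 3-hidden-unit net, 4-step sequence vs central differences."""
        rng = np.random.default_rng(4)
        net = SequenceMemoryNet(w_in=rng.uniform(-0.5, 0.5, (3, 2)),
                                w_rec=rng.uniform(-0.5, 0.5, (3, 3)),
                                w_out=rng.uniform(-0.5, 0.5, (2, 3)),
                                context0=np.zeros(2))
        seq = rng.uniform(-1, 1, (4, 2))
        h_start = np.ones(3)
        params = net.get_params()

        def rollout(p):
            net.set_params(p)
            h = h_start
            ys = []
            for u in seq:
                h, y = net.step(h, u)
                ys.append(y)
            return np.concatenate(ys)

        net.set_params(params)
        J = bptt_jacobian(net, seq, h_start)
        J_fd = finite_difference_jacobian(rollout, params)
        rel = np.abs(J - J_fd) / (np.abs(J_fd) + 1e-8)
        assert rel.max() < 1e-5

    def test_shape_mismatch_rejected(self):
        net = SequenceMemoryNet(w_in=np.zeros((2, 3)), w_rec=np.zeros((2, 2)),
                                w_out=np.zeros((3, 2)), context0=np.zeros(3))
        with pytest.raises(ValueError):
            bptt_jacobian(net, np.zeros((2, 4)), np.zeros(2))
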