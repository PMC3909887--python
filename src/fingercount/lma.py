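"""Levenberg-Marquardt least-squares trainer with a BPTT Jacobian for the RNNs.

All networks in the package (the recurrent sequence memories, the softmax
competitive classifier, the associative maps) are trained by the same damped
Gauss-Newton scheme.  The performance function is the mean of the squared
output errors, perf = mean(e^2).  Each candidate update solves

    (J^T J + mu I) dx = J^T e

where J holds the first derivatives of the residuals with respect to the flat
parameter vector.  With mu -> 0 this is the Gauss-Newton step; with mu large
it degenerates to a short gradient-descent step.  mu is multiplied by
``mu_decrease`` after every accepted step (reduction in perf) and by
``mu_increase`` after every rejected trial, so perf decreases at every
accepted iteration by construction.  Epochs count accepted steps only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import scipy.linalg

__all__ = [
    "LMAConfig",
    "LMAState",
    "ResidualModel",
    "FunctionModel",
    "lma_step",
    "train",
    "finite_difference_jacobian",
    "bptt_jacobian",
]


@dataclass
class LMAConfig:
    """Damping schedule and stopping rules.

    mu_init=1e-3, x10 on rejection, x0.1 on acceptance, cap 1e10; stop when
    the performance gradient falls below ``grad_tol`` (infinity norm of
    d perf / d params = (2/N) J^T e), after ``max_epochs`` accepted steps,
    when mu overflows, or optionally when perf reaches ``perf_goal``.
    """

    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    max_epochs: int = 1000
    perf_goal: float | None = None
    grad_norm: str = "inf"  # "inf" or "2"

    def __post_init__(self) -> None:
        if not (self.mu_init > 0 and self.mu_increase > 1
                and 0 < self.mu_decrease < 1 and self.mu_max > self.mu_init
                and self.grad_tol > 0 and self.max_epochs >= 1):
            raise ValueError("invalid LMA configuration")


class ResidualModel(Protocol):
    """Anything exposing residuals e(x) and their Jacobian de/dx."""

    def residuals(self, params: np.ndarray) -> np.ndarray: ...

    def jacobian(self, params: np.ndarray) -> np.ndarray: ...


@dataclass
class FunctionModel:
    """ResidualModel built from two callables (convenience for tests/toys)."""

    residuals_fn: Callable[[np.ndarray], np.ndarray]
    jacobian_fn: Callable[[np.ndarray], np.ndarray]

    def residuals(self, params: np.ndarray) -> np.ndarray:
        return np.asarray(self.residuals_fn(params), dtype=float)

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        return np.asarray(self.jacobian_fn(params), dtype=float)


@dataclass
class LMAState:
    """Mutable optimizer state: parameters, damping, counters, stop flag."""

    params: np.ndarray
    mu: float
    epoch: int = 0
    perf: float = np.inf
    grad_norm: float = np.inf
    stop_reason: str | None = None


def _perf(e: np.ndarray) -> float:
    return float(np.mean(e * e))


def _grad_norm(g: np.ndarray, kind: str) -> float:
    return float(np.max(np.abs(g)) if kind == "inf" else np.linalg.norm(g))


def _solve_damped(JtJ: np.ndarray, mu: float, Jte: np.ndarray) -> np.ndarray:
    A = JtJ + mu * np.eye(JtJ.shape[0])
    try:
        c, low = scipy.linalg.cho_factor(A)
        return scipy.linalg.cho_solve((c, low), Jte)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, Jte, rcond=1e-12)[0]
    except scipy.linalg.LinAlgError:
        return np.linalg.lstsq(A, Jte, rcond=1e-12)[0]


def lma_step(model: ResidualModel, state: LMAState, config: LMAConfig) -> LMAState:
    """One accepted LM iteration (retrying with larger mu on rejection).

    Mutates and returns ``state``.  Rejected trials inside the step raise mu
    but do not consume an epoch; mu exceeding ``mu_max`` sets
    ``stop_reason='mu_overflow'`` and leaves the parameters unchanged.
    """
    if state.stop_reason is not None:
        raise RuntimeError(f"optimizer already stopped ({state.stop_reason})")
    e = model.residuals(state.params)
    if not np.all(np.isfinite(e)):
        raise FloatingPointError("non-finite residuals")
    J = model.jacobian(state.params)
    perf = _perf(e)
    JtJ = J.T @ J
    Jte = J.T @ e
    state.perf = perf
    state.grad_norm = _grad_norm(2.0 * Jte / e.size, config.grad_norm)
    while True:
        dx = _solve_damped(JtJ, state.mu, Jte)
        trial = state.params - dx
        perf_trial = _perf(model.residuals(trial))
        if perf_trial < perf:
            state.params = trial
            state.perf = perf_trial
            state.mu = state.mu * config.mu_decrease
            state.epoch += 1
            e2 = model.residuals(trial)
            J2 = model.jacobian(trial)
            state.grad_norm = _grad_norm(2.0 * (J2.T @ e2) / e2.size,
                                         config.grad_norm)
            return state
        state.mu = state.mu * config.mu_increase
        if state.mu > config.mu_max:
            state.stop_reason = "mu_overflow"
            return state


def train(model: ResidualModel, init_params: np.ndarray,
          config: LMAConfig | None = None) -> tuple[LMAState, list[dict]]:
    """Iterate ``lma_step`` until a stopping rule fires.

    Returns the final state and a per-accepted-epoch trace of
    ``{'epoch', 'perf', 'grad_norm', 'mu'}`` records.
    """
    config = config or LMAConfig()
    init_params = np.asarray(init_params, dtype=float)
    if not np.all(np.isfinite(init_params)):
        raise ValueError("non-finite initial parameters")
    state = LMAState(params=init_params.copy(), mu=config.mu_init)
    e0 = model.residuals(state.params)
    if not np.all(np.isfinite(e0)):
        raise FloatingPointError("non-finite residuals at init")
    state.perf = _perf(e0)
    g0 = 2.0 * (model.jacobian(state.params).T @ e0) / e0.size
    state.grad_norm = _grad_norm(g0, config.grad_norm)
    trace: list[dict] = []
    while state.stop_reason is None:
        if state.grad_norm < config.grad_tol:
            state.stop_reason = "grad_tol"
            break
        if config.perf_goal is not None and state.perf <= config.perf_goal:
            state.stop_reason = "perf_goal"
            break
        if state.epoch >= config.max_epochs:
            state.stop_reason = "max_epochs"
            break
        lma_step(model, state, config)
        if state.stop_reason is None:
            trace.append({"epoch": state.epoch, "perf": state.perf,
                          "grad_norm": state.grad_norm, "mu": state.mu})
    return state, trace


def finite_difference_jacobian(residuals_fn: Callable[[np.ndarray], np.ndarray],
                               params: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian, the independent check for analytic ones."""
    params = np.asarray(params, dtype=float)
    e0 = np.asarray(residuals_fn(params))
    J = np.empty((e0.size, params.size))
    for k in range(params.size):
        up = params.copy(); up[k] += h
        dn = params.copy(); dn[k] -= h
        J[:, k] = (np.asarray(residuals_fn(up)) - np.asarray(residuals_fn(dn))) / (2 * h)
    return J


def bptt_jacobian(net, inputs: np.ndarray, h0: np.ndarray) -> np.ndarray:
    """Jacobian of a linear recurrent net's outputs w.r.t. its flat weights.

    The net is unfolded through time: with teacher-forced inputs
    ``u_t = inputs[t]`` the dynamics are ``h_t = W_in u_t + W_rec h_{t-1}``,
    ``y_t = W_out h_t`` (linear, no biases).  Derivatives are accumulated in
    forward mode, so the hidden sensitivity recursion mirrors the unfolding:
    d h_t = d W_in u_t + d W_rec h_{t-1} + W_rec d h_{t-1}.

    Rows are time-step-major, output-unit-minor; columns follow the canonical
    parameter flattening (W_in, W_rec, W_out, each row-major).
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    T = inputs.shape[0]
    if T < 1:
        raise ValueError("sequence length must be >= 1")
    H, I = net.w_in.shape
    O = net.w_out.shape[0]
    if inputs.shape[1] != I or len(h0) != H:
        raise ValueError("shape mismatch between net and sequence")
    n_in, n_rec, n_out = H * I, H * H, O * H
    n_params = n_in + n_rec + n_out
    J = np.empty((T * O, n_params))
    h = np.asarray(h0, dtype=float)
    dh = np.zeros((H, n_params))  # sensitivities of hidden state
    for t in range(T):
        u = inputs[t]
        dh = net.w_rec @ dh
        # d(W_in u)/dW_in[i, j] = u[j] on hidden unit i
        for i in range(H):
            dh[i, i * I:(i + 1) * I] += u
            dh[i, n_in + i * H:n_in + (i + 1) * H] += h
        h = net.w_in @ u + net.w_rec @ h
        # y = W_out h: dy = W_out dh + dW_out h
        block = net.w_out @ dh
        for o in range(O):
            block[o, n_in + n_rec + o * H:n_in + n_rec + (o + 1) * H] += h
        J[t * O:(t + 1) * O] = block
    return J
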