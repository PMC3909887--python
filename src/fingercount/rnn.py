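"""Recurrent sequence memories for finger counting and spoken number words.

Three small Jordan-style recurrent networks memorise the number sequences:

* right-hand motor net  — 5 hidden units, 7 joint-angle outputs, steps one..five
  (the right hand is fully open from five on, so its sequence saturates);
* left-hand motor net   — 5 hidden units, 7 outputs, steps six..ten;
* auditory net          — 10 hidden units, 13 MFCC outputs, words one..ten.

The dynamics are linear with no biases:

    h_t = W_in y_{t-1} + W_rec h_{t-1},      y_t = W_out h_t

where y_{t-1} is the previous output (proprioceptive/auditory feedback): the
target during teacher-forced training, the net's own output when free-running.
Counting is started by setting every hidden unit to 1; an all-zero hidden
state is silent forever (no bias, linear), and incepting the stored hidden
state of number n makes the net continue with n+1, n+2, ...

The per-step hidden activation vectors are the internal number
representations; five feature datasets are assembled from them (and from the
raw MFCC rows) for the classification experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import data as _data
from .lma import LMAConfig, bptt_jacobian, train

__all__ = [
    "SequenceMemoryNet",
    "HiddenTrajectory",
    "CountingSequenceModel",
    "CountingSequenceResults",
    "MotorControllerMemory",
    "RepresentationDataset",
    "free_run",
    "start_state",
    "count_with_fingers",
    "build_representation_datasets",
    "train_counting_net",
    "VARIANT_DIMS",
]

TRAINED_PERF_THRESHOLD = 1e-6
VARIANT_DIMS = {1: 10, 2: 13, 3: 10, 4: 23, 5: 20}


@dataclass
class SequenceMemoryNet:
    """A linear, bias-free recurrent net with output feedback.

    ``context0`` is the step-0 feedback fed at the first step of a count
    started from the all-ones state: the normalized rest configuration for a
    motor net, silence (zeros) for the auditory net.
    """

    w_in: np.ndarray   # hidden x output (feedback) weights
    w_rec: np.ndarray  # hidden x hidden
    w_out: np.ndarray  # output x hidden
    context0: np.ndarray
    perf: float | None = None        # teacher-forced MSE after training
    seed: int | None = None
    epochs: int | None = None

    @property
    def hidden_size(self) -> int:
        return self.w_rec.shape[0]

    @property
    def output_size(self) -> int:
        return self.w_out.shape[0]

    @property
    def n_params(self) -> int:
        return self.w_in.size + self.w_rec.size + self.w_out.size

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w_in.ravel(), self.w_rec.ravel(),
                               self.w_out.ravel()])

    def set_params(self, params: np.ndarray) -> None:
        H, O = self.hidden_size, self.output_size
        i = H * O
        self.w_in = params[:i].reshape(H, O).copy()
        self.w_rec = params[i:i + H * H].reshape(H, H).copy()
        self.w_out = params[i + H * H:].reshape(O, H).copy()

    def step(self, h: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h_new = self.w_in @ u + self.w_rec @ h
        return h_new, self.w_out @ h_new

    def to_json(self, path) -> None:
        doc = {
            "w_in": self.w_in.tolist(), "w_rec": self.w_rec.tolist(),
            "w_out": self.w_out.tolist(), "context0": self.context0.tolist(),
            "perf": self.perf, "seed": self.seed, "epochs": self.epochs,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "SequenceMemoryNet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(w_in=np.array(doc["w_in"]), w_rec=np.array(doc["w_rec"]),
                   w_out=np.array(doc["w_out"]),
                   context0=np.array(doc["context0"]),
                   perf=doc["perf"], seed=doc["seed"], epochs=doc["epochs"])


@dataclass
class HiddenTrajectory:
    """Ordered (number index, hidden vector, output vector) records."""

    numbers: list[int]
    hidden: np.ndarray   # steps x hidden dims
    outputs: np.ndarray  # steps x output dims


def start_state(net: SequenceMemoryNet) -> np.ndarray:
    """The counting start state: every hidden unit set to 1."""
    return np.ones(net.hidden_size)


def _first_input(net: SequenceMemoryNet, init_hidden: np.ndarray) -> np.ndarray:
    """Feedback fed at the first free-running step.

    A silent net (all-zero hidden state) receives no feedback, so it stays
    silent; the all-ones start state receives the stored step-0 context (rest
    configuration / silence); any other incepted hidden state receives the
    output it reads out, so counting resumes from that number's successor.
    """
    if not np.any(init_hidden):
        return np.zeros(net.output_size)
    if np.array_equal(init_hidden, np.ones(net.hidden_size)):
        return net.context0.copy()
    return net.w_out @ init_hidden


def free_run(net: SequenceMemoryNet, init_hidden: np.ndarray, n_steps: int,
             first_input: np.ndarray | None = None,
             start_number: int = 1) -> HiddenTrajectory:
    """Autonomous rollout: each output is fed back as the next input."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    init_hidden = np.asarray(init_hidden, dtype=float)
    if len(init_hidden) != net.hidden_size:
        raise ValueError("init_hidden length must equal hidden_size")
    u = _first_input(net, init_hidden) if first_input is None else np.asarray(first_input, float)
    h = init_hidden
    hs, ys = [], []
    for _ in range(n_steps):
        h, y = net.step(h, u)
        hs.append(h)
        ys.append(y)
        u = y
    return HiddenTrajectory(numbers=list(range(start_number, start_number + n_steps)),
                            hidden=np.array(hs), outputs=np.array(ys))


class _TeacherForcedProblem:
    """Residuals/Jacobian of next-step prediction on one target sequence."""

    def __init__(self, net: SequenceMemoryNet, targets: np.ndarray,
                 context0: np.ndarray):
        self.net = net
        self.targets = np.asarray(targets, dtype=float)
        # teacher forcing: feedback input at step t is the target at t-1
        self.inputs = np.vstack([np.asarray(context0, float), self.targets[:-1]])
        self.h0 = np.ones(net.hidden_size)

    def _outputs(self, params: np.ndarray) -> np.ndarray:
        self.net.set_params(params)
        h = self.h0
        ys = []
        for u in self.inputs:
            h, y = self.net.step(h, u)
            ys.append(y)
        return np.array(ys)

    def residuals(self, params: np.ndarray) -> np.ndarray:
        return (self._outputs(params) - self.targets).ravel()

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        self.net.set_params(params)
        return bptt_jacobian(self.net, self.inputs, self.h0)


@dataclass
class CountingSequenceResults:
    """A trained sequence memory plus its training diagnostics."""

    net: SequenceMemoryNet
    perf: float
    epochs: int
    stop_reason: str
    trace: list[dict]
    attempts: int
    seed_used: int

    @property
    def converged(self) -> bool:
        return self.perf < TRAINED_PERF_THRESHOLD

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)

    def summary(self) -> str:
        lines = [
            "Counting sequence memory (linear Jordan RNN, no bias)",
            f"  hidden units: {self.net.hidden_size}   outputs: {self.net.output_size}",
            f"  parameters:   {self.net.n_params}",
            f"  seed: {self.seed_used} (attempt {self.attempts})",
            f"  accepted LM epochs: {self.epochs}   stop: {self.stop_reason}",
            f"  teacher-forced MSE: {self.perf:.3e}   converged: {self.converged}",
        ]
        return "\n".join(lines)


@dataclass
class CountingSequenceModel:
    """Fit a sequence memory to an ordered, normalized target sequence.

    ``targets`` is steps x channels (already in [-1, 1]); ``context0`` is the
    step-0 feedback.  ``fit`` initializes weights from seeded uniform
    (-0.5, 0.5), trains with Levenberg-Marquardt through time and, if the
    teacher-forced MSE does not reach 1e-6, retries with the next seed (up to
    ``max_attempts``).
    """

    targets: np.ndarray
    context0: np.ndarray
    hidden_size: int
    lma: LMAConfig = field(default_factory=LMAConfig)

    def __post_init__(self) -> None:
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("non-finite targets")
        if self.targets.shape[0] < 2:
            raise ValueError("need at least 2 sequence steps")

    def _init_net(self, rng: np.random.Generator) -> SequenceMemoryNet:
        H, O = self.hidden_size, self.targets.shape[1]
        return SequenceMemoryNet(
            w_in=rng.uniform(-0.5, 0.5, (H, O)),
            w_rec=rng.uniform(-0.5, 0.5, (H, H)),
            w_out=rng.uniform(-0.5, 0.5, (O, H)),
            context0=np.asarray(self.context0, dtype=float).copy(),
        )

    def fit(self, seed: int = 0, max_attempts: int = 10) -> CountingSequenceResults:
        last = None
        for attempt in range(max_attempts):
            s = seed + attempt
            net = self._init_net(np.random.default_rng(s))
            problem = _TeacherForcedProblem(net, self.targets, self.context0)
            state, trace = train(problem, net.get_params(), self.lma)
            net.set_params(state.params)
            net.perf, net.seed, net.epochs = state.perf, s, state.epoch
            last = CountingSequenceResults(
                net=net, perf=state.perf, epochs=state.epoch,
                stop_reason=state.stop_reason, trace=trace,
                attempts=attempt + 1, seed_used=s)
            if last.converged:
                return last
        return last


def train_counting_net(targets: np.ndarray, context0: np.ndarray,
                       hidden_size: int, lma: LMAConfig | None = None,
                       seed: int = 0) -> CountingSequenceResults:
    """Functional wrapper around :class:`CountingSequenceModel`."""
    model = CountingSequenceModel(targets=targets, context0=context0,
                                  hidden_size=hidden_size,
                                  lma=lma or LMAConfig())
    return model.fit(seed=seed)


@dataclass
class MotorControllerMemory:
    """The lateralized motor memory: one RNN per hand.

    The right net counts one..five; from six on the right hand stays open (the
    right net holds its final state) and the left net counts six..ten.  While
    numbers 1-5 are processed the left net is switched off: its hidden state
    is clamped to exactly zero.
    """

    right: SequenceMemoryNet
    left: SequenceMemoryNet

    @property
    def hidden_size(self) -> int:
        return self.right.hidden_size + self.left.hidden_size


def count_with_fingers(mcm: MotorControllerMemory, n: int) -> HiddenTrajectory:
    """Count 1..n on the fingers; returns concatenated (right+left) states."""
    if not 1 <= n <= 10:
        raise ValueError("n must be in 1..10")
    right_traj = free_run(mcm.right, start_state(mcm.right), min(n, 5))
    Hr, Hl = mcm.right.hidden_size, mcm.left.hidden_size
    hidden = np.zeros((n, Hr + Hl))
    outputs = np.zeros((n, mcm.right.output_size + mcm.left.output_size))
    for t in range(min(n, 5)):
        hidden[t, :Hr] = right_traj.hidden[t]
        outputs[t, :mcm.right.output_size] = right_traj.outputs[t]
    if n > 5:
        # right hand fully open: net holds its number-five state
        hidden[5:, :Hr] = right_traj.hidden[-1]
        outputs[5:, :mcm.right.output_size] = right_traj.outputs[-1]
        left_traj = free_run(mcm.left, start_state(mcm.left), n - 5,
                             start_number=6)
        hidden[5:, Hr:] = left_traj.hidden
        outputs[5:, mcm.right.output_size:] = left_traj.outputs
    return HiddenTrajectory(numbers=list(range(1, n + 1)), hidden=hidden,
                            outputs=outputs)


@dataclass
class RepresentationDataset:
    """Per-number feature vectors for one of the five training-input variants.

    1: motor hidden states (10); 2: raw normalized MFCC rows (13);
    3: auditory hidden states (10); 4: concat of 1 and 2 (23);
    5: concat of 1 and 3 (20).
    """

    variant: int
    features: np.ndarray  # 10 x d
    labels: list[int] = field(default_factory=lambda: list(range(1, 11)))

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        d = VARIANT_DIMS.get(self.variant)
        if d is None:
            raise ValueError(f"unknown variant {self.variant}")
        if self.features.shape != (10, d):
            raise ValueError(f"variant {self.variant} expects shape (10, {d}), "
                             f"got {self.features.shape}")

    @property
    def width(self) -> int:
        return self.features.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.features,
                          columns=[f"f{i + 1}" for i in range(self.width)])
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, variant: int) -> "RepresentationDataset":
        df = pd.read_csv(path)
        return cls(variant=variant, labels=df["label"].tolist(),
                   features=df.drop(columns="label").to_numpy(dtype=float))


def _check_trained(net: SequenceMemoryNet, name: str) -> None:
    if net.perf is None or net.perf >= TRAINED_PERF_THRESHOLD:
        raise ValueError(f"{name} net is not trained to threshold "
                         f"(perf={net.perf})")


def build_representation_datasets(
        mcm: MotorControllerMemory, auditory_net: SequenceMemoryNet,
        mfcc: _data.MfccTable | None = None,
) -> dict[int, RepresentationDataset]:
    """Assemble the five per-number feature datasets from trained memories."""
    _check_trained(mcm.right, "right motor")
    _check_trained(mcm.left, "left motor")
    _check_trained(auditory_net, "auditory")
    mfcc = mfcc or _data.load_mfcc_table()
    motor = count_with_fingers(mcm, 10).hidden            # 10 x 10
    words = _data.normalize(mfcc.values).values           # 10 x 13
    audio = free_run(auditory_net, start_state(auditory_net), 10).hidden
    return {
        1: RepresentationDataset(1, motor),
        2: RepresentationDataset(2, words),
        3: RepresentationDataset(3, audio),
        4: RepresentationDataset(4, np.hstack([motor, words])),
        5: RepresentationDataset(5, np.hstack([motor, audio])),
    }
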