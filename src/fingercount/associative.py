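"""Switch/associative layer: starting, stopping, cross-modal transfer, addition.

Once the motor and auditory sequence memories can count on their own, a small
supervisory layer lets them cooperate:

* it starts a count by setting every hidden unit of both memories to 1,
* it resets one memory (clamping its hidden state to zero) while the other
  keeps its state as a buffer,
* it transfers a number representation between modalities through two learned
  linear maps -- w1 (motor hidden -> auditory hidden) and w2 (the reverse) --
  fitted by Levenberg-Marquardt on the ten per-number hidden vectors,
* and it redirects a finished count to the competitive classifier.

Two-operand addition (a + b <= 10) follows a five-step procedure: both
memories count to the first operand; the auditory memory is reset when the
plus word is heard while the motor memory holds the partial sum; both count
the second operand so the motor memory reaches a + b; the motor state is
transferred through w1 into auditory form; and the result is classified.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import data as _data
from .classifier import SoftmaxClassifier, classify
from .lma import LMAConfig, train
from .rnn import (MotorControllerMemory, SequenceMemoryNet, count_with_fingers,
                  free_run, start_state)

__all__ = [
    "SwitchMode",
    "SwitchEvent",
    "TransitionError",
    "AdditionOverflowError",
    "step",
    "TRANSITIONS",
    "AssociativeWeights",
    "AssociativeMapModel",
    "train_transfer",
    "transfer",
    "recognize_word",
    "NumberSystem",
    "AdditionTrace",
    "add",
]


class SwitchMode(str, enum.Enum):
    IDLE = "idle"
    START_ALL = "start_all"
    COUNTING = "counting"
    RESET_AUDITORY = "reset_auditory"
    RESET_MOTOR = "reset_motor"
    TRANSFER_F2W = "transfer_fingers_to_words"
    TRANSFER_W2F = "transfer_words_to_fingers"
    OUTPUT = "output_to_classifier"


class SwitchEvent(str, enum.Enum):
    OPERAND_HEARD = "operand_heard"
    PLUS_HEARD = "plus_heard"
    OPERAND_DONE = "operand_done"
    COUNT_TICK = "count_tick"


class TransitionError(RuntimeError):
    """An event that is illegal in the current switch mode."""


class AdditionOverflowError(ValueError):
    """Sum beyond ten: no number representation exists past the tenth."""


# (mode, event) -> (next mode, directives).  Reconstructed from the five-step
# addition narrative plus the layer's four capabilities (start, reset, and the
# two transfer directions).  Directives are instructions to the executor:
#   init_all_ones      set every hidden unit of both memories to 1
#   init_auditory_ones restart only the auditory memory (motor buffer holds)
#   init_motor_ones    restart only the motor memory (auditory buffer holds)
#   clamp_auditory     zero the auditory hidden state
#   clamp_motor        zero the motor hidden state
#   tick               advance the active memories one count step
#   apply_w1/apply_w2  map a hidden state to the other modality
#   emit               hand the current representation to the classifier
TRANSITIONS: dict[tuple[SwitchMode, SwitchEvent], tuple[SwitchMode, tuple[str, ...]]] = {
    (SwitchMode.IDLE, SwitchEvent.OPERAND_HEARD):
        (SwitchMode.START_ALL, ("init_all_ones",)),
    (SwitchMode.START_ALL, SwitchEvent.COUNT_TICK):
        (SwitchMode.COUNTING, ("tick",)),
    (SwitchMode.COUNTING, SwitchEvent.COUNT_TICK):
        (SwitchMode.COUNTING, ("tick",)),
    (SwitchMode.COUNTING, SwitchEvent.PLUS_HEARD):
        (SwitchMode.RESET_AUDITORY, ("clamp_auditory",)),
    (SwitchMode.RESET_AUDITORY, SwitchEvent.OPERAND_HEARD):
        (SwitchMode.START_ALL, ("init_auditory_ones",)),
    (SwitchMode.RESET_MOTOR, SwitchEvent.OPERAND_HEARD):
        (SwitchMode.START_ALL, ("init_motor_ones",)),
    (SwitchMode.COUNTING, SwitchEvent.OPERAND_DONE):
        (SwitchMode.TRANSFER_F2W, ("apply_w1",)),
    (SwitchMode.TRANSFER_F2W, SwitchEvent.OPERAND_DONE):
        (SwitchMode.OUTPUT, ("emit",)),
    (SwitchMode.TRANSFER_W2F, SwitchEvent.OPERAND_DONE):
        (SwitchMode.OUTPUT, ("emit",)),
    (SwitchMode.OUTPUT, SwitchEvent.OPERAND_DONE):
        (SwitchMode.IDLE, ()),
}


def step(mode: SwitchMode, event: SwitchEvent) -> tuple[SwitchMode, tuple[str, ...]]:
    """Advance the switch state machine; illegal transitions raise."""
    key = (SwitchMode(mode), SwitchEvent(event))
    if key not in TRANSITIONS:
        raise TransitionError(f"event {key[1].value!r} is illegal in mode "
                              f"{key[0].value!r}")
    return TRANSITIONS[key]


class _LinearMapProblem:
    """Residuals/Jacobian of W X^T - Y^T over the ten representation pairs."""

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        self.X = X  # n x d_in
        self.Y = Y  # n x d_out
        self.d_in = X.shape[1]
        self.d_out = Y.shape[1]
        # residual (s, i) = W[i] . x_s - y_s[i]; params = W row-major
        n = X.shape[0]
        self._J = np.zeros((n * self.d_out, self.d_out * self.d_in))
        for s in range(n):
            for i in range(self.d_out):
                self._J[s * self.d_out + i,
                        i * self.d_in:(i + 1) * self.d_in] = X[s]

    def residuals(self, params: np.ndarray) -> np.ndarray:
        W = params.reshape(self.d_out, self.d_in)
        return (self.X @ W.T - self.Y).ravel()

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        return self._J


@dataclass
class AssociativeWeights:
    """The two learned cross-modal maps and their training diagnostics."""

    w1: np.ndarray  # motor hidden (10) -> auditory hidden (10)
    w2: np.ndarray  # auditory hidden (10) -> motor hidden (10)
    train_iterations: float   # mean accepted LM epochs over both directions
    train_error: float        # mean of the two final MSEs
    rank_deficient: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"w1": self.w1.tolist(), "w2": self.w2.tolist(),
                       "train_iterations": self.train_iterations,
                       "train_error": self.train_error,
                       "rank_deficient": self.rank_deficient}, fh)

    @classmethod
    def from_json(cls, path) -> "AssociativeWeights":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(w1=np.array(doc["w1"]), w2=np.array(doc["w2"]),
                   train_iterations=doc["train_iterations"],
                   train_error=doc["train_error"],
                   rank_deficient=doc["rank_deficient"])


@dataclass
class AssociativeMapModel:
    """Fit w1/w2 between the per-number motor and auditory hidden vectors.

    Each direction is a 10x10 linear map trained by Levenberg-Marquardt from
    a seeded uniform(-0.5, 0.5) initialization until the mean squared mapping
    error falls below ``error_goal``.
    """

    motor_reps: np.ndarray
    auditory_reps: np.ndarray
    error_goal: float = 1e-15
    lma: LMAConfig | None = None

    def __post_init__(self) -> None:
        self.motor_reps = np.asarray(self.motor_reps, dtype=float)
        self.auditory_reps = np.asarray(self.auditory_reps, dtype=float)
        if self.motor_reps.shape[0] != 10 or self.auditory_reps.shape[0] != 10:
            raise ValueError("need one representation row per number 1..10")

    def _fit_direction(self, X: np.ndarray, Y: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, int, float, bool]:
        deficient = np.linalg.matrix_rank(X) < X.shape[1]
        if deficient:
            warnings.warn("rank-deficient representations; using the "
                          "pseudo-inverse least-squares solution")
            W = (np.linalg.pinv(X) @ Y).T
            err = float(np.mean((X @ W.T - Y) ** 2))
            return W, 0, err, True
        # stop on the mapping-error floor, not the gradient floor: near the
        # least-squares solution the gradient is far below any useful
        # tolerance long before the error goal is met
        cfg = self.lma or LMAConfig(perf_goal=self.error_goal,
                                    grad_tol=1e-30, max_epochs=200)
        problem = _LinearMapProblem(X, Y)
        w0 = rng.uniform(-0.5, 0.5, X.shape[1] * Y.shape[1])
        state, _ = train(problem, w0, cfg)
        return (state.params.reshape(Y.shape[1], X.shape[1]),
                state.epoch, state.perf, False)

    def fit(self, seed: int = 0) -> AssociativeWeights:
        rng = np.random.default_rng(seed)
        w1, it1, err1, def1 = self._fit_direction(self.motor_reps,
                                                  self.auditory_reps, rng)
        w2, it2, err2, def2 = self._fit_direction(self.auditory_reps,
                                                  self.motor_reps, rng)
        return AssociativeWeights(w1=w1, w2=w2,
                                  train_iterations=(it1 + it2) / 2.0,
                                  train_error=(err1 + err2) / 2.0,
                                  rank_deficient=def1 or def2)


def train_transfer(motor_reps: np.ndarray, auditory_reps: np.ndarray,
                   lma: LMAConfig | None = None,
                   seed: int = 0) -> AssociativeWeights:
    """Functional wrapper around :class:`AssociativeMapModel`."""
    return AssociativeMapModel(motor_reps=motor_reps,
                               auditory_reps=auditory_reps,
                               lma=lma).fit(seed=seed)


def transfer(h: np.ndarray, direction: str, aw: AssociativeWeights) -> np.ndarray:
    """Map a hidden vector to the other modality through w1 or w2."""
    h = np.asarray(h, dtype=float)
    if direction == "fingers_to_words":
        return aw.w1 @ h
    if direction == "words_to_fingers":
        return aw.w2 @ h
    raise ValueError(f"unknown transfer direction {direction!r}")


def recognize_word(mfcc_row: np.ndarray,
                   table: _data.MfccTable | None = None) -> tuple[int, float]:
    """Nearest-neighbour word matcher over the normalized MFCC table.

    Returns the matched number (1..10) and the Euclidean distance, measured in
    normalized (per-coefficient) units.  Total function: no rejection
    threshold, arbitrary vectors match their closest word.
    """
    table = table or _data.load_mfcc_table()
    nm = _data.normalize(table.values)
    v = np.asarray(mfcc_row, dtype=float) / nm.scale_factors
    dists = np.linalg.norm(nm.values - v, axis=1)
    idx = int(np.argmin(dists))
    return idx + 1, float(dists[idx])


@dataclass
class AdditionTrace:
    """Deterministic replay log of one two-operand addition."""

    operand_a: int
    operand_b: int
    step_log: list[dict] = field(default_factory=list)
    result_class: int | None = None
    result_likelihood: float | None = None

    def to_json(self, path) -> None:
        doc = {
            "operand_a": self.operand_a, "operand_b": self.operand_b,
            "result_class": self.result_class,
            "result_likelihood": self.result_likelihood,
            "step_log": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in rec.items()}
                for rec in self.step_log
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


@dataclass
class NumberSystem:
    """A fully trained system: both memories, the maps, and a classifier.

    ``classifier`` must be trained on the 20-dim concatenation of motor and
    auditory hidden states (variant 5), which is what the switch layer emits.
    """

    mcm: MotorControllerMemory
    auditory: SequenceMemoryNet
    weights: AssociativeWeights
    classifier: SoftmaxClassifier


def _motor_hidden_at(mcm: MotorControllerMemory, n: int) -> np.ndarray:
    return count_with_fingers(mcm, n).hidden[-1]


def add(a: int, b: int, system: NumberSystem,
        mfcc: _data.MfccTable | None = None) -> AdditionTrace:
    """Two-operand addition via the five-step switch procedure.

    Operands are presented as spoken-word MFCC rows and recognised by the
    nearest-neighbour matcher; the motor memory acts as the accumulator and
    the auditory memory as the operand counter.
    """
    if not (1 <= a <= 10 and 1 <= b <= 10):
        raise ValueError("operands must be in 1..10")
    if a + b > 10:
        raise AdditionOverflowError(
            f"{a} + {b} = {a + b} exceeds the representation range 1..10")
    mfcc = mfcc or _data.load_mfcc_table()
    trace = AdditionTrace(operand_a=a, operand_b=b)
    mode = SwitchMode.IDLE

    def fire(event: SwitchEvent, **extra):
        nonlocal mode
        mode, directives = step(mode, event)
        trace.step_log.append({"state": mode.value, "event": event.value,
                               "directives": list(directives), **extra})
        return directives

    # step 1: first operand heard; both memories count to a
    heard_a, dist_a = recognize_word(mfcc.row(_data.WORD_LABELS[a - 1]), mfcc)
    fire(SwitchEvent.OPERAND_HEARD, heard=heard_a, distance=dist_a)
    for _ in range(heard_a):
        fire(SwitchEvent.COUNT_TICK)
    motor_after_a = _motor_hidden_at(system.mcm, heard_a)
    auditory_traj = free_run(system.auditory, start_state(system.auditory),
                             heard_a)
    trace.step_log[-1].update(motor_hidden=motor_after_a,
                              auditory_hidden=auditory_traj.hidden[-1])

    # step 2: plus heard; auditory reset, motor buffer holds the operand
    fire(SwitchEvent.PLUS_HEARD)

    # step 3: second operand heard; auditory restarts, motor keeps counting
    heard_b, dist_b = recognize_word(mfcc.row(_data.WORD_LABELS[b - 1]), mfcc)
    fire(SwitchEvent.OPERAND_HEARD, heard=heard_b, distance=dist_b)
    for _ in range(heard_b):
        fire(SwitchEvent.COUNT_TICK)
    total = heard_a + heard_b
    motor_final = _motor_hidden_at(system.mcm, total)
    auditory_b = free_run(system.auditory, start_state(system.auditory),
                          heard_b)
    trace.step_log[-1].update(motor_hidden=motor_final,
                              auditory_hidden=auditory_b.hidden[-1])

    # step 4: count done; the total is incepted into auditory form through w1
    fire(SwitchEvent.OPERAND_DONE)
    transferred = transfer(motor_final, "fingers_to_words", system.weights)
    trace.step_log[-1].update(transferred=transferred)

    # step 5: the result is emitted to the competitive classifier
    fire(SwitchEvent.OPERAND_DONE)
    probs = classify(system.classifier,
                     np.concatenate([motor_final, transferred]))
    trace.result_class = int(np.argmax(probs)) + 1
    trace.result_likelihood = float(probs[trace.result_class - 1])
    trace.step_log[-1].update(likelihoods=probs)
    fire(SwitchEvent.OPERAND_DONE)  # back to idle
    return trace
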