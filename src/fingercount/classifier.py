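"""Softmax competitive-layer classification of number representations.

A single softmax layer maps a representation vector x (one of the five
feature variants) to a probability distribution over the ten number classes:

    p = softmax(W^T x + b)

It is trained with the same Levenberg-Marquardt scheme as the sequence
memories, minimising the mean squared error between the softmax outputs and
one-hot targets over the ten exemplars (one per class) -- the experiments
measure how quickly and how well the classes can be fitted from each
representation, not held-out generalisation.  The repeated-runs protocol
retrains the classifier from many seeded random initializations and reports
per-class medians/std-devs of the likelihood assigned to the true class,
plus per-epoch learning curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lma import LMAConfig, LMAState, lma_step
from .rnn import RepresentationDataset

__all__ = [
    "softmax",
    "SoftmaxClassifier",
    "NumberClassificationModel",
    "NumberClassificationResults",
    "ClassificationReport",
    "PairwiseTestResult",
    "train_classifier",
    "classify",
    "evaluate_runs",
    "pairwise_tests",
]

N_CLASSES = 10


def softmax(q: np.ndarray) -> np.ndarray:
    """Stable softmax: exp(q_i) / sum_j exp(q_j), computed with max-shift."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("empty input to softmax")
    z = np.exp(q - q.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


@dataclass
class SoftmaxClassifier:
    """d -> 10 softmax layer; ``weights`` is d x 10, ``bias`` is length 10."""

    weights: np.ndarray
    bias: np.ndarray

    @property
    def input_dim(self) -> int:
        return self.weights.shape[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, "
                             f"got {x.shape[-1]}")
        return softmax(x @ self.weights + self.bias)

    def predict(self, x: np.ndarray) -> int:
        """Predicted class in 1..10; ties break toward the lower index."""
        p = self.predict_proba(x)
        return int(np.argmax(p)) + 1  # argmax takes the first maximum

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.weights.ravel(), self.bias])

    def set_params(self, params: np.ndarray) -> None:
        d = self.input_dim
        self.weights = params[:d * N_CLASSES].reshape(d, N_CLASSES).copy()
        self.bias = params[d * N_CLASSES:].copy()


def classify(clf: SoftmaxClassifier, x: np.ndarray) -> np.ndarray:
    """Probability vector over classes 1..10 for one feature vector."""
    return clf.predict_proba(np.asarray(x, dtype=float))


class _ClassifierProblem:
    """Squared error of softmax outputs against one-hot targets.

    The Jacobian rows run sample-major, class-minor; the softmax derivative
    dp/dq = diag(p) - p p^T is folded in analytically.
    """

    def __init__(self, features: np.ndarray, clf: SoftmaxClassifier):
        self.X = np.asarray(features, dtype=float)   # n x d
        self.T = np.eye(N_CLASSES)                   # one-hot, row i = class i+1
        self.clf = clf

    def residuals(self, params: np.ndarray) -> np.ndarray:
        self.clf.set_params(params)
        return (self.clf.predict_proba(self.X) - self.T).ravel()

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        self.clf.set_params(params)
        P = self.clf.predict_proba(self.X)           # n x 10
        n, d = self.X.shape
        # D[s] = diag(p_s) - p_s p_s^T : derivative of softmax wrt net input
        D = np.einsum("si,ij->sij", P, np.eye(N_CLASSES)) \
            - np.einsum("si,sj->sij", P, P)
        # dq_j/dW[k, j] = x_k  ->  dp_i/dW[k, j] = D[s, i, j] * x_s[k]
        JW = np.einsum("sij,sk->sikj", D, self.X)
        JW = JW.reshape(n * N_CLASSES, d * N_CLASSES)
        Jb = D.reshape(n * N_CLASSES, N_CLASSES)
        return np.hstack([JW, Jb])


@dataclass
class NumberClassificationResults:
    """A trained classifier, its per-epoch snapshots, and fit diagnostics."""

    classifier: SoftmaxClassifier
    snapshots: list[SoftmaxClassifier]
    perf: float
    epochs_run: int
    stop_reason: str
    seed: int
    variant: int

    def true_class_likelihoods(self, features: np.ndarray) -> np.ndarray:
        P = self.classifier.predict_proba(features)
        return np.diag(P)

    def summary(self) -> str:
        lines = [
            f"Softmax competitive classifier (variant {self.variant})",
            f"  input dim: {self.classifier.input_dim}   classes: {N_CLASSES}",
            f"  seed: {self.seed}   accepted epochs: {self.epochs_run}"
            f"   stop: {self.stop_reason}",
            f"  final MSE: {self.perf:.4e}",
        ]
        return "\n".join(lines)


@dataclass
class NumberClassificationModel:
    """Fit the softmax layer to one representation dataset.

    One exemplar per class; ``fit`` runs the requested number of accepted LM
    epochs (snapshotting the layer after each) from a seeded uniform
    (-0.5, 0.5) initialization of weights and bias.
    """

    dataset: RepresentationDataset
    lma: LMAConfig = field(default_factory=LMAConfig)

    def __post_init__(self) -> None:
        if sorted(self.dataset.labels) != list(range(1, 11)):
            raise ValueError("dataset must contain exactly one row per class 1..10")

    def fit(self, epochs: int = 10, seed: int = 0) -> NumberClassificationResults:
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng(seed)
        d = self.dataset.width
        clf = SoftmaxClassifier(weights=rng.uniform(-0.5, 0.5, (d, N_CLASSES)),
                                bias=rng.uniform(-0.5, 0.5, N_CLASSES))
        problem = _ClassifierProblem(self.dataset.features, clf)
        state = LMAState(params=clf.get_params(), mu=self.lma.mu_init)
        e0 = problem.residuals(state.params)
        state.perf = float(np.mean(e0 * e0))
        snapshots: list[SoftmaxClassifier] = []
        stop = "max_epochs"
        for _ in range(epochs):
            g = problem.jacobian(state.params).T @ problem.residuals(state.params)
            if float(np.max(np.abs(2.0 * g / (10 * N_CLASSES)))) < self.lma.grad_tol:
                stop = "grad_tol"
                break
            lma_step(problem, state, self.lma)
            if state.stop_reason is not None:
                stop = state.stop_reason
                break
            snap = SoftmaxClassifier(weights=np.empty((d, N_CLASSES)),
                                     bias=np.empty(N_CLASSES))
            snap.set_params(state.params)
            snapshots.append(snap)
        # a run that converges early keeps its final layer for later epochs
        while len(snapshots) < epochs:
            snapshots.append(snapshots[-1] if snapshots else
                             SoftmaxClassifier(weights=clf.weights.copy(),
                                               bias=clf.bias.copy()))
        clf.set_params(state.params)
        return NumberClassificationResults(
            classifier=clf, snapshots=snapshots, perf=state.perf,
            epochs_run=state.epoch, stop_reason=stop, seed=seed,
            variant=self.dataset.variant)


def train_classifier(dataset: RepresentationDataset, epochs: int = 10,
                     lma: LMAConfig | None = None,
                     seed: int = 0) -> NumberClassificationResults:
    """Functional wrapper around :class:`NumberClassificationModel`."""
    model = NumberClassificationModel(dataset=dataset, lma=lma or LMAConfig())
    return model.fit(epochs=epochs, seed=seed)


@dataclass
class ClassificationReport:
    """Repeated-runs statistics for one representation variant.

    ``run_likelihoods`` keeps the raw per-run true-class likelihoods
    (n_runs x 10) so reports can be compared with paired t-tests.
    """

    variant: int
    per_class_median: np.ndarray
    per_class_std: np.ndarray
    avg_median: float
    per_epoch_avg_likelihood: np.ndarray          # length = epochs
    per_epoch_median_misclassifications: np.ndarray
    n_runs: int
    seeds: list[int]
    run_likelihoods: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": list(range(1, 11)),
            "median": self.per_class_median,
            "std": self.per_class_std,
        })

    def to_json(self, path) -> None:
        doc = {
            "variant": self.variant,
            "per_class_median": self.per_class_median.tolist(),
            "per_class_std": self.per_class_std.tolist(),
            "avg_median": self.avg_median,
            "per_epoch_avg_likelihood": self.per_epoch_avg_likelihood.tolist(),
            "per_epoch_median_misclassifications":
                self.per_epoch_median_misclassifications.tolist(),
            "n_runs": self.n_runs,
            "seeds": self.seeds,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def evaluate_runs(dataset: RepresentationDataset, n_runs: int = 100,
                  epochs: int = 10, base_seed: int = 0,
                  lma: LMAConfig | None = None) -> ClassificationReport:
    """Retrain the classifier ``n_runs`` times and summarise the likelihoods.

    Run r uses seed ``base_seed + r``.  For every run the likelihood assigned
    to the true class of each exemplar is recorded at the final epoch; the
    learning curves track, per epoch, the average true-class likelihood
    (across classes and runs) and the median (across runs) count of
    argmax-misclassified classes.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    model = NumberClassificationModel(dataset=dataset, lma=lma or LMAConfig())
    X = dataset.features
    likes = np.empty((n_runs, N_CLASSES))
    epoch_likes = np.empty((n_runs, epochs))
    epoch_miscls = np.empty((n_runs, epochs))
    seeds = [base_seed + r for r in range(n_runs)]
    for r, seed in enumerate(seeds):
        res = model.fit(epochs=epochs, seed=seed)
        for ep, snap in enumerate(res.snapshots):
            P = snap.predict_proba(X)
            epoch_likes[r, ep] = np.mean(np.diag(P))
            preds = np.argmax(P, axis=1) + 1
            epoch_miscls[r, ep] = np.sum(preds != np.arange(1, 11))
        likes[r] = np.diag(res.snapshots[-1].predict_proba(X))
    per_class_median = np.median(likes, axis=0)
    per_class_std = np.std(likes, axis=0, ddof=1)
    return ClassificationReport(
        variant=dataset.variant,
        per_class_median=per_class_median,
        per_class_std=per_class_std,
        avg_median=float(np.mean(per_class_median)),
        per_epoch_avg_likelihood=epoch_likes.mean(axis=0),
        per_epoch_median_misclassifications=np.median(epoch_miscls, axis=0),
        n_runs=n_runs, seeds=seeds, run_likelihoods=likes)


@dataclass
class PairwiseTestResult:
    """Per-class paired t-tests between two repeated-runs experiments."""

    variant_pair: tuple[int, int]
    per_class_p: np.ndarray
    per_class_t: np.ndarray
    alpha: float = 0.05

    @property
    def per_class_significant(self) -> np.ndarray:
        return self.per_class_p < self.alpha


def pairwise_tests(report_a: ClassificationReport,
                   report_b: ClassificationReport,
                   alpha: float = 0.05) -> PairwiseTestResult:
    """Two-sided paired t-test per class on true-class likelihoods.

    Runs are paired by seed index; no multiple-testing correction is applied.
    Identical samples (zero differences) yield p = 1.
    """
    A, B = report_a.run_likelihoods, report_b.run_likelihoods
    if A.shape != B.shape:
        raise ValueError("reports must have equal run counts")
    ps = np.empty(N_CLASSES)
    ts = np.empty(N_CLASSES)
    for c in range(N_CLASSES):
        diff = A[:, c] - B[:, c]
        if np.allclose(diff, 0.0):
            ts[c], ps[c] = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(A[:, c], B[:, c])
            ts[c], ps[c] = t, p
    return PairwiseTestResult(variant_pair=(report_a.variant, report_b.variant),
                              per_class_p=ps, per_class_t=ts, alpha=alpha)
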