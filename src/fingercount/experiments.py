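"""End-to-end reproduction runs: the five-dataset comparison, learning
curves, representation clustering, and the addition demo.

The canonical experiment trains the three sequence memories once (seeded),
builds the five representation datasets, and then retrains the softmax
classifier 100 times per dataset for 10 accepted epochs each.  The summary
statistics are written in the layout of the likelihood table (per-class
median/std per variant plus the average row); curves, clustering and the
addition narrative are convenience views over the same trained system.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import yaml

from . import data as _data
from .associative import (AdditionTrace, AssociativeMapModel, NumberSystem,
                          add)
from .classifier import (ClassificationReport, NumberClassificationModel,
                         evaluate_runs)
from .lma import LMAConfig
from .rnn import (CountingSequenceModel, MotorControllerMemory,
                  RepresentationDataset, SequenceMemoryNet,
                  build_representation_datasets)

__all__ = [
    "ExperimentConfig",
    "ClusteringResult",
    "build_system",
    "run_table3",
    "run_learning_curves",
    "cluster_representations",
    "run_addition_demo",
]

log = logging.getLogger("fingercount")

VARIANT_TITLES = {
    1: "Fingers sequence only",
    2: "Number words out of sequence",
    3: "Words sequence only",
    4: "Finger sequence and number words",
    5: "Fingers and words sequences",
}


@dataclass
class ExperimentConfig:
    """Seeds, sizes and switches for a full reproduction run.

    The sequence memories are trained once per experiment (with their own
    seeds); the 100 classifier runs reuse that single representation set and
    draw their initializations from ``base_seed + run``.
    """

    base_seed: int = 0
    rnn_seed_right: int | None = None   # default: base_seed + 101
    rnn_seed_left: int | None = None    # default: base_seed + 202
    rnn_seed_auditory: int | None = None  # default: base_seed + 303
    runs: int = 100
    epochs: int = 10
    variants: tuple[int, ...] = (1, 2, 3, 4, 5)
    normalization_mode: str = "per_feature"
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.rnn_seed_right is None:
            self.rnn_seed_right = self.base_seed + 101
        if self.rnn_seed_left is None:
            self.rnn_seed_left = self.base_seed + 202
        if self.rnn_seed_auditory is None:
            self.rnn_seed_auditory = self.base_seed + 303

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "variants" in doc:
            doc["variants"] = tuple(doc["variants"])
        return cls(**doc)


@dataclass
class TrainedSystem:
    """Everything a reproduction run needs, trained from one config."""

    mcm: MotorControllerMemory
    auditory: SequenceMemoryNet
    datasets: dict[int, RepresentationDataset]
    training_summaries: list[str]


def build_system(config: ExperimentConfig | None = None) -> TrainedSystem:
    """Train the three counting memories and assemble the five datasets.

    The right-hand net learns the normalized right-hand joint sequence
    one..ten (constant from five on), the left-hand net the left-hand
    sequence six..ten, the auditory net the normalized MFCC word sequence;
    step-0 contexts are the normalized rest configuration (motor) and
    silence (auditory).
    """
    config = config or ExperimentConfig()
    finger = _data.load_finger_table()
    mfcc = _data.load_mfcc_table()
    norm_f = _data.normalize(finger.values, config.normalization_mode).values
    norm_w = _data.normalize(mfcc.values, config.normalization_mode).values
    rest = norm_f[0]

    right = CountingSequenceModel(targets=norm_f[1:, _data.RIGHT_HAND],
                                  context0=rest[_data.RIGHT_HAND],
                                  hidden_size=5)
    left = CountingSequenceModel(targets=norm_f[6:, _data.LEFT_HAND],
                                 context0=rest[_data.LEFT_HAND],
                                 hidden_size=5)
    auditory = CountingSequenceModel(targets=norm_w,
                                     context0=np.zeros(norm_w.shape[1]),
                                     hidden_size=10)
    res_r = right.fit(seed=config.rnn_seed_right)
    res_l = left.fit(seed=config.rnn_seed_left)
    res_a = auditory.fit(seed=config.rnn_seed_auditory)
    for name, res in (("right", res_r), ("left", res_l), ("auditory", res_a)):
        log.info("trained %s net: perf=%.3e epochs=%d attempts=%d",
                 name, res.perf, res.epochs, res.attempts)
    mcm = MotorControllerMemory(right=res_r.net, left=res_l.net)
    datasets = build_representation_datasets(mcm, res_a.net, mfcc)
    return TrainedSystem(mcm=mcm, auditory=res_a.net, datasets=datasets,
                         training_summaries=[r.summary()
                                             for r in (res_r, res_l, res_a)])


def _prepare_outdir(outdir, config: ExperimentConfig) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass overwrite=True "
            f"(--overwrite) to replace it")
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    return outdir


def table3_frame(reports: dict[int, ClassificationReport]) -> pd.DataFrame:
    """Per-class median/std columns per variant, plus the average row."""
    cols: dict[str, list[float]] = {}
    for v, rep in sorted(reports.items()):
        title = VARIANT_TITLES[v]
        cols[f"{title} median"] = list(rep.per_class_median) + [rep.avg_median]
        cols[f"{title} std"] = (list(rep.per_class_std)
                                + [float(np.mean(rep.per_class_std))])
    index = [str(i) for i in range(1, 11)] + ["avg"]
    return pd.DataFrame(cols, index=pd.Index(index, name="class"))


def run_table3(config: ExperimentConfig | None = None,
               system: TrainedSystem | None = None,
               outdir=None) -> dict[int, ClassificationReport]:
    """The repeated-runs classification comparison over the five datasets."""
    config = config or ExperimentConfig()
    system = system or build_system(config)
    reports: dict[int, ClassificationReport] = {}
    for v in config.variants:
        log.info("variant %d: %d runs x %d epochs", v, config.runs,
                 config.epochs)
        reports[v] = evaluate_runs(system.datasets[v], n_runs=config.runs,
                                   epochs=config.epochs,
                                   base_seed=config.base_seed + 1000)
    if outdir is not None:
        outdir = _prepare_outdir(outdir, config)
        table3_frame(reports).to_csv(outdir / "likelihood_table.csv")
        for v, rep in reports.items():
            rep.to_json(outdir / f"variant{v}_report.json")
            np.savetxt(outdir / f"variant{v}_run_likelihoods.csv",
                       rep.run_likelihoods, delimiter=",")
    return reports


def curves_frame(reports: dict[int, ClassificationReport]) -> pd.DataFrame:
    rows = []
    for v, rep in sorted(reports.items()):
        for ep in range(len(rep.per_epoch_avg_likelihood)):
            rows.append({
                "variant": v, "epoch": ep + 1,
                "avg_likelihood": rep.per_epoch_avg_likelihood[ep],
                "median_misclassifications":
                    rep.per_epoch_median_misclassifications[ep],
            })
    return pd.DataFrame(rows)


def run_learning_curves(config: ExperimentConfig | None = None,
                        system: TrainedSystem | None = None,
                        reports: dict[int, ClassificationReport] | None = None,
                        outdir=None) -> pd.DataFrame:
    """Per-epoch average likelihood and median misclassification curves."""
    config = config or ExperimentConfig()
    if reports is None:
        reports = run_table3(config, system=system)
    df = curves_frame(reports)
    if outdir is not None:
        outdir = _prepare_outdir(outdir, config)
        df.to_csv(outdir / "learning_curves.csv", index=False)
    return df


@dataclass
class ClusteringResult:
    """Agglomerative clustering of the ten representation vectors.

    ``adjacency_score`` is the mean absolute numeric difference between
    consecutive leaves of the optimally ordered dendrogram: 1 means the tree
    orders the numbers exactly along the counting sequence.
    """

    variant: int
    linkage: np.ndarray
    leaf_order: list[int]
    adjacency_score: float
    degenerate: bool = False


def cluster_representations(dataset: RepresentationDataset) -> ClusteringResult:
    """Complete-linkage hierarchy with optimal leaf ordering.

    Euclidean distances between the ten per-number feature rows; the leaf
    order minimises the sum of consecutive-leaf distances among orders
    consistent with the tree.
    """
    X = dataset.features
    degenerate = len(np.unique(X.round(12), axis=0)) < X.shape[0]
    D = ssd.pdist(X, metric="euclidean")
    Z = sch.linkage(D, method="complete")
    Z = sch.optimal_leaf_ordering(Z, D)
    leaves = sch.leaves_list(Z)
    labels = np.asarray(dataset.labels)[leaves]
    score = float(np.mean(np.abs(np.diff(labels))))
    return ClusteringResult(variant=dataset.variant, linkage=Z,
                            leaf_order=[int(x) for x in labels],
                            adjacency_score=score, degenerate=degenerate)


ADDITION_NARRATIVE = (
    "1. The first operand ({a}) is heard; both memories count up to it.",
    "2. The plus word is heard: the auditory memory is reset while the "
    "motor memory keeps the first operand.",
    "3. The second operand ({b}) is heard; both memories count again -- the "
    "auditory memory reaches {b}, the motor memory reaches {total}.",
    "4. The count is done: the total is incepted from the finger memory "
    "into the auditory memory through the associative connection (w1).",
    "5. The resulting number is emitted to the competitive classifier: "
    "class {result} (likelihood {likelihood:.3f}).",
)


def run_addition_demo(system: NumberSystem, a: int, b: int) -> tuple[AdditionTrace, str]:
    """Run one addition and render the five-step narrative."""
    trace = add(a, b, system)
    text = "\n".join(s.format(a=a, b=b, total=a + b,
                              result=trace.result_class,
                              likelihood=trace.result_likelihood)
                     for s in ADDITION_NARRATIVE)
    return trace, text


def make_number_system(config: ExperimentConfig | None = None,
                       system: TrainedSystem | None = None,
                       classifier_seed: int | None = None) -> NumberSystem:
    """Train the associative maps and a variant-5 classifier for arithmetic."""
    config = config or ExperimentConfig()
    system = system or build_system(config)
    aw = AssociativeMapModel(
        motor_reps=system.datasets[1].features,
        auditory_reps=system.datasets[3].features).fit(
            seed=config.base_seed + 7)
    clf_res = NumberClassificationModel(system.datasets[5]).fit(
        epochs=config.epochs,
        seed=config.base_seed + 1000 if classifier_seed is None
        else classifier_seed)
    return NumberSystem(mcm=system.mcm, auditory=system.auditory,
                        weights=aw, classifier=clf_res.classifier)
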