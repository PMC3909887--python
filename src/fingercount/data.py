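"""Embodied number fixtures: finger-joint configurations and number-word MFCCs.

The package models a child-like humanoid robot that counts on its fingers
(right hand for one..five, left hand added for six..ten) and hears spoken
number words.  Two small numeric tables carry all of the embodiment:

* the joint angles (degrees) of the 14 controlled finger joints for the rest
  position and the ten number configurations, and
* 13 mel-frequency cepstral coefficients (MFCCs) for each spoken number word
  one..ten.

Both tables are embedded verbatim; everything downstream (sequence memories,
classifier, arithmetic) is trained on normalized copies of them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONFIG_LABELS",
    "WORD_LABELS",
    "JOINT_NAMES",
    "MFCC_NAMES",
    "FingerJointTable",
    "MfccTable",
    "NormalizedMatrix",
    "load_finger_table",
    "load_mfcc_table",
    "normalize",
    "denormalize",
    "perturb",
]

CONFIG_LABELS = (
    "rest", "one", "two", "three", "four", "five",
    "six", "seven", "eight", "nine", "ten",
)
WORD_LABELS = CONFIG_LABELS[1:]

# 7 joints per hand: 2 DoF for thumb/index/middle, 1 for the glued ring+pinky.
JOINT_NAMES = (
    "r_thumb_1", "r_thumb_2", "r_index_1", "r_index_2",
    "r_middle_1", "r_middle_2", "r_ring_pinky",
    "l_thumb_1", "l_thumb_2", "l_index_1", "l_index_2",
    "l_middle_1", "l_middle_2", "l_ring_pinky",
)
RIGHT_HAND = slice(0, 7)
LEFT_HAND = slice(7, 14)

MFCC_NAMES = tuple(f"c{i}" for i in range(1, 14))

# Joint angles in degrees, one row per joint, one column per configuration
# (rest, one..ten).  High values = finger closed, low = open; the exact values
# deviate from the ideal 0/90/180/220 because of element collision and tendon
# limits in the simulated hand.
_FINGER_ROWS_BY_JOINT = """
90.0  90.0  90.0  10.9  88.9  11.1  11.1  11.1  11.1  11.1  11.1
180.0 180.0 180.0 2.1   88.8  1.2   1.2   1.2   1.2   1.2   1.2
90.0  1.1   0.0   0.0   0.0   0.0   0.0   0.0   0.0   0.0   0.0
180.0 2.2   0.0   0.0   0.0   0.0   0.0   0.0   0.0   0.0   0.0
90.0  90.0  1.1   0.0   0.0   0.0   0.0   0.0   0.0   0.0   0.0
180.0 180.0 2.2   0.0   0.0   0.0   0.0   0.0   0.0   0.0   0.0
220.0 220.0 220.0 220.0 3.0   0.0   0.0   0.0   0.0   0.0   0.0
90.0  90.0  90.0  90.0  90.0  90.0  90.0  90.0  11.0  89.0  11.0
180.0 180.0 180.0 180.0 180.0 180.0 180.0 180.0 2.2   88.9  1.2
90.0  90.0  90.0  90.0  90.0  90.0  1.0   0.0   0.0   0.0   0.0
180.0 180.0 180.0 180.0 180.0 180.0 2.1   0.0   0.0   0.0   0.0
90.0  90.0  90.0  90.0  90.0  90.0  90.0  1.0   0.0   0.0   0.0
180.0 180.0 180.0 180.0 180.0 180.0 180.0 2.1   0.0   0.0   0.0
220.0 220.0 220.0 220.0 220.0 220.0 220.0 220.0 220.0 2.7   0.0
"""

# MFCCs (dimensionless), one row per coefficient c1..c13, one column per word
# one..ten.  c1 is the energy-like term and dominates every word.
_MFCC_ROWS_BY_COEFF = """
-35.5929 -32.9669 -32.4777 -31.2712 -29.7136 -35.4331 -35.442  -32.0295 -31.2157 -31.9479
-1.0919  -1.3581  -1.5224  -1.8495  -1.4493  -1.2686  -1.0689  -1.9539  -1.1709  -2.0959
0.4216   1.1045   0.6798   0.0099   -0.6858  0.7221   0.6448   0.6668   0.1402   0.5683
-0.1042  0.2708   -0.0635  -0.3179  -0.4566  0.184    0.1756   0.2295   0.7539   -0.2115
0.3303   0.0268   0.2202   0.0331   0.507    -0.08    -0.2727  -0.0303  -0.4317  -0.2456
-0.1156  0.3903   -0.0071  -0.3468  0.3923   0.0328   0.0277   -0.2201  -0.189   0.1962
0.0052   0.1658   -0.0939  0.3523   -0.3028  0.1184   0.7074   0.0011   0.9789   0.2468
-0.1069  0.0182   0.0204   0.3312   -0.1998  -0.4751  0.036    -0.0101  0.3488   0.4278
-0.1343  -0.1744  0.0419   0.1559   -0.1472  0.0975   0.2879   0.1467   -0.2435  0.5773
0.1164   -0.1774  0.0226   -0.0661  -0.1542  0.5202   0.1546   0.1802   0.4552   -0.1427
-0.5587  0.3471   -0.0303  -0.0531  0.3098   -0.1306  0.155    0.0578   -0.1662  -0.0612
-0.1981  -0.0564  0.1463   0.0979   0.2068   -0.0164  -0.2105  0.2783   -0.2708  -0.0456
0.223    -0.0566  -0.0506  0.033    -0.0655  0.0037   -0.1311  -0.0695  -0.176   0.0915
"""


def _parse_block(text: str) -> np.ndarray:
    return np.loadtxt(io.StringIO(text))


@dataclass
class FingerJointTable:
    """Joint angles (degrees) for the rest position and configurations one..ten.

    ``values`` is 11 configurations x 14 joints; rows follow ``labels``
    (rest first), columns follow ``joint_names`` (right hand then left hand).
    """

    values: np.ndarray
    labels: tuple[str, ...] = CONFIG_LABELS
    joint_names: tuple[str, ...] = JOINT_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.joint_names)):
            raise ValueError(
                f"expected {(len(self.labels), len(self.joint_names))}, "
                f"got {self.values.shape}"
            )

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.joint_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="configuration")

    @classmethod
    def from_csv(cls, path) -> "FingerJointTable":
        df = pd.read_csv(path, index_col="configuration")
        return cls(values=df.to_numpy(dtype=float),
                   labels=tuple(df.index), joint_names=tuple(df.columns))


@dataclass
class MfccTable:
    """Mel-frequency cepstral coefficients for the spoken words one..ten.

    ``values`` is 10 words x 13 coefficients; c1 is the energy-like term.
    """

    values: np.ndarray
    labels: tuple[str, ...] = WORD_LABELS
    coeff_names: tuple[str, ...] = MFCC_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.coeff_names)):
            raise ValueError(
                f"expected {(len(self.labels), len(self.coeff_names))}, "
                f"got {self.values.shape}"
            )

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.coeff_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="word")

    @classmethod
    def from_csv(cls, path) -> "MfccTable":
        df = pd.read_csv(path, index_col="word")
        return cls(values=df.to_numpy(dtype=float),
                   labels=tuple(df.index), coeff_names=tuple(df.columns))


def load_finger_table() -> FingerJointTable:
    """The embedded finger-joint table (11 configurations x 14 joints)."""
    return FingerJointTable(values=_parse_block(_FINGER_ROWS_BY_JOINT).T)


def load_mfcc_table() -> MfccTable:
    """The embedded MFCC table (10 words x 13 coefficients)."""
    return MfccTable(values=_parse_block(_MFCC_ROWS_BY_COEFF).T)


@dataclass
class NormalizedMatrix:
    """A matrix rescaled into [-1, 1] together with the divisors used.

    ``scale_factors`` has one entry per feature (``per_feature`` mode) or a
    single entry (``global`` mode); ``denormalize`` undoes the scaling.
    """

    values: np.ndarray
    scale_factors: np.ndarray
    mode: str

    def denormalize(self) -> np.ndarray:
        return self.values * self.scale_factors


def normalize(matrix: np.ndarray, mode: str = "per_feature") -> NormalizedMatrix:
    """Scale a matrix into [-1, 1] by dividing by the maximum absolute value.

    In ``per_feature`` mode each column (one joint, or one cepstral
    coefficient, observed across the configurations/words) is divided by its
    own maximum absolute value, so every feature spans the full range; columns
    that are identically zero pass through unchanged.  ``global`` mode divides
    the whole matrix by one scalar.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    if mode == "per_feature":
        scale = np.abs(matrix).max(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
    elif mode == "global":
        s = np.abs(matrix).max()
        if s == 0.0:
            raise ValueError("degenerate scale: matrix is identically zero")
        scale = np.full(matrix.shape[1], s) if matrix.ndim == 2 else np.array([s])
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return NormalizedMatrix(values=matrix / scale, scale_factors=scale, mode=mode)


def denormalize(nm: NormalizedMatrix) -> np.ndarray:
    return nm.denormalize()


def perturb(table, sigma: float, seed: int):
    """Return a copy of a fixture table with i.i.d. Gaussian noise added.

    Noise is zero-mean with standard deviation ``sigma`` in the table's own
    units (degrees for joints, dimensionless for MFCCs); ``sigma=0`` returns
    an exact copy.  Used to generate robustness fixtures.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=table.values.shape) if sigma > 0 else 0.0
    cls = type(table)
    if isinstance(table, FingerJointTable):
        return cls(values=table.values + noise, labels=table.labels,
                   joint_names=table.joint_names)
    return cls(values=table.values + noise, labels=table.labels,
               coeff_names=table.coeff_names)
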