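"""Per-exam feature vector for low/high-risk classification.

Four derived 10-vectors are computed from the temperature groups:

* internal gradient per breast — deep minus skin temperature at matched
  points (a tumour locally *reduces* this gradient as heat reaches the skin);
* thermal asymmetry per channel — signed left minus right at symmetric
  points (sidedness is kept; a classifier can learn it).

Aggregates (min, max, mean, range) of each derived vector and of the four
raw breast groups, plus Q_max and R, complete the vector.  The layout is
fixed and versioned: FEATURE_NAMES documents the exact order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mwr import compute_asymmetry, compute_qmax, compute_r
from .thermogram import TemperatureGroups, Thermogram, group_temperatures

FEATURE_SCHEMA_VERSION = "1"

AGGREGATES = ("min", "max", "mean", "range")

_VECTOR_FAMILIES = ("grad_right", "grad_left", "asym_skin", "asym_int")
_RAW_FAMILIES = ("skin_right", "skin_left", "int_right", "int_left")


def _feature_names() -> list[str]:
    names: list[str] = []
    for fam in _VECTOR_FAMILIES:
        names += [f"{fam}_{i}" for i in range(10)]
    for fam in _VECTOR_FAMILIES + _RAW_FAMILIES:
        names += [f"{fam}_{agg}" for agg in AGGREGATES]
    names += ["q_max", "r"]
    return names


#: canonical feature order; length is constant across patients
FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names())
N_FEATURES = len(FEATURE_NAMES)  # 4*10 + 8*4 + 2 = 74


@dataclass
class FeatureVector:
    grad_right: np.ndarray
    grad_left: np.ndarray
    asym_skin: np.ndarray
    asym_int: np.ndarray
    values: np.ndarray  # full flat vector in FEATURE_NAMES order

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def compute_gradients(groups: TemperatureGroups) -> tuple[np.ndarray, np.ndarray]:
    """Internal temperature gradient per breast: mw − ir at matched points."""
    return (
        groups.int_right - groups.skin_right,
        groups.int_left - groups.skin_left,
    )


def compute_asymmetry_vectors(
    groups: TemperatureGroups,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed left − right difference per channel at symmetric points."""
    return (
        groups.skin_left - groups.skin_right,
        groups.int_left - groups.int_right,
    )


def _aggregate(vec: np.ndarray) -> list[float]:
    return [
        float(np.min(vec)),
        float(np.max(vec)),
        float(np.mean(vec)),
        float(np.max(vec) - np.min(vec)),
    ]


def build_feature_vector(tg: Thermogram | TemperatureGroups) -> FeatureVector:
    """Deterministic fixed-length feature vector for one valid exam.

    Reference points T1/T2 do not enter the vector (they serve only as
    measurement controls); Q_max and R are appended so the rule-based
    statistics are available to any downstream classifier.
    """
    groups = tg if isinstance(tg, TemperatureGroups) else group_temperatures(tg)
    grad_right, grad_left = compute_gradients(groups)
    asym_skin, asym_int = compute_asymmetry_vectors(groups)

    q_max, _ = compute_qmax(groups)
    asym = compute_asymmetry(groups)
    r, _ = compute_r(groups, asym)

    derived = {
        "grad_right": grad_right,
        "grad_left": grad_left,
        "asym_skin": asym_skin,
        "asym_int": asym_int,
    }
    raw = {
        "skin_right": groups.skin_right,
        "skin_left": groups.skin_left,
        "int_right": groups.int_right,
        "int_left": groups.int_left,
    }

    values: list[float] = []
    for fam in _VECTOR_FAMILIES:
        values += [float(v) for v in derived[fam]]
    for fam in _VECTOR_FAMILIES:
        values += _aggregate(derived[fam])
    for fam in _RAW_FAMILIES:
        values += _aggregate(raw[fam])
    values += [q_max, r]

    arr = np.asarray(values, dtype=float)
    assert arr.shape == (N_FEATURES,)
    return FeatureVector(
        grad_right=grad_right,
        grad_left=grad_left,
        asym_skin=asym_skin,
        asym_int=asym_int,
        values=arr,
    )
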