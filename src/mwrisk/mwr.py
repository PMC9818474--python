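"""Bilateral MWR screening statistics Q_max and R, and the three-way rule.

Two empirical coefficients summarise one exam:

* ``Q_max`` — focal heating: the larger of (max − mean) over the 20 internal
  breast temperatures and over the 20 skin breast temperatures.  Reference
  points are excluded from these pools.
* ``R`` — thermal asymmetry: per channel, ``k`` is the maximum absolute
  left−right difference at symmetric points.  If the internal and skin
  maxima fall at the same point, ``R = k_int + k_skin``; otherwise the
  larger ``k`` is augmented by the other channel's difference at its point.

Classification: Q_max > 2.0 °C and R > 2.5 °C together suggest malignancy;
both strictly below suggest a benign process; anything else (one-sided
exceedance, boundary equality) is ambiguous and warrants further work-up.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .thermogram import TemperatureGroups, Thermogram, group_temperatures

Q_THRESHOLD = 2.0
R_THRESHOLD = 2.5


class MwrClass(str, enum.Enum):
    MALIGNANT_SUSPECTED = "malignant_suspected"
    BENIGN = "benign"
    AMBIGUOUS = "ambiguous"


class RBranch(str, enum.Enum):
    SAME_POINT = "same_point"
    CROSS_CHANNEL = "cross_channel"


@dataclass
class AsymmetryResult:
    k_int: float
    n_int: int
    k_skin: float
    n_skin: int


@dataclass
class MwrScore:
    """Full bookkeeping of one exam's screening statistics (all °C)."""

    t_max_mw: float
    t_max_ir: float
    t_mean_mw: float
    t_mean_ir: float
    q_max: float
    k_int: float
    n_int: int
    k_skin: float
    n_skin: int
    r: float
    branch: RBranch
    mwr_class: MwrClass

    def to_dict(self) -> dict:
        d = {
            "t_max_mw": self.t_max_mw,
            "t_max_ir": self.t_max_ir,
            "t_mean_mw": self.t_mean_mw,
            "t_mean_ir": self.t_mean_ir,
            "q_max": self.q_max,
            "k_int": self.k_int,
            "n_int": self.n_int,
            "k_skin": self.k_skin,
            "n_skin": self.n_skin,
            "r": self.r,
            "branch": self.branch.value,
            "mwr_class": self.mwr_class.value,
        }
        return d


def compute_qmax(groups: TemperatureGroups) -> tuple[float, dict[str, float]]:
    """Q_max and its components from the 20-element per-channel pools."""
    pool_mw = groups.breast_pool("mw")
    pool_ir = groups.breast_pool("ir")
    t_max_mw = float(np.max(pool_mw))
    t_max_ir = float(np.max(pool_ir))
    t_mean_mw = float(np.mean(pool_mw))
    t_mean_ir = float(np.mean(pool_ir))
    q_max = max(t_max_mw - t_mean_mw, t_max_ir - t_mean_ir)
    return q_max, {
        "t_max_mw": t_max_mw,
        "t_max_ir": t_max_ir,
        "t_mean_mw": t_mean_mw,
        "t_mean_ir": t_mean_ir,
    }


def compute_asymmetry(
    groups: TemperatureGroups, signed: bool = False
) -> AsymmetryResult:
    """Per-channel maximum left-right difference at symmetric points.

    ``signed=False`` (default) uses |left − right| so tumours on either
    side score equally; ``signed=True`` uses the raw left − right maximum.
    Argmax ties break to the lowest point index.
    """
    d_int = groups.int_left - groups.int_right
    d_skin = groups.skin_left - groups.skin_right
    if not signed:
        d_int = np.abs(d_int)
        d_skin = np.abs(d_skin)
    n_int = int(np.argmax(d_int))  # first occurrence = lowest index
    n_skin = int(np.argmax(d_skin))
    return AsymmetryResult(
        k_int=float(d_int[n_int]),
        n_int=n_int,
        k_skin=float(d_skin[n_skin]),
        n_skin=n_skin,
    )


def compute_r(
    groups: TemperatureGroups, asym: AsymmetryResult, signed: bool = False
) -> tuple[float, RBranch]:
    """Combine the two asymmetry coefficients into R.

    Same argmax point on both channels: R = k_int + k_skin.  Different
    points: take the larger k (channel tie broken toward internal) and add
    the *other* channel's left-right difference at that same point.
    """
    if asym.n_int == asym.n_skin:
        return asym.k_int + asym.k_skin, RBranch.SAME_POINT
    if asym.k_int >= asym.k_skin:  # tie -> internal channel
        n = asym.n_int
        other = groups.skin_left[n] - groups.skin_right[n]
        k_star = asym.k_int
    else:
        n = asym.n_skin
        other = groups.int_left[n] - groups.int_right[n]
        k_star = asym.k_skin
    if not signed:
        other = abs(other)
    return float(k_star + other), RBranch.CROSS_CHANNEL


def classify_mwr(
    q_max: float,
    r: float,
    q_threshold: float = Q_THRESHOLD,
    r_threshold: float = R_THRESHOLD,
) -> MwrClass:
    """Three-way decision rule on (Q_max, R).

    Strictly above both thresholds -> malignancy suspected; strictly below
    both -> benign; otherwise ambiguous (boundary equality included, since
    the rule is defined only for strict exceedance).
    """
    if math.isnan(q_max) or math.isnan(r):
        raise ValueError("Q_max and R must be finite")
    if q_max > q_threshold and r > r_threshold:
        return MwrClass.MALIGNANT_SUSPECTED
    if q_max < q_threshold and r < r_threshold:
        return MwrClass.BENIGN
    return MwrClass.AMBIGUOUS


def score_thermogram(
    tg: Thermogram | TemperatureGroups,
    q_threshold: float = Q_THRESHOLD,
    r_threshold: float = R_THRESHOLD,
    signed: bool = False,
) -> MwrScore:
    """End-to-end scoring of one exam: groups -> Q_max, k's, R, class."""
    groups = tg if isinstance(tg, TemperatureGroups) else group_temperatures(tg)
    q_max, comps = compute_qmax(groups)
    asym = compute_asymmetry(groups, signed=signed)
    r, branch = compute_r(groups, asym, signed=signed)
    return MwrScore(
        t_max_mw=comps["t_max_mw"],
        t_max_ir=comps["t_max_ir"],
        t_mean_mw=comps["t_mean_mw"],
        t_mean_ir=comps["t_mean_ir"],
        q_max=q_max,
        k_int=asym.k_int,
        n_int=asym.n_int,
        k_skin=asym.k_skin,
        n_skin=asym.n_skin,
        r=r,
        branch=branch,
        mwr_class=classify_mwr(q_max, r, q_threshold, r_threshold),
    )
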