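"""Data model for one bilateral microwave-radiometry (MWR) breast examination.

An exam records temperature at 10 points per breast (indexed 0-9 on the
standard measurement scheme) plus two axillary reference points T1/T2, each
in two channels: ``mw`` (internal/deep temperature sensed by the microwave
radiometer) and ``ir`` (skin temperature from the infrared sensor) --
44 measurements in total.  Temperatures are degrees Celsius throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

N_POINTS = 10
REF_POINTS = ("T1", "T2")
#: plausibility window for human surface/deep temperature, °C
TEMP_WINDOW = (20.0, 45.0)


@dataclass(frozen=True)
class MeasurementPoint:
    """One location on the examination scheme.

    Breast points carry an integer index 0-9 and a side (``left``/``right``);
    reference points carry the symbolic index ``T1`` or ``T2`` and side
    ``reference``.
    """

    index: int | str
    side: str  # {"left", "right", "reference"}

    def __post_init__(self) -> None:
        if self.side in ("left", "right"):
            if not (isinstance(self.index, int) and 0 <= self.index < N_POINTS):
                raise ValueError(f"breast point index must be 0..9, got {self.index!r}")
        elif self.side == "reference":
            if self.index not in REF_POINTS:
                raise ValueError(f"reference index must be T1/T2, got {self.index!r}")
        else:
            raise ValueError(f"unknown side {self.side!r}")


def _as_vector(values: Sequence[float], n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"expected {n} values, got shape {arr.shape}")
    return arr


@dataclass
class Thermogram:
    """A complete bilateral exam: skin (ir) and internal (mw) channels.

    ``t_*_right`` / ``t_*_left`` are 10-vectors over breast points 0-9;
    ``t_*_ref`` are 2-vectors over the reference points (T1, T2).
    """

    patient_id: str
    visit_date: str  # ISO date
    t_skin_right: np.ndarray
    t_skin_left: np.ndarray
    t_int_right: np.ndarray
    t_int_left: np.ndarray
    t_skin_ref: np.ndarray
    t_int_ref: np.ndarray

    def __post_init__(self) -> None:
        self.t_skin_right = np.asarray(self.t_skin_right, dtype=float)
        self.t_skin_left = np.asarray(self.t_skin_left, dtype=float)
        self.t_int_right = np.asarray(self.t_int_right, dtype=float)
        self.t_int_left = np.asarray(self.t_int_left, dtype=float)
        self.t_skin_ref = np.asarray(self.t_skin_ref, dtype=float)
        self.t_int_ref = np.asarray(self.t_int_ref, dtype=float)

    def swap_breasts(self) -> "Thermogram":
        """Mirror the exam left<->right (reference points unchanged)."""
        return replace(
            self,
            t_skin_right=self.t_skin_left.copy(),
            t_skin_left=self.t_skin_right.copy(),
            t_int_right=self.t_int_left.copy(),
            t_int_left=self.t_int_right.copy(),
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


@dataclass
class TemperatureGroups:
    """The six named temperature groups of one exam.

    skin (ir): right breast, left breast, reference; internal (mw): same --
    exactly partitioning the 44 measurements.
    """

    skin_right: np.ndarray
    skin_left: np.ndarray
    skin_ref: np.ndarray
    int_right: np.ndarray
    int_left: np.ndarray
    int_ref: np.ndarray

    def breast_pool(self, channel: str) -> np.ndarray:
        """All 20 breast temperatures of one channel (reference excluded)."""
        if channel == "mw":
            return np.concatenate([self.int_right, self.int_left])
        if channel == "ir":
            return np.concatenate([self.skin_right, self.skin_left])
        raise ValueError(f"unknown channel {channel!r}")


def validate_thermogram(
    tg: Thermogram, window: tuple[float, float] = TEMP_WINDOW
) -> ValidationReport:
    """Check completeness and plausibility of every measurement.

    Returns a report listing violations (wrong vector length, NaN, value
    outside ``window``); the exam is valid iff the list is empty.
    """
    report = ValidationReport()
    lo, hi = window
    fields = [
        ("t_skin_right", tg.t_skin_right, N_POINTS),
        ("t_skin_left", tg.t_skin_left, N_POINTS),
        ("t_int_right", tg.t_int_right, N_POINTS),
        ("t_int_left", tg.t_int_left, N_POINTS),
        ("t_skin_ref", tg.t_skin_ref, len(REF_POINTS)),
        ("t_int_ref", tg.t_int_ref, len(REF_POINTS)),
    ]
    for name, vec, n in fields:
        if vec.shape != (n,):
            report.violations.append(f"{name}: length {vec.size} != {n}")
            continue
        for i, v in enumerate(vec):
            if math.isnan(v):
                report.violations.append(f"{name}[{i}]: missing value (NaN)")
            elif not (lo <= v <= hi):
                report.violations.append(
                    f"{name}[{i}]: {v:.2f} °C out of window [{lo}, {hi}]"
                )
    return report


def group_temperatures(tg: Thermogram) -> TemperatureGroups:
    """Partition a valid exam into the six named temperature groups.

    Raises ``ValueError`` if the exam fails validation.
    """
    report = validate_thermogram(tg)
    if not report.valid:
        raise ValueError("invalid thermogram: " + "; ".join(report.violations))
    return TemperatureGroups(
        skin_right=tg.t_skin_right.copy(),
        skin_left=tg.t_skin_left.copy(),
        skin_ref=tg.t_skin_ref.copy(),
        int_right=tg.t_int_right.copy(),
        int_left=tg.t_int_left.copy(),
        int_ref=tg.t_int_ref.copy(),
    )


def from_groups(
    groups: TemperatureGroups, patient_id: str = "anon", visit_date: str = "1970-01-01"
) -> Thermogram:
    """Inverse of :func:`group_temperatures` (round-trip identity)."""
    return Thermogram(
        patient_id=patient_id,
        visit_date=visit_date,
        t_skin_right=groups.skin_right.copy(),
        t_skin_left=groups.skin_left.copy(),
        t_int_right=groups.int_right.copy(),
        t_int_left=groups.int_left.copy(),
        t_skin_ref=groups.skin_ref.copy(),
        t_int_ref=groups.int_ref.copy(),
    )
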