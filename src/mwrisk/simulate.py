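"""Synthetic thermograms, miRNA panels and cohorts.

No raw patient temperatures or panel measurements are publicly available,
so every pipeline stage is exercised on synthetic data built to carry the
conceptual signatures of the two patient groups:

* healthy — smooth temperature fields: skin around 31.5 °C, internal around
  34.5 °C, i.i.d. Gaussian noise (sd 0.25 °C), skin spread well under 2 °C,
  no hot area, normal internal-minus-skin gradient, left/right symmetry;
* high risk — a focal hot area: internal temperature elevated by
  ``focus_delta_int`` at one point (half that at adjacent points) on one
  side, with the skin elevated by ``focus_delta_int − focus_gradient_reduction``
  at the matching points.  This produces the high skin spread (>2 °C),
  the hot area, the locally reduced internal gradient and the inter-breast
  asymmetry that characterise the at-risk thermogram.

Panel profiles place norm concentrations at published healthy-reference
geometric means with lognormal dispersion; pathology concentrations apply
per-marker fold multipliers in each marker's risk direction.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import build_feature_vector
from .mirna import PANEL, MarkerMeasurement, RiskDirection
from .thermogram import N_POINTS, Thermogram


@dataclass(frozen=True)
class ThermogramProfile:
    profile_kind: str  # {"healthy", "high_risk"}
    skin_base: float = 31.5
    int_base: float = 34.5
    noise_sd: float = 0.25
    focus_point: int | None = None  # None -> drawn uniformly per exam (high_risk)
    focus_side: str = "left"
    focus_delta_int: float = 3.0
    focus_gradient_reduction: float = 1.0

    def __post_init__(self) -> None:
        if self.profile_kind not in ("healthy", "high_risk"):
            raise ValueError(f"unknown profile kind {self.profile_kind!r}")
        if self.profile_kind == "high_risk" and self.focus_delta_int <= 0:
            raise ValueError("high_risk profile requires focus_delta_int > 0")
        if self.focus_side not in ("left", "right"):
            raise ValueError(f"focus_side must be left/right, got {self.focus_side!r}")
        if self.focus_point is not None and not 0 <= self.focus_point < N_POINTS:
            raise ValueError("focus_point must be in 0..9")


HEALTHY = ThermogramProfile(profile_kind="healthy")
HIGH_RISK = ThermogramProfile(profile_kind="high_risk")


def _table_multipliers() -> dict[str, float]:
    # pathology/norm ratios of a published clinical panel, expressed in each
    # marker's risk direction (protective markers: norm/pathology)
    conc = {
        "mir-155": (28294, 202238),
        "mir-199a-3p": (104809, 324654),
        "mir-222-3p": (159928, 88908),
        "let-7a-5p": (13327568, 2665531),
        "mir-196a-2": (1665957, 333191),
        "mir-106a-5p": (380633, 76126),
        "mir-21-5p": (22209402, 111047010),
        "mir-137": (555235050, 111047010),
    }
    out = {}
    for m in PANEL:
        norm, path = conc[m.name]
        out[m.name] = (
            path / norm if m.risk_direction is RiskDirection.UP_IS_RISK else norm / path
        )
    return out


#: healthy-reference geometric mean concentration per marker, copies/μL
NORM_MEANS: dict[str, float] = {
    "mir-155": 28294.0,
    "mir-199a-3p": 104809.0,
    "mir-222-3p": 159928.0,
    "let-7a-5p": 13327568.0,
    "mir-196a-2": 1665957.0,
    "mir-106a-5p": 380633.0,
    "mir-21-5p": 22209402.0,
    "mir-137": 555235050.0,
}


@dataclass(frozen=True)
class PanelProfile:
    risk_level: str  # {"low", "high"}
    norm_means: dict[str, float] = field(default_factory=lambda: dict(NORM_MEANS))
    lognormal_sd: float = 0.1  # sd of log-concentration noise
    risk_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.risk_level not in ("low", "high"):
            raise ValueError(f"unknown risk level {self.risk_level!r}")
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be >= 0")

    def multiplier(self, marker: str) -> float:
        if marker in self.risk_multipliers:
            return self.risk_multipliers[marker]
        return 1.0 if self.risk_level == "low" else _table_multipliers()[marker]


LOW_PANEL = PanelProfile(risk_level="low")
HIGH_PANEL = PanelProfile(risk_level="high")


def generate_thermogram(
    profile: ThermogramProfile,
    seed: int | np.random.Generator,
    patient_id: str = "sim",
    visit_date: str = "2022-01-01",
) -> Thermogram:
    """Draw one exam from a profile, reproducibly for an integer seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    skin_r = rng.normal(profile.skin_base, profile.noise_sd, N_POINTS)
    skin_l = rng.normal(profile.skin_base, profile.noise_sd, N_POINTS)
    int_r = rng.normal(profile.int_base, profile.noise_sd, N_POINTS)
    int_l = rng.normal(profile.int_base, profile.noise_sd, N_POINTS)
    skin_ref = rng.normal(profile.skin_base, profile.noise_sd, 2)
    int_ref = rng.normal(profile.int_base, profile.noise_sd, 2)

    if profile.profile_kind == "high_risk":
        focus = (
            profile.focus_point
            if profile.focus_point is not None
            else int(rng.integers(0, N_POINTS))
        )
        d_int = profile.focus_delta_int
        d_skin = d_int - profile.focus_gradient_reduction
        bump_int = np.zeros(N_POINTS)
        bump_skin = np.zeros(N_POINTS)
        bump_int[focus] = d_int
        bump_skin[focus] = d_skin
        for nb in (focus - 1, focus + 1):  # half-amplitude shoulder points
            if 0 <= nb < N_POINTS:
                bump_int[nb] = d_int / 2.0
                bump_skin[nb] = d_skin / 2.0
        if profile.focus_side == "left":
            int_l += bump_int
            skin_l += bump_skin
        else:
            int_r += bump_int
            skin_r += bump_skin

    return Thermogram(
        patient_id=patient_id,
        visit_date=visit_date,
        t_skin_right=skin_r,
        t_skin_left=skin_l,
        t_int_right=int_r,
        t_int_left=int_l,
        t_skin_ref=skin_ref,
        t_int_ref=int_ref,
    )


def generate_panel(
    profile: PanelProfile, seed: int | np.random.Generator
) -> list[MarkerMeasurement]:
    """Draw one 8-marker panel measurement set from a profile."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for marker in PANEL:
        mean = profile.norm_means[marker.name]
        norm = mean * float(np.exp(rng.normal(0.0, profile.lognormal_sd)))
        m = profile.multiplier(marker.name)
        fold = m if marker.risk_direction is RiskDirection.UP_IS_RISK else 1.0 / m
        path = norm * fold * float(np.exp(rng.normal(0.0, profile.lognormal_sd)))
        out.append(
            MarkerMeasurement(marker=marker, norm_conc=norm, path_conc=path)
        )
    return out


@dataclass
class Cohort:
    thermograms: list[Thermogram]
    labels: list[str]  # "low" / "high" per exam
    features: np.ndarray  # (n, 74)


def generate_cohort(
    n_low: int,
    n_high: int,
    seed: int,
    low_profile: ThermogramProfile = HEALTHY,
    high_profile: ThermogramProfile = HIGH_RISK,
) -> Cohort:
    """Labelled synthetic cohort with feature vectors, ~8:1 imbalance by default.

    High-risk exams draw focus point and side at random per patient unless
    the profile pins them.
    """
    if n_low < 1 or n_high < 1:
        raise ValueError("need at least one exam per class")
    rng = np.random.default_rng(seed)
    thermograms: list[Thermogram] = []
    labels: list[str] = []
    for i in range(n_low):
        thermograms.append(
            generate_thermogram(low_profile, rng, patient_id=f"low-{i:04d}")
        )
        labels.append("low")
    for i in range(n_high):
        prof = high_profile
        if prof.focus_point is None:
            prof = replace(
                prof,
                focus_point=int(rng.integers(0, N_POINTS)),
                focus_side=("left", "right")[int(rng.integers(0, 2))],
            )
        thermograms.append(generate_thermogram(prof, rng, patient_id=f"high-{i:04d}"))
        labels.append("high")
    X = np.vstack([build_feature_vector(tg).values for tg in thermograms])
    return Cohort(thermograms=thermograms, labels=labels, features=X)
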