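"""8-marker circulating miRNA oncopanel risk scoring.

Each marker has a risk direction: oncogenic markers (miR-155, miR-21-5p,
miR-222-3p, miR-199a-3p) signal risk when *elevated* relative to the norm;
protective markers (let-7a-5p, miR-196a-2, miR-106a-5p, miR-137) signal
risk when *reduced*.  The fold change (pathology / norm concentration,
copies/μL) is converted into an effective-change magnitude in the marker's
risk direction, then binned:

    magnitude < 1.5        -> score 0 (norm)
    1.5 <= magnitude < 2   -> score 1 (slight)
    2   <= magnitude < 5   -> score 2 (moderate)
    magnitude >= 5         -> score 3 (pronounced/significant)

The panel risk factor is the sum of the eight scores (0-24); sums below the
cutoff (default 5) are categorised low risk, at or above it high risk.
Measurements may instead carry a categorical expression label, mapped to
the same 0-3 ordinal scale.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

DEFAULT_BANDS = (1.5, 2.0, 5.0)
DEFAULT_CUTOFF = 5


class RiskDirection(str, enum.Enum):
    UP_IS_RISK = "up_is_risk"
    DOWN_IS_RISK = "down_is_risk"


@dataclass(frozen=True)
class MarkerDef:
    name: str  # canonical, e.g. "mir-155"
    risk_direction: RiskDirection


#: the eight-marker panel with each marker's risk-relevant direction
PANEL: tuple[MarkerDef, ...] = (
    MarkerDef("mir-155", RiskDirection.UP_IS_RISK),
    MarkerDef("mir-199a-3p", RiskDirection.UP_IS_RISK),
    MarkerDef("mir-222-3p", RiskDirection.UP_IS_RISK),
    MarkerDef("let-7a-5p", RiskDirection.DOWN_IS_RISK),
    MarkerDef("mir-196a-2", RiskDirection.DOWN_IS_RISK),
    MarkerDef("mir-106a-5p", RiskDirection.DOWN_IS_RISK),
    MarkerDef("mir-21-5p", RiskDirection.UP_IS_RISK),
    MarkerDef("mir-137", RiskDirection.DOWN_IS_RISK),
)

PANEL_BY_NAME: dict[str, MarkerDef] = {m.name: m for m in PANEL}

# printed marker names are inconsistent across sources ("Hsa-", "Has-",
# "Micro-RNA-", case); "mir-196a-3p" appears in the 199a-3p panel slot in
# some tables and is accepted as an alias for it.
_ALIASES = {"mir-196a-3p": "mir-199a-3p"}

_PREFIX_RE = re.compile(r"^(hsa-|has-)?(micro-rna-|microrna-|micro-|mirna-|mir-)?")


def canonical_marker_name(raw: str) -> str:
    """Normalise a printed marker name to its canonical panel form."""
    s = raw.strip().lower()
    if s.startswith(("hsa-let", "has-let", "let")):
        s = re.sub(r"^(hsa-|has-)", "", s)
    else:
        s = "mir-" + _PREFIX_RE.sub("", s)
    return _ALIASES.get(s, s)


@dataclass
class MarkerMeasurement:
    """One marker's measurement: concentrations and/or an expression label."""

    marker: MarkerDef
    norm_conc: float | None = None
    path_conc: float | None = None
    label: str | None = None

    @property
    def fold(self) -> float:
        if self.norm_conc is None or self.path_conc is None:
            raise ValueError(f"{self.marker.name}: no concentrations recorded")
        return fold_change(self.norm_conc, self.path_conc, rounded=False)


@dataclass
class PanelResult:
    scores: dict[str, int]  # canonical marker name -> 0..3
    risk_sum: int
    category: str  # {"low", "high"}


def fold_change(norm_conc: float, path_conc: float, rounded: bool = True) -> float:
    """Pathology/norm concentration ratio.

    The exact ratio is retained internally; reported values are rounded
    half-up to one decimal (matching clinical reporting convention).
    """
    if norm_conc <= 0 or path_conc <= 0:
        raise ValueError("concentrations must be positive")
    ratio = path_conc / norm_conc
    if not rounded:
        return ratio
    return float(Decimal(repr(ratio)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def effective_change(fold: float, direction: RiskDirection) -> float:
    """Fold change as a magnitude >= 1 in the marker's risk direction.

    A change *against* the risk direction (e.g. an oncogenic marker going
    down) carries no risk signal and collapses to magnitude 1.
    """
    if fold <= 0:
        raise ValueError("fold change must be positive")
    if direction is RiskDirection.UP_IS_RISK:
        return fold if fold >= 1.0 else 1.0
    return 1.0 / fold if fold <= 1.0 else 1.0


def score_marker(magnitude: float, bands: tuple[float, float, float] = DEFAULT_BANDS) -> int:
    """Bin an effective-change magnitude into the ordinal 0-3 risk score.

    Bands are half-open [1.5, 2), [2, 5), [5, inf): a boundary value falls
    in the upper band.
    """
    slight, moderate, pronounced = bands
    if magnitude >= pronounced:
        return 3
    if magnitude >= moderate:
        return 2
    if magnitude >= slight:
        return 1
    return 0


_LABEL_SCORES = {
    "norm": 0,
    "normal": 0,
    "slight": 1,
    "slight increase": 1,
    "moderate": 2,
    "moderate increase": 2,
    "pronounced": 3,
    "pronounced increase": 3,
    "significant": 3,
    "significant increase": 3,
}


def label_to_score(label: str) -> int:
    """Map a categorical expression label (e.g. "Pronounced increase—3") to 0-3.

    A trailing em/en-dash or hyphen followed by the explicit score digit,
    as printed in clinical tables, is stripped before lookup.
    """
    s = label.strip().lower()
    s = re.sub(r"\s*[—–-]\s*[0-3]$", "", s)
    try:
        return _LABEL_SCORES[s]
    except KeyError:
        raise ValueError(f"unknown expression label {label!r}") from None


def score_measurement(
    m: MarkerMeasurement, bands: tuple[float, float, float] = DEFAULT_BANDS
) -> int:
    """Score one measurement: label path if a label is present, else the
    concentration path (fold change -> effective magnitude -> band)."""
    if m.label is not None:
        return label_to_score(m.label)
    return score_marker(effective_change(m.fold, m.marker.risk_direction), bands)


def panel_risk(
    measurements: list[MarkerMeasurement],
    low_high_cutoff: int = DEFAULT_CUTOFF,
    bands: tuple[float, float, float] = DEFAULT_BANDS,
) -> PanelResult:
    """Score a complete 8-marker panel and categorise the summed risk factor.

    Requires exactly the eight panel markers, each once.
    """
    names = [m.marker.name for m in measurements]
    missing = sorted(set(PANEL_BY_NAME) - set(names))
    extra = sorted(set(names) - set(PANEL_BY_NAME))
    if missing or extra or len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        parts = []
        if missing:
            parts.append(f"missing markers: {missing}")
        if extra:
            parts.append(f"unknown markers: {extra}")
        if dup:
            parts.append(f"duplicate markers: {dup}")
        raise ValueError("invalid panel — " + "; ".join(parts))
    scores = {m.marker.name: score_measurement(m, bands) for m in measurements}
    risk_sum = sum(scores.values())
    category = "low" if risk_sum < low_high_cutoff else "high"
    return PanelResult(scores=scores, risk_sum=risk_sum, category=category)


def panel_from_labels(labels: dict[str, str]) -> list[MarkerMeasurement]:
    """Build panel measurements from {printed marker name: expression label}."""
    out = []
    for raw, label in labels.items():
        name = canonical_marker_name(raw)
        if name not in PANEL_BY_NAME:
            raise ValueError(f"unknown panel marker {raw!r}")
        out.append(MarkerMeasurement(marker=PANEL_BY_NAME[name], label=label))
    return out


def panel_from_concentrations(conc: dict[str, tuple[float, float]]) -> list[MarkerMeasurement]:
    """Build panel measurements from {printed name: (norm, pathology)} copies/μL."""
    out = []
    for raw, (norm, path) in conc.items():
        name = canonical_marker_name(raw)
        if name not in PANEL_BY_NAME:
            raise ValueError(f"unknown panel marker {raw!r}")
        out.append(
            MarkerMeasurement(marker=PANEL_BY_NAME[name], norm_conc=norm, path_conc=path)
        )
    return out
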