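"""Run configuration: every tunable threshold and generator default in one
YAML-serialisable object, so a clinical deployment can pin and audit them."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import AGGREGATES


@dataclass
class RunConfig:
    # decision thresholds, °C
    q_threshold: float = 2.0
    r_threshold: float = 2.5
    # miRNA band edges (slight/moderate/pronounced) and panel cutoff
    mirna_bands: tuple[float, float, float] = (1.5, 2.0, 5.0)
    mirna_cutoff: int = 5
    # asymmetry sign convention: absolute (side-symmetric) or signed (left-right)
    signed_asymmetry: bool = False
    # feature-space aggregate list (versioned)
    aggregates: tuple[str, ...] = AGGREGATES
    # synthetic generator defaults, °C
    skin_base: float = 31.5
    int_base: float = 34.5
    noise_sd: float = 0.25
    focus_delta_int: float = 3.0
    focus_gradient_reduction: float = 1.0
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["mirna_bands"] = list(self.mirna_bands)
        d["aggregates"] = list(self.aggregates)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        d["mirna_bands"] = tuple(d["mirna_bands"])
        d["aggregates"] = tuple(d["aggregates"])
        return cls(**d)
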