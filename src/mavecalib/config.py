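"""Analysis configuration: thresholds, zones, CI level, seed.

Defaults are the calibrated gene-specific zones: AlphaMissense ≤0.65/≥0.75,
ΔΔG ≤+1.5/≥+2.5 kcal/mol (both template variants), BayesDel ≤0.15/≥0.28.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .classify import FunctionalThresholds, RsaBinning
from .core import ValidationError
from .lr import ThreeZone, ZoneDirection

__all__ = ["AnalysisConfig", "default_zones"]


def default_zones() -> dict[str, ThreeZone]:
    return {
        "AM": ThreeZone("AM", 0.65, 0.75),
        "DDG_AF": ThreeZone("DDG_AF", 1.5, 2.5),
        "DDG_PDB": ThreeZone("DDG_PDB", 1.5, 2.5),
        "BD": ThreeZone("BD", 0.15, 0.28),
    }


@dataclass
class AnalysisConfig:
    functional_thresholds: FunctionalThresholds = field(
        default_factory=FunctionalThresholds
    )
    rsa_binning: RsaBinning = field(default_factory=RsaBinning)
    zones: dict[str, ThreeZone] = field(default_factory=default_zones)
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be strictly between 0 and 1")

    def to_dict(self) -> dict:
        return {
            "functional_thresholds": {
                "func_min_exclusive": self.functional_thresholds.func_min_exclusive,
                "lof_max_exclusive": self.functional_thresholds.lof_max_exclusive,
            },
            "rsa_binning": {
                "buried_max_exclusive": self.rsa_binning.buried_max_exclusive,
                "partial_max_inclusive": self.rsa_binning.partial_max_inclusive,
            },
            "zones": {
                tool: {
                    "benign_max": z.benign_max,
                    "path_min": z.path_min,
                    "direction": z.direction.value,
                }
                for tool, z in self.zones.items()
            },
            "ci_level": self.ci_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        ft = data.get("functional_thresholds", {})
        rb = data.get("rsa_binning", {})
        zones = {
            tool: ThreeZone(
                tool,
                spec["benign_max"],
                spec["path_min"],
                ZoneDirection(spec.get("direction", "HIGHER_IS_PATHOGENIC")),
            )
            for tool, spec in data.get("zones", {}).items()
        }
        return cls(
            functional_thresholds=FunctionalThresholds(**ft) if ft else FunctionalThresholds(),
            rsa_binning=RsaBinning(**rb) if rb else RsaBinning(),
            zones=zones or default_zones(),
            ci_level=data.get("ci_level", 0.95),
            seed=data.get("seed", 0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
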