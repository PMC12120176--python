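"""MAVE functional-class assignment and RSA binning.

Functional classes follow fixed MAVE score cutoffs: FUNC (functional) above
−0.748, LoF (loss of function) below −1.328, INT (intermediate) in between.
Scores landing exactly on a cutoff go to INT — the strict published
inequalities leave the boundaries undefined, and INT is the conservative,
evidence-free class. Residues are binned by relative solvent accessibility
into buried (RSA < 30%), partially buried (30% ≤ RSA ≤ 60%) and exposed
(RSA > 60%); boundary values go to PARTIAL, matching the closed interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .core import FunctionalClass, ScoreTable, ValidationError, VariantRecord

__all__ = [
    "FunctionalThresholds",
    "RsaBin",
    "RsaBinning",
    "assign_functional_class",
    "assign_rsa_bin",
    "classify_table",
    "build_analysis_cohort",
]


@dataclass(frozen=True)
class FunctionalThresholds:
    """MAVE score cutoffs separating FUNC / INT / LoF."""

    func_min_exclusive: float = -0.748
    lof_max_exclusive: float = -1.328

    def __post_init__(self) -> None:
        if not self.lof_max_exclusive < self.func_min_exclusive:
            raise ValidationError(
                "lof_max_exclusive must be below func_min_exclusive"
            )


class RsaBin(str, Enum):
    BURIED = "BURIED"
    PARTIAL = "PARTIAL"
    EXPOSED = "EXPOSED"


@dataclass(frozen=True)
class RsaBinning:
    """RSA (%) cutpoints for buried / partially buried / exposed residues."""

    buried_max_exclusive: float = 30.0
    partial_max_inclusive: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.buried_max_exclusive < self.partial_max_inclusive:
            raise ValidationError("require 0 < buried cutoff < partial cutoff")


def assign_functional_class(
    score: float, thresholds: FunctionalThresholds = FunctionalThresholds()
) -> FunctionalClass:
    """Map one MAVE score to LOF / INT / FUNC (boundaries inclusive to INT)."""
    if not math.isfinite(score):
        raise ValidationError(f"non-finite MAVE score: {score}")
    if score > thresholds.func_min_exclusive:
        return FunctionalClass.FUNC
    if score < thresholds.lof_max_exclusive:
        return FunctionalClass.LOF
    return FunctionalClass.INT


def assign_rsa_bin(rsa: float, binning: RsaBinning = RsaBinning()) -> RsaBin:
    """Map one RSA percentage to BURIED / PARTIAL / EXPOSED."""
    if not rsa >= 0:
        raise ValidationError(f"rsa must be >= 0, got {rsa}")
    if rsa < binning.buried_max_exclusive:
        return RsaBin.BURIED
    if rsa <= binning.partial_max_inclusive:
        return RsaBin.PARTIAL
    return RsaBin.EXPOSED


def classify_table(
    table: ScoreTable, thresholds: FunctionalThresholds = FunctionalThresholds()
) -> ScoreTable:
    """Return a copy of ``table`` with functional_class assigned on every record."""
    records = [
        replace(r, functional_class=assign_functional_class(r.mave_score, thresholds))
        for r in table
    ]
    return ScoreTable(records, provenance=table.provenance)


def build_analysis_cohort(table: ScoreTable) -> tuple[ScoreTable, dict[str, int]]:
    """Drop INT variants, keeping the LoF/FUNC calibration cohort.

    Intermediate-activity variants are excluded from likelihood-ratio
    calibration because partial activity has no clear disease association;
    the returned counts report what was kept and dropped.
    """
    unassigned = [
        r.variant_id for r in table if r.functional_class is FunctionalClass.UNASSIGNED
    ]
    if unassigned:
        raise ValidationError(
            f"{len(unassigned)} record(s) lack a functional class "
            f"(first: {unassigned[0]}); run classify_table first"
        )
    keep = {FunctionalClass.LOF, FunctionalClass.FUNC}
    cohort = table.subset(
        lambda r: r.functional_class in keep, provenance=table.provenance
    )
    counts = {cls.value: n for cls, n in table.class_counts().items() if n}
    counts["kept"] = len(cohort)
    counts["dropped_int"] = counts.get("INT", 0)
    return cohort, counts


def rsa_bin_of(record: VariantRecord, binning: RsaBinning = RsaBinning()) -> RsaBin | None:
    """RSA bin of a record, or None when RSA is unavailable."""
    if record.rsa is None:
        return None
    return assign_rsa_bin(record.rsa, binning)
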