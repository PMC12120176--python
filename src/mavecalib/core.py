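"""Core domain types for score-calibration cohorts.

A cohort is a :class:`ScoreTable` of :class:`VariantRecord` objects, each
describing one missense variant: a functional score from a multiplexed assay
of variant effect (MAVE), the relative solvent accessibility (RSA) of the
mutated residue, and a sparse map of computational scores (AlphaMissense-like
pathogenicity probabilities in [0, 1], FoldX-style folding ΔΔG in kcal/mol,
meta-predictor scores).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterator

import pandas as pd

__all__ = [
    "Domain",
    "FunctionalClass",
    "VariantRecord",
    "ScoreTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class Domain(str, Enum):
    """Protein functional domain harbouring the variant."""

    RING = "RING"
    BRCT = "BRCT"
    OTHER = "OTHER"


class FunctionalClass(str, Enum):
    """MAVE functional class: loss of function, intermediate, or functional."""

    LOF = "LOF"
    INT = "INT"
    FUNC = "FUNC"
    UNASSIGNED = "UNASSIGNED"


@dataclass
class VariantRecord:
    """One missense variant with its functional and computational annotations.

    Parameters
    ----------
    variant_id
        Unique identifier, typically protein-level HGVS (e.g. ``p.Cys61Gly``).
    mave_score
        MAVE functional score (unitless; more negative = more impaired).
    domain
        Functional domain label.
    rsa
        Relative solvent accessibility of the target residue, in percent.
        Values above 100 are permitted (normalised accessibility can exceed
        100%); ``None`` means not available.
    functional_class
        MAVE class; ``UNASSIGNED`` until classification runs.
    scores
        Sparse tool-name → score map. Missing tools are absent keys, never
        sentinel numbers.
    """

    variant_id: str
    mave_score: float
    domain: Domain = Domain.OTHER
    rsa: float | None = None
    functional_class: FunctionalClass = FunctionalClass.UNASSIGNED
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if self.rsa is not None and not (self.rsa >= 0):
            raise ValidationError(
                f"{self.variant_id}: rsa must be >= 0, got {self.rsa}"
            )
        for tool, value in self.scores.items():
            if not math.isfinite(value):
                raise ValidationError(
                    f"{self.variant_id}: non-finite score for tool {tool!r}"
                )

    def with_class(self, cls: FunctionalClass) -> "VariantRecord":
        return replace(self, functional_class=cls)


@dataclass
class ScoreTable:
    """Ordered collection of variant records with unique identifiers."""

    records: list[VariantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        counts = Counter(r.variant_id for r in self.records)
        dupes = sorted(vid for vid, n in counts.items() if n > 1)
        if dupes:
            raise ValidationError(f"duplicate variant_id(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def subset(
        self, predicate: Callable[[VariantRecord], bool], provenance: str = ""
    ) -> "ScoreTable":
        """New table holding the records for which ``predicate`` is true."""
        return ScoreTable(
            [r for r in self.records if predicate(r)],
            provenance=provenance or self.provenance,
        )

    def class_counts(self) -> dict[FunctionalClass, int]:
        counts = Counter(r.functional_class for r in self.records)
        return {cls: counts.get(cls, 0) for cls in FunctionalClass}

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to a DataFrame; one column per tool seen anywhere."""
        tools = sorted({t for r in self.records for t in r.scores})
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "variant_id": r.variant_id,
                "domain": r.domain.value,
                "mave_score": r.mave_score,
                "functional_class": r.functional_class.value,
                "rsa": r.rsa,
            }
            for t in tools:
                row[t] = r.scores.get(t)
            rows.append(row)
        return pd.DataFrame(rows)
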