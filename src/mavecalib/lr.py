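"""Three-zone likelihood-ratio calibration of computational scores.

The central quantity is the likelihood ratio of a score zone,

    LR(zone) = P(zone | LoF) / P(zone | FUNC),

with LoF variants serving as the pathogenic proxy class and FUNC variants as
the benign proxy. Scores are split by two thresholds into a benignity zone,
an uninformative (gray) zone where no evidence code applies, and a
pathogenicity zone. log2 LR maps onto the point-based ACMG/AMP evidence
scheme: points 1, 2, 4, 8 correspond to Supporting, Moderate, Strong and
Very Strong evidence, signed toward pathogenicity (PP3) or benignity (BP4).

Confidence intervals use the asymptotic interval on ln LR,

    ln LR ± z * sqrt((1 − p1)/x1 + (1 − p2)/x2),

the standard large-sample interval for a ratio of two binomial proportions
(Simel et al. style), converted to the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations_with_replacement

from scipy.stats import norm

from .core import FunctionalClass, ScoreTable, ValidationError

__all__ = [
    "ZoneDirection",
    "ThreeZone",
    "Zone",
    "ZoneCounts",
    "LrEstimate",
    "EvidenceDirection",
    "StrengthTier",
    "EvidenceStrength",
    "ToolReport",
    "count_zones",
    "lr_pathogenic",
    "lr_benign",
    "log2_lr_ci",
    "map_strength",
    "evaluate_tool",
    "search_thresholds",
    "SearchOutcome",
]

LN2 = math.log(2.0)


class ZoneDirection(str, Enum):
    HIGHER_IS_PATHOGENIC = "HIGHER_IS_PATHOGENIC"
    LOWER_IS_PATHOGENIC = "LOWER_IS_PATHOGENIC"


class Zone(str, Enum):
    BENIGN = "BENIGN"
    GRAY = "GRAY"
    PATH = "PATH"


@dataclass(frozen=True)
class ThreeZone:
    """Benignity / uninformative / pathogenicity score zones for one tool.

    For a HIGHER_IS_PATHOGENIC tool, scores ≤ ``benign_max`` carry benignity
    evidence and scores ≥ ``path_min`` pathogenicity evidence; the open
    interval between them is uninformative. ``benign_max == path_min`` gives
    an empty gray zone (the boundary score then counts as benign, matching
    the ≤ rule). LOWER_IS_PATHOGENIC mirrors the comparisons.
    """

    tool: str
    benign_max: float
    path_min: float
    direction: ZoneDirection = ZoneDirection.HIGHER_IS_PATHOGENIC

    def __post_init__(self) -> None:
        if self.direction is ZoneDirection.HIGHER_IS_PATHOGENIC:
            if not self.benign_max <= self.path_min:
                raise ValidationError(
                    f"{self.tool}: benign_max ({self.benign_max}) must be "
                    f"<= path_min ({self.path_min})"
                )
        else:
            if not self.benign_max >= self.path_min:
                raise ValidationError(
                    f"{self.tool}: benign_max ({self.benign_max}) must be "
                    f">= path_min ({self.path_min}) for LOWER_IS_PATHOGENIC"
                )

    def zone_of(self, score: float) -> Zone:
        if self.direction is ZoneDirection.HIGHER_IS_PATHOGENIC:
            if score <= self.benign_max:
                return Zone.BENIGN
            if score >= self.path_min:
                return Zone.PATH
        else:
            if score >= self.benign_max:
                return Zone.BENIGN
            if score <= self.path_min:
                return Zone.PATH
        return Zone.GRAY


@dataclass
class ZoneCounts:
    """LoF and FUNC tallies per score zone."""

    lof_benign: int = 0
    lof_gray: int = 0
    lof_path: int = 0
    func_benign: int = 0
    func_gray: int = 0
    func_path: int = 0
    n_excluded_missing: int = 0

    @property
    def n_lof(self) -> int:
        return self.lof_benign + self.lof_gray + self.lof_path

    @property
    def n_func(self) -> int:
        return self.func_benign + self.func_gray + self.func_path

    @property
    def gray_fraction(self) -> float:
        total = self.n_lof + self.n_func
        return (self.lof_gray + self.func_gray) / total if total else 0.0


@dataclass
class LrEstimate:
    """A likelihood ratio with its log2 value and asymptotic CI.

    ``x1/n1`` is the LoF-class (numerator) proportion, ``x2/n2`` the
    FUNC-class (denominator) proportion. When a zero count forced the
    Haldane–Anscombe +0.5 correction, ``corrected`` is set.
    """

    lr: float
    log2_lr: float
    ci95_log2: tuple[float, float]
    x1: int
    n1: int
    x2: int
    n2: int
    level: float = 0.95
    corrected: bool = False


class EvidenceDirection(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    BENIGN = "BENIGN"
    NONE = "NONE"


class StrengthTier(str, Enum):
    NONE = "NONE"
    SUPPORTING = "SUPPORTING"
    MODERATE = "MODERATE"
    STRONG = "STRONG"
    VERY_STRONG = "VERY_STRONG"


_POINTS_TO_TIER = {
    0: StrengthTier.NONE,
    1: StrengthTier.SUPPORTING,
    2: StrengthTier.MODERATE,
    4: StrengthTier.STRONG,
    8: StrengthTier.VERY_STRONG,
}


@dataclass(frozen=True)
class EvidenceStrength:
    direction: EvidenceDirection
    strength: StrengthTier
    points: int  # signed: pathogenic +, benign −

    def __post_init__(self) -> None:
        none_like = (
            self.direction is EvidenceDirection.NONE,
            self.strength is StrengthTier.NONE,
            self.points == 0,
        )
        if any(none_like) and not all(none_like):
            raise ValidationError("direction NONE ⇔ strength NONE ⇔ points 0")


def count_zones(cohort: ScoreTable, zone: ThreeZone) -> ZoneCounts:
    """Tally LoF/FUNC variants per zone of ``zone.tool``.

    Records missing the tool's score are excluded and reported in
    ``n_excluded_missing``; the cohort must contain only LOF/FUNC records.
    """
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    counts = ZoneCounts()
    for record in cohort:
        if record.functional_class not in (FunctionalClass.LOF, FunctionalClass.FUNC):
            raise ValidationError(
                f"{record.variant_id}: cohort must contain only LOF/FUNC records "
                f"(found {record.functional_class.value}); run build_analysis_cohort"
            )
        score = record.scores.get(zone.tool)
        if score is None:
            counts.n_excluded_missing += 1
            continue
        z = zone.zone_of(score)
        attr = ("lof_" if record.functional_class is FunctionalClass.LOF else "func_") + (
            "benign" if z is Zone.BENIGN else "gray" if z is Zone.GRAY else "path"
        )
        setattr(counts, attr, getattr(counts, attr) + 1)
    return counts


def log2_lr_ci(
    x1: int, n1: int, x2: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """Asymptotic ``level`` CI for log2 LR of two binomial proportions."""
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if not (0 < x1 <= n1 and 0 < x2 <= n2):
        raise ValidationError("require 0 < x1 <= n1 and 0 < x2 <= n2")
    p1, p2 = x1 / n1, x2 / n2
    z = norm.ppf(0.5 + level / 2.0)
    se_ln = math.sqrt((1 - p1) / x1 + (1 - p2) / x2)
    center = math.log2(p1 / p2)
    half = z * se_ln / LN2
    return (center - half, center + half)


def _lr_from_counts(
    x1: float,
    n1: float,
    x2: float,
    n2: float,
    level: float = 0.95,
    allow_double_zero: bool = False,
) -> LrEstimate:
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("both classes must be non-empty (n1 > 0 and n2 > 0)")
    ix1, in1, ix2, in2 = int(x1), int(n1), int(x2), int(n2)
    corrected = False
    if x1 == 0 and x2 == 0 and not allow_double_zero:
        raise ValidationError("no observations in this zone for either class")
    if x1 == 0 or x2 == 0:
        # Haldane–Anscombe: +0.5 everywhere keeps the LR finite.
        x1, n1, x2, n2 = x1 + 0.5, n1 + 0.5, x2 + 0.5, n2 + 0.5
        corrected = True
    lr = (x1 / n1) / (x2 / n2)
    p1, p2 = x1 / n1, x2 / n2
    z = norm.ppf(0.5 + level / 2.0)
    se_ln = math.sqrt((1 - p1) / x1 + (1 - p2) / x2)
    center = math.log2(lr)
    half = z * se_ln / LN2
    return LrEstimate(
        lr=lr,
        log2_lr=center,
        ci95_log2=(center - half, center + half),
        x1=ix1,
        n1=in1,
        x2=ix2,
        n2=in2,
        level=level,
        corrected=corrected,
    )


def lr_pathogenic(counts: ZoneCounts, level: float = 0.95) -> LrEstimate:
    """LR toward pathogenicity: P(path zone | LoF) / P(path zone | FUNC)."""
    if counts.lof_path == 0 and counts.func_path == 0:
        raise ValidationError("no pathogenic-zone observations")
    return _lr_from_counts(
        counts.lof_path, counts.n_lof, counts.func_path, counts.n_func, level
    )


def lr_benign(counts: ZoneCounts, level: float = 0.95) -> LrEstimate:
    """LR of the benign zone (values < 1 indicate benignity evidence)."""
    if counts.lof_benign == 0 and counts.func_benign == 0:
        raise ValidationError("no benign-zone observations")
    return _lr_from_counts(
        counts.lof_benign, counts.n_lof, counts.func_benign, counts.n_func, level
    )


def lr_gray(counts: ZoneCounts, level: float = 0.95) -> LrEstimate:
    """LR of the uninformative zone (diagnostic; no evidence code applies)."""
    return _lr_from_counts(
        counts.lof_gray, counts.n_lof, counts.func_gray, counts.n_func, level,
        allow_double_zero=True,
    )


_POINT_GRID = (1, 2, 4, 8)


def map_strength(
    estimate: LrEstimate, require_ci_excludes_null: bool = False
) -> EvidenceStrength:
    """Snap a log2 LR to the nearest ACMG point tier {1, 2, 4, 8}.

    |log2 LR| below 0.5 (under the rounding basin of one point) yields no
    evidence. Ties between two points go to the lower. With
    ``require_ci_excludes_null``, a CI containing 0 also yields no evidence.
    """
    mag = abs(estimate.log2_lr)
    lo, hi = estimate.ci95_log2
    if mag < 0.5 or (require_ci_excludes_null and lo <= 0.0 <= hi):
        return EvidenceStrength(EvidenceDirection.NONE, StrengthTier.NONE, 0)
    points = min(_POINT_GRID, key=lambda p: (abs(mag - p), p))
    if estimate.log2_lr > 0:
        return EvidenceStrength(
            EvidenceDirection.PATHOGENIC, _POINTS_TO_TIER[points], points
        )
    return EvidenceStrength(EvidenceDirection.BENIGN, _POINTS_TO_TIER[points], -points)


@dataclass
class ToolReport:
    """Full three-zone evaluation of one tool on a LoF/FUNC cohort."""

    zone: ThreeZone
    counts: ZoneCounts
    lr_path: LrEstimate
    lr_benign: LrEstimate
    strength_path: EvidenceStrength
    strength_benign: EvidenceStrength
    gray_fraction: float


def evaluate_tool(
    cohort: ScoreTable,
    zone: ThreeZone,
    level: float = 0.95,
    require_ci_excludes_null: bool = False,
) -> ToolReport:
    """Zone counts, both LRs, and mapped evidence strengths for one tool."""
    counts = count_zones(cohort, zone)
    if counts.n_lof == 0 or counts.n_func == 0:
        raise ValidationError(
            f"{zone.tool}: degenerate cohort "
            f"(n_lof={counts.n_lof}, n_func={counts.n_func})"
        )
    est_p = lr_pathogenic(counts, level)
    est_b = lr_benign(counts, level)
    return ToolReport(
        zone=zone,
        counts=counts,
        lr_path=est_p,
        lr_benign=est_b,
        strength_path=map_strength(est_p, require_ci_excludes_null),
        strength_benign=map_strength(est_b, require_ci_excludes_null),
        gray_fraction=counts.gray_fraction,
    )


@dataclass
class SearchCandidate:
    zone: ThreeZone
    report: ToolReport
    min_abs_log2: float
    gray_fraction: float
    tier_points: int  # min(|points| on the two sides)


@dataclass
class SearchOutcome:
    """Pareto front of threshold pairs plus search diagnostics."""

    front: list[SearchCandidate]
    n_pairs: int = 0
    n_unevaluable: int = 0
    n_failed_constraints: int = 0


def search_thresholds(
    cohort: ScoreTable,
    tool: str,
    candidate_grid: list[float],
    constraints: dict[str, float] | None = None,
    direction: ZoneDirection = ZoneDirection.HIGHER_IS_PATHOGENIC,
    level: float = 0.95,
) -> SearchOutcome:
    """Exhaustive grid search over (benign_max, path_min) pairs.

    Mirrors the trade-off between maximising evidence strength on both sides
    and minimising the uninformative fraction: every ordered pair on the grid
    is evaluated, pairs failing the constraints (minimum |log2 LR| on each
    side with a CI excluding 0, maximum gray fraction) are dropped, and the
    Pareto front under (max min-|log2 LR|, min gray fraction) is returned,
    ranked by achieved strength tier then gray fraction.
    """
    if not candidate_grid:
        raise ValidationError("empty candidate grid")
    grid = list(candidate_grid)
    if grid != sorted(grid):
        raise ValidationError("candidate grid must be sorted ascending")
    constraints = constraints or {}
    min_each_side = constraints.get("min_abs_log2_each_side", 0.5)
    max_gray = constraints.get("max_gray_fraction", 1.0)

    outcome = SearchOutcome(front=[])
    candidates: list[SearchCandidate] = []
    for lo, hi in combinations_with_replacement(grid, 2):
        benign_max, path_min = (
            (lo, hi) if direction is ZoneDirection.HIGHER_IS_PATHOGENIC else (hi, lo)
        )
        outcome.n_pairs += 1
        zone = ThreeZone(tool, benign_max, path_min, direction)
        try:
            report = evaluate_tool(cohort, zone, level, require_ci_excludes_null=True)
        except ValidationError:
            outcome.n_unevaluable += 1
            continue
        sp, sb = report.strength_path, report.strength_benign
        min_abs = min(abs(report.lr_path.log2_lr), abs(report.lr_benign.log2_lr))
        ok = (
            sp.direction is EvidenceDirection.PATHOGENIC
            and sb.direction is EvidenceDirection.BENIGN
            and min_abs >= min_each_side
            and report.gray_fraction <= max_gray
        )
        if not ok:
            outcome.n_failed_constraints += 1
            continue
        candidates.append(
            SearchCandidate(
                zone=zone,
                report=report,
                min_abs_log2=min_abs,
                gray_fraction=report.gray_fraction,
                tier_points=min(abs(sp.points), abs(sb.points)),
            )
        )

    front = [
        c
        for c in candidates
        if not any(
            (o.min_abs_log2 >= c.min_abs_log2 and o.gray_fraction <= c.gray_fraction)
            and (o.min_abs_log2 > c.min_abs_log2 or o.gray_fraction < c.gray_fraction)
            for o in candidates
        )
    ]
    front.sort(key=lambda c: (-c.tier_points, c.gray_fraction, -c.min_abs_log2))
    outcome.front = front
    return outcome
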