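"""Stratified likelihood ratios, tool concordance, and cascade evidence.

Benignity evidence in particular is strongly modulated by residue burial:
for exposed residues, absence of predicted destabilisation does not imply
functionality, so BP4-style evidence frequently fails to reach significance
there. This module evaluates score zones within RSA or domain strata, builds
concordance categories for tool pairs (discordant pairs are treated as
uninformative), and routes variants through a small decision tree (RSA bin →
pathogenicity score → ΔΔG) whose leaves carry likelihood ratios estimated on
the calibration cohort; leaves whose CI spans log2 LR = 0 are demoted to the
uninformative label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Union

from .classify import RsaBin, RsaBinning, assign_rsa_bin
from .core import Domain, FunctionalClass, ScoreTable, ValidationError, VariantRecord
from .lr import (
    LrEstimate,
    ThreeZone,
    ToolReport,
    ZoneDirection,
    _lr_from_counts,
    evaluate_tool,
)

__all__ = [
    "Stratum",
    "rsa_strata",
    "domain_strata",
    "StratumReport",
    "stratified_evaluate",
    "ConcordanceReport",
    "concordance_evaluate",
    "CascadeLeaf",
    "CascadeNode",
    "CascadeRule",
    "EvidenceAssignment",
    "CascadeResult",
    "cascade_assign",
    "default_cascade",
]

GRAY_LABEL = "GRAY"


@dataclass
class Stratum:
    name: str
    predicate: Callable[[VariantRecord], bool]


def rsa_strata(binning: RsaBinning = RsaBinning()) -> list[Stratum]:
    """Buried / partially buried / exposed strata (RSA-less records excluded
    by every predicate, so callers should filter those first)."""

    def in_bin(target: RsaBin) -> Callable[[VariantRecord], bool]:
        return lambda r: r.rsa is not None and assign_rsa_bin(r.rsa, binning) is target

    return [Stratum(b.value, in_bin(b)) for b in RsaBin]


def domain_strata() -> list[Stratum]:
    def in_domain(target: Domain) -> Callable[[VariantRecord], bool]:
        return lambda r: r.domain is target

    return [Stratum(d.value, in_domain(d)) for d in Domain]


def _check_partition(cohort: ScoreTable, strata: list[Stratum]) -> None:
    for record in cohort:
        hits = [s.name for s in strata if s.predicate(record)]
        if len(hits) != 1:
            raise ValidationError(
                f"strata do not partition the cohort: {record.variant_id} "
                f"matches {hits or 'no stratum'}"
            )


@dataclass
class StratumReport:
    name: str
    n_lof: int
    n_func: int
    report: ToolReport | None
    flags: list[str] = field(default_factory=list)


def stratified_evaluate(
    cohort: ScoreTable,
    strata: list[Stratum],
    zone: ThreeZone,
    level: float = 0.95,
) -> list[StratumReport]:
    """Per-stratum three-zone evaluation.

    Strata with fewer than 2 variants in either class are flagged rather
    than errored; a side whose CI spans log2 LR = 0 is flagged as providing
    no statistically significant evidence.
    """
    _check_partition(cohort, strata)
    out: list[StratumReport] = []
    for stratum in strata:
        sub = cohort.subset(stratum.predicate, provenance=stratum.name)
        counts = sub.class_counts()
        n_lof = counts.get(FunctionalClass.LOF, 0)
        n_func = counts.get(FunctionalClass.FUNC, 0)
        entry = StratumReport(stratum.name, n_lof, n_func, report=None)
        if n_lof < 2 or n_func < 2:
            entry.flags.append("insufficient data")
            out.append(entry)
            continue
        try:
            entry.report = evaluate_tool(sub, zone, level)
        except ValidationError as exc:
            entry.flags.append(f"not evaluable: {exc}")
            out.append(entry)
            continue
        for side, est in (
            ("pathogenic", entry.report.lr_path),
            ("benign", entry.report.lr_benign),
        ):
            lo, hi = est.ci95_log2
            if lo <= 0.0 <= hi:
                entry.flags.append(f"no statistically significant {side} evidence")
        out.append(entry)
    return out


@dataclass
class ConcordanceReport:
    """Two-tool concordance categories and their likelihood ratios."""

    tool_a: str
    tool_b: str
    lof_both_path: int
    lof_both_benign: int
    lof_uninformative: int
    func_both_path: int
    func_both_benign: int
    func_uninformative: int
    n_excluded_missing: int
    lr_path: LrEstimate
    lr_benign: LrEstimate

    @property
    def uninformative_fraction(self) -> float:
        total = (
            self.lof_both_path
            + self.lof_both_benign
            + self.lof_uninformative
            + self.func_both_path
            + self.func_both_benign
            + self.func_uninformative
        )
        return (self.lof_uninformative + self.func_uninformative) / total


def concordance_evaluate(
    cohort: ScoreTable,
    zone_a: ThreeZone,
    zone_b: ThreeZone,
    level: float = 0.95,
) -> ConcordanceReport:
    """Evidence from two tools jointly: concordant calls carry evidence,
    discordant or any-gray pairs are uninformative."""
    tallies = {
        (cls, cat): 0
        for cls in (FunctionalClass.LOF, FunctionalClass.FUNC)
        for cat in ("path", "benign", "gray")
    }
    excluded = 0
    n_lof = n_func = 0
    for record in cohort:
        if record.functional_class not in (FunctionalClass.LOF, FunctionalClass.FUNC):
            raise ValidationError(
                f"{record.variant_id}: cohort must contain only LOF/FUNC records"
            )
        sa = record.scores.get(zone_a.tool)
        sb = record.scores.get(zone_b.tool)
        if sa is None or sb is None:
            excluded += 1
            continue
        za, zb = zone_a.zone_of(sa), zone_b.zone_of(sb)
        if za.value == "PATH" and zb.value == "PATH":
            cat = "path"
        elif za.value == "BENIGN" and zb.value == "BENIGN":
            cat = "benign"
        else:
            cat = "gray"
        tallies[(record.functional_class, cat)] += 1
        if record.functional_class is FunctionalClass.LOF:
            n_lof += 1
        else:
            n_func += 1
    if n_lof == 0 or n_func == 0:
        raise ValidationError("both LoF and FUNC records with both scores required")
    lof, func = FunctionalClass.LOF, FunctionalClass.FUNC
    lr_p = _lr_from_counts(
        tallies[(lof, "path")], n_lof, tallies[(func, "path")], n_func, level,
        allow_double_zero=True,
    )
    lr_b = _lr_from_counts(
        tallies[(lof, "benign")], n_lof, tallies[(func, "benign")], n_func, level,
        allow_double_zero=True,
    )
    return ConcordanceReport(
        tool_a=zone_a.tool,
        tool_b=zone_b.tool,
        lof_both_path=tallies[(lof, "path")],
        lof_both_benign=tallies[(lof, "benign")],
        lof_uninformative=tallies[(lof, "gray")],
        func_both_path=tallies[(func, "path")],
        func_both_benign=tallies[(func, "benign")],
        func_uninformative=tallies[(func, "gray")],
        n_excluded_missing=excluded,
        lr_path=lr_p,
        lr_benign=lr_b,
    )


# ---------------------------------------------------------------------------
# Cascade trees


@dataclass(frozen=True)
class CascadeLeaf:
    """Terminal label: an evidence direction+strength name, or GRAY."""

    name: str
    label: str  # e.g. "PATHOGENIC_STRONG", "BENIGN_MODERATE", or "GRAY"


_OPS: dict[str, Callable[[float, float], bool]] = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
}


@dataclass(frozen=True)
class CascadeNode:
    """Binary decision on one record field.

    ``field`` is ``"rsa"``, ``"mave_score"`` or a tool name; the record's
    value is compared against ``threshold`` with ``op``.
    """

    field: str
    op: str
    threshold: float
    if_true: Union["CascadeNode", CascadeLeaf]
    if_false: Union["CascadeNode", CascadeLeaf]

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValidationError(f"unknown comparator {self.op!r}")


@dataclass
class CascadeRule:
    root: CascadeNode

    def __post_init__(self) -> None:
        if self._depth(self.root) > 4:
            raise ValidationError("cascade depth must be <= 4")
        self._warn_unreachable(self.root, {})

    @staticmethod
    def _depth(node) -> int:
        if isinstance(node, CascadeLeaf):
            return 0
        return 1 + max(CascadeRule._depth(node.if_true), CascadeRule._depth(node.if_false))

    @staticmethod
    def _warn_unreachable(node, bounds: dict[str, tuple[float, float]]) -> None:
        # Track per-field (lo, hi) intervals along each path; an empty
        # interval means everything at or below this point is unreachable.
        empty = [f for f, (lo, hi) in bounds.items() if lo >= hi]
        if empty:
            warnings.warn(
                f"unreachable subtree below contradictory {empty[0]} tests"
            )
            return
        if isinstance(node, CascadeLeaf):
            return
        lo, hi = bounds.get(node.field, (float("-inf"), float("inf")))
        t = node.threshold
        true_bounds = dict(bounds)
        false_bounds = dict(bounds)
        if node.op in ("<", "<="):
            true_bounds[node.field] = (lo, min(hi, t))
            false_bounds[node.field] = (max(lo, t), hi)
        else:
            true_bounds[node.field] = (max(lo, t), hi)
            false_bounds[node.field] = (lo, min(hi, t))
        CascadeRule._warn_unreachable(node.if_true, true_bounds)
        CascadeRule._warn_unreachable(node.if_false, false_bounds)

    def leaves(self) -> list[CascadeLeaf]:
        found: list[CascadeLeaf] = []

        def walk(node) -> None:
            if isinstance(node, CascadeLeaf):
                found.append(node)
            else:
                walk(node.if_true)
                walk(node.if_false)

        walk(self.root)
        return found

    def route(self, record: VariantRecord) -> CascadeLeaf | None:
        """Leaf for a record, or None when a required field is missing."""
        node = self.root
        while isinstance(node, CascadeNode):
            if node.field == "rsa":
                value = record.rsa
            elif node.field == "mave_score":
                value = record.mave_score
            else:
                value = record.scores.get(node.field)
            if value is None:
                return None
            node = node.if_true if _OPS[node.op](value, node.threshold) else node.if_false
        return node

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        def dump(node):
            if isinstance(node, CascadeLeaf):
                return {"leaf": node.name, "label": node.label}
            return {
                "field": node.field,
                "op": node.op,
                "threshold": node.threshold,
                "if_true": dump(node.if_true),
                "if_false": dump(node.if_false),
            }

        return dump(self.root)

    @classmethod
    def from_dict(cls, data: dict) -> "CascadeRule":
        def load(obj):
            if "leaf" in obj:
                return CascadeLeaf(obj["leaf"], obj["label"])
            return CascadeNode(
                field=obj["field"],
                op=obj["op"],
                threshold=float(obj["threshold"]),
                if_true=load(obj["if_true"]),
                if_false=load(obj["if_false"]),
            )

        return cls(root=load(data))


@dataclass
class EvidenceAssignment:
    variant_id: str
    leaf: str
    label: str  # post-demotion label actually emitted
    nominal_label: str  # label the tree declared for the leaf


@dataclass
class CascadeResult:
    assignments: list[EvidenceAssignment]
    leaf_lr: dict[str, LrEstimate]
    leaf_counts: dict[str, tuple[int, int]]  # (LoF, FUNC) per leaf
    demoted: list[str]
    n_missing_field: int
    gray_fraction: float


def cascade_assign(
    cohort: ScoreTable, rule: CascadeRule, level: float = 0.95
) -> CascadeResult:
    """Route every variant through the tree and calibrate the leaves.

    Per-leaf LRs are estimated on the same cohort being assigned (the
    calibration cohort); evidence leaves whose CI spans log2 LR = 0 are
    demoted to GRAY in the emitted assignments. Variants missing a field
    used by the tree are assigned GRAY and counted.
    """
    routed: list[tuple[VariantRecord, CascadeLeaf | None]] = []
    n_missing = 0
    n_lof = n_func = 0
    leaf_tally: dict[str, list[int]] = {leaf.name: [0, 0] for leaf in rule.leaves()}
    for record in cohort:
        if record.functional_class not in (FunctionalClass.LOF, FunctionalClass.FUNC):
            raise ValidationError(
                f"{record.variant_id}: cohort must contain only LOF/FUNC records"
            )
        leaf = rule.route(record)
        routed.append((record, leaf))
        if record.functional_class is FunctionalClass.LOF:
            n_lof += 1
        else:
            n_func += 1
        if leaf is None:
            n_missing += 1
            continue
        idx = 0 if record.functional_class is FunctionalClass.LOF else 1
        leaf_tally[leaf.name][idx] += 1
    if n_lof == 0 or n_func == 0:
        raise ValidationError("both LoF and FUNC records required for leaf calibration")

    leaf_lr: dict[str, LrEstimate] = {}
    demoted: list[str] = []
    effective_label: dict[str, str] = {}
    for leaf in rule.leaves():
        x_lof, x_func = leaf_tally[leaf.name]
        est = _lr_from_counts(x_lof, n_lof, x_func, n_func, level, allow_double_zero=True)
        leaf_lr[leaf.name] = est
        label = leaf.label
        lo, hi = est.ci95_log2
        if label != GRAY_LABEL and lo <= 0.0 <= hi:
            demoted.append(leaf.name)
            label = GRAY_LABEL
        effective_label[leaf.name] = label

    assignments = []
    n_gray = 0
    for record, leaf in routed:
        if leaf is None:
            assignments.append(
                EvidenceAssignment(record.variant_id, "missing_field", GRAY_LABEL, GRAY_LABEL)
            )
            n_gray += 1
            continue
        label = effective_label[leaf.name]
        if label == GRAY_LABEL:
            n_gray += 1
        assignments.append(
            EvidenceAssignment(record.variant_id, leaf.name, label, leaf.label)
        )
    return CascadeResult(
        assignments=assignments,
        leaf_lr=leaf_lr,
        leaf_counts={k: (v[0], v[1]) for k, v in leaf_tally.items()},
        demoted=demoted,
        n_missing_field=n_missing,
        gray_fraction=n_gray / len(cohort) if len(cohort) else 0.0,
    )


def default_cascade(
    binning: RsaBinning = RsaBinning(),
    am_tool: str = "AM",
    am_benign_max: float = 0.65,
    am_path_min: float = 0.75,
    ddg_tool: str = "DDG_AF",
    ddg_benign_max: float = 1.5,
    ddg_path_min: float = 2.5,
) -> CascadeRule:
    """RSA bin → pathogenicity score → ΔΔG cascade with the main-text zones.

    Buried/partially buried residues can receive concordance-boosted Strong
    evidence on either side; exposed residues can receive pathogenicity
    evidence only (ΔΔG non-destabilisation is not informative of benignity
    at the protein surface).
    """
    buried_partial = CascadeNode(
        field=am_tool,
        op=">=",
        threshold=am_path_min,
        if_true=CascadeNode(
            field=ddg_tool,
            op=">=",
            threshold=ddg_path_min,
            if_true=CascadeLeaf("core_concordant_path", "PATHOGENIC_STRONG"),
            if_false=CascadeLeaf("core_am_path", "PATHOGENIC_MODERATE"),
        ),
        if_false=CascadeNode(
            field=am_tool,
            op="<=",
            threshold=am_benign_max,
            if_true=CascadeNode(
                field=ddg_tool,
                op="<=",
                threshold=ddg_benign_max,
                if_true=CascadeLeaf("core_concordant_benign", "BENIGN_STRONG"),
                if_false=CascadeLeaf("core_am_benign", "BENIGN_MODERATE"),
            ),
            if_false=CascadeLeaf("core_gray", GRAY_LABEL),
        ),
    )
    exposed = CascadeNode(
        field=am_tool,
        op=">=",
        threshold=am_path_min,
        if_true=CascadeLeaf("exposed_path", "PATHOGENIC_MODERATE"),
        if_false=CascadeLeaf("exposed_gray", GRAY_LABEL),
    )
    return CascadeRule(
        root=CascadeNode(
            field="rsa",
            op="<=",
            threshold=binning.partial_max_inclusive,
            if_true=buried_partial,
            if_false=exposed,
        )
    )
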