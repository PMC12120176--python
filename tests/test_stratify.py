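import math

import numpy as np
import pytest

from mavecalib import (
    FunctionalClass,
    GeneratorConfig,
    RsaBin,
    ScoreTable,
    Stratum,
    ThreeZone,
    ValidationError,
    VariantRecord,
    build_analysis_cohort,
    cascade_assign,
    concordance_evaluate,
    default_cascade,
    evaluate_tool,
    generate_mave_cohort,
    rsa_strata,
    stratified_evaluate,
)
from mavecalib.lr import ZoneCounts, lr_pathogenic
from mavecalib.stratify import GRAY_LABEL, CascadeLeaf, CascadeNode, CascadeRule
from mavecalib.synth import ScoreModel

from conftest import make_cohort

AM_ZONE = ThreeZone("AM", 0.65, 0.75)
DDG_ZONE = ThreeZone("DDG_AF", 1.5, 2.5)


class TestStratifiedEvaluate:
    def test_single_all_inclusive_stratum_matches_unstratified(self, synthetic_cohort):
        whole = [Stratum("all", lambda r: True)]
        [entry] = stratified_evaluate(synthetic_cohort, whole, AM_ZONE)
        direct = evaluate_tool(synthetic_cohort, AM_ZONE)
        assert entry.report.lr_path.log2_lr == direct.lr_path.log2_lr
        assert entry.report.counts.gray_fraction == direct.counts.gray_fraction

    def test_non_partitioning_strata_error(self, synthetic_cohort):
        overlapping = [Stratum("a", lambda r: True), Stratum("b", lambda r: True)]
        with pytest.raises(ValidationError, match="partition"):
            stratified_evaluate(synthetic_cohort, overlapping, AM_ZONE)

    def test_collapsing_strata_recovers_unstratified_lr(self, synthetic_cohort):
        entries = stratified_evaluate(synthetic_cohort, rsa_strata(), AM_ZONE)
        pooled = ZoneCounts()
        for e in entries:
            assert e.report is not None
            for attr in ("lof_path", "lof_gray", "lof_benign",
                         "func_path", "func_gray", "func_benign"):
                setattr(pooled, attr, getattr(pooled, attr) + getattr(e.report.counts, attr))
        direct = evaluate_tool(synthetic_cohort, AM_ZONE)
        assert math.isclose(
            lr_pathogenic(pooled).lr, direct.lr_path.lr, rel_tol=1e-12
        )

    def test_sparse_stratum_is_flagged_not_errored(self):
        cohort = make_cohort([0.9], [0.1, 0.2, 0.3], rsa=10.0)
        entries = stratified_evaluate(cohort, rsa_strata(), AM_ZONE)
        buried = next(e for e in entries if e.name == "BURIED")
        assert "insufficient data" in buried.flags
        assert buried.report is None

    def test_weakly_separated_exposed_stratum_lacks_significant_benign_evidence(self):
        # A tool whose class-conditional locations barely differ: with the few
        # impaired variants at exposed residues, benignity CIs should span 0.
        weak = {
            FunctionalClass.LOF: ScoreModel("truncnorm", 2.0, 2.0, lower=-5),
            FunctionalClass.INT: ScoreModel("truncnorm", 1.5, 2.0, lower=-5),
            FunctionalClass.FUNC: ScoreModel("truncnorm", 1.0, 2.0, lower=-5),
        }
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            config = GeneratorConfig(
                n_variants=600, score_models={"WEAK": weak}, seed=1000 + rep,
                copula_correlations={},
            )
            cohort, _ = build_analysis_cohort(generate_mave_cohort(config))
            entries = stratified_evaluate(
                cohort, rsa_strata(), ThreeZone("WEAK", 1.5, 2.5)
            )
            exposed = next(e for e in entries if e.name == "EXPOSED")
            if exposed.report is None or any(
                "benign" in f or "insufficient" in f or "not evaluable" in f
                for f in exposed.flags
            ):
                hits += 1
        assert hits >= 0.8 * n_rep


class TestConcordance:
    def test_perfectly_correlated_tools_reduce_to_single_tool_gray(self, synthetic_cohort):
        # duplicate AM under a second name: uninformative category must equal
        # the single-tool gray zone exactly
        records = [
            VariantRecord(
                r.variant_id, r.mave_score, r.domain, r.rsa, r.functional_class,
                {**r.scores, "AM2": r.scores["AM"]},
            )
            for r in synthetic_cohort
        ]
        cohort = ScoreTable(records)
        rep = concordance_evaluate(cohort, AM_ZONE, ThreeZone("AM2", 0.65, 0.75))
        direct = evaluate_tool(cohort, AM_ZONE)
        assert math.isclose(rep.uninformative_fraction, direct.gray_fraction)
        assert rep.lr_path.lr == direct.lr_path.lr

    def test_independent_null_tools_give_unit_concordant_lrs(self):
        rng = np.random.default_rng(0)
        n_lof, n_func = 400, 1200
        records = []
        for i in range(n_lof + n_func):
            cls = FunctionalClass.LOF if i < n_lof else FunctionalClass.FUNC
            records.append(
                VariantRecord(
                    f"v{i}", -2.0 if cls is FunctionalClass.LOF else 0.0,
                    functional_class=cls,
                    scores={"A": rng.random(), "B": rng.random()},
                )
            )
        rep = concordance_evaluate(
            ScoreTable(records), ThreeZone("A", 0.4, 0.6), ThreeZone("B", 0.4, 0.6)
        )
        # null cohort: both concordant LRs within a broad sampling band of 1
        assert abs(rep.lr_path.log2_lr) < 1.0
        assert abs(rep.lr_benign.log2_lr) < 1.0

    def test_anticorrelated_tools_are_mostly_uninformative(self):
        rng = np.random.default_rng(1)
        scores = rng.random(500)
        records = [
            VariantRecord(
                f"v{i}", -2.0 if i % 4 == 0 else 0.0,
                functional_class=FunctionalClass.LOF if i % 4 == 0 else FunctionalClass.FUNC,
                scores={"A": s, "B": 1.0 - s},
            )
            for i, s in enumerate(scores)
        ]
        rep = concordance_evaluate(
            ScoreTable(records), ThreeZone("A", 0.5, 0.5), ThreeZone("B", 0.5, 0.5)
        )
        assert rep.uninformative_fraction > 0.95

    def test_records_missing_either_tool_are_excluded_and_counted(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(60):
            cls = FunctionalClass.LOF if i % 3 == 0 else FunctionalClass.FUNC
            scores = {"A": rng.random()}
            if i % 2 == 0:  # only half carry tool B
                scores["B"] = rng.random()
            records.append(
                VariantRecord(
                    f"v{i}", -2.0 if cls is FunctionalClass.LOF else 0.0,
                    functional_class=cls, scores=scores,
                )
            )
        rep = concordance_evaluate(
            ScoreTable(records), ThreeZone("A", 0.4, 0.6), ThreeZone("B", 0.4, 0.6)
        )
        assert rep.n_excluded_missing == 30
        included = (
            rep.lof_both_path + rep.lof_both_benign + rep.lof_uninformative
            + rep.func_both_path + rep.func_both_benign + rep.func_uninformative
        )
        assert included == 30


class TestCascade:
    def test_assignment_is_a_partition(self, synthetic_cohort):
        result = cascade_assign(synthetic_cohort, default_cascade())
        assert len(result.assignments) == len(synthetic_cohort)
        routed = sum(lof + func for lof, func in result.leaf_counts.values())
        assert routed + result.n_missing_field == len(synthetic_cohort)

    def test_leaf_lrs_are_monotone_in_evidence_direction(self, synthetic_cohort):
        result = cascade_assign(synthetic_cohort, default_cascade())
        lr = {k: v.log2_lr for k, v in result.leaf_lr.items()}
        assert lr["core_concordant_path"] >= lr["core_am_path"]
        assert lr["core_am_benign"] >= lr["core_concordant_benign"]
        assert lr["core_concordant_path"] > 0 > lr["core_concordant_benign"]

    def test_depth_one_tree_reduces_to_single_tool_categories(self, synthetic_cohort):
        tree = CascadeRule(
            CascadeNode(
                "AM", ">=", 0.75,
                if_true=CascadeLeaf("path", "PATHOGENIC_MODERATE"),
                if_false=CascadeLeaf("rest", GRAY_LABEL),
            )
        )
        result = cascade_assign(synthetic_cohort, tree)
        counts = evaluate_tool(synthetic_cohort, AM_ZONE).counts
        lof, func = result.leaf_counts["path"]
        assert (lof, func) == (counts.lof_path, counts.func_path)

    def test_weak_leaf_is_demoted_to_gray_and_demotion_is_idempotent(self):
        rng = np.random.default_rng(2)
        # benign-labelled leaf backed by almost no signal → CI spans 0
        cohort = make_cohort(rng.uniform(0, 1, 30), rng.uniform(0, 1, 90))
        tree = CascadeRule(
            CascadeNode(
                "AM", "<=", 0.5,
                if_true=CascadeLeaf("noise_benign", "BENIGN_MODERATE"),
                if_false=CascadeLeaf("noise_path", "PATHOGENIC_MODERATE"),
            )
        )
        result = cascade_assign(cohort, tree)
        assert set(result.demoted) == {"noise_benign", "noise_path"}
        assert all(a.label == GRAY_LABEL for a in result.assignments)
        again = cascade_assign(cohort, tree)
        assert [a.label for a in again.assignments] == [a.label for a in result.assignments]

    def test_missing_field_routes_to_gray_and_is_counted(self):
        cohort = make_cohort([0.9, 0.8], [0.1, 0.2, 0.7])  # records lack rsa
        result = cascade_assign(cohort, default_cascade())
        assert result.n_missing_field == len(cohort)
        assert all(a.leaf == "missing_field" and a.label == GRAY_LABEL
                   for a in result.assignments)

    def test_serialisation_round_trip(self):
        tree = default_cascade()
        clone = CascadeRule.from_dict(tree.to_dict())
        assert clone.to_dict() == tree.to_dict()

    def test_depth_limit_enforced(self):
        leaf = CascadeLeaf("x", GRAY_LABEL)
        node = CascadeNode("AM", ">=", 0.5, leaf, leaf)
        for _ in range(4):
            node = CascadeNode("AM", ">=", 0.5, node, leaf)
        with pytest.raises(ValidationError, match="depth"):
            CascadeRule(node)

    def test_contradictory_subtree_warns(self):
        tree_dict = {
            "field": "rsa", "op": "<", "threshold": 30,
            "if_true": {
                "field": "rsa", "op": ">", "threshold": 60,
                "if_true": {"leaf": "impossible", "label": "PATHOGENIC_STRONG"},
                "if_false": {"leaf": "ok", "label": "GRAY"},
            },
            "if_false": {"leaf": "rest", "label": "GRAY"},
        }
        with pytest.warns(UserWarning, match="unreachable"):
            CascadeRule.from_dict(tree_dict)
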