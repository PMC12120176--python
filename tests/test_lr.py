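import math

import numpy as np
import pytest

from mavecalib import (
    EvidenceDirection,
    StrengthTier,
    ThreeZone,
    ValidationError,
    ZoneDirection,
    count_zones,
    evaluate_tool,
    log2_lr_ci,
    lr_benign,
    lr_pathogenic,
    map_strength,
    search_thresholds,
)
from mavecalib.lr import ZoneCounts, _lr_from_counts, lr_gray

from conftest import make_cohort


class TestCountZones:
    def test_hand_counted_toy_cohort(self):
        cohort = make_cohort([0.9, 0.8, 0.5], [0.1, 0.6, 0.9])
        counts = count_zones(cohort, ThreeZone("AM", 0.65, 0.75))
        assert (counts.lof_path, counts.lof_gray, counts.lof_benign) == (2, 0, 1)
        assert (counts.func_path, counts.func_gray, counts.func_benign) == (1, 0, 2)

    def test_collapsed_thresholds_give_empty_gray_zone(self):
        cohort = make_cohort([0.9, 0.8, 0.5], [0.1, 0.6, 0.9])
        counts = count_zones(cohort, ThreeZone("AM", 0.6, 0.6))
        assert counts.lof_gray == counts.func_gray == 0
        assert counts.gray_fraction == 0.0

    def test_lower_is_pathogenic_mirrors(self):
        cohort = make_cohort([0.1], [0.9])
        zone = ThreeZone("AM", 0.8, 0.2, ZoneDirection.LOWER_IS_PATHOGENIC)
        counts = count_zones(cohort, zone)
        assert counts.lof_path == 1 and counts.func_benign == 1

    def test_missing_scores_are_excluded_and_reported(self):
        cohort = make_cohort([0.9], [0.1], tool="BD")
        counts = count_zones(cohort, ThreeZone("AM", 0.65, 0.75))
        assert counts.n_excluded_missing == 2

    def test_empty_cohort_errors(self):
        from mavecalib import ScoreTable

        with pytest.raises(ValidationError, match="empty"):
            count_zones(ScoreTable([]), ThreeZone("AM", 0.65, 0.75))


class TestLikelihoodRatios:
    def test_equal_proportions_give_unit_lr(self):
        counts = ZoneCounts(lof_path=10, lof_benign=90, func_path=100, func_benign=900)
        est = lr_pathogenic(counts)
        assert math.isclose(est.lr, 1.0) and math.isclose(est.log2_lr, 0.0)

    def test_log2_consistency(self):
        est = _lr_from_counts(284, 337, 142, 1182)
        assert abs(est.log2_lr - math.log2(est.lr)) < 1e-12

    def test_benign_zone_empty_in_both_classes_errors(self):
        counts = ZoneCounts(lof_path=5, func_path=5)
        with pytest.raises(ValidationError, match="benign-zone"):
            lr_benign(counts)

    def test_haldane_correction_flags_zero_cells(self):
        est = _lr_from_counts(0, 100, 50, 100)
        assert est.corrected and est.lr > 0 and math.isfinite(est.log2_lr)

    def test_sensitivity_over_one_minus_specificity_when_no_gray(self):
        counts = ZoneCounts(lof_path=80, lof_benign=20, func_path=30, func_benign=170)
        sens = 80 / 100
        spec = 170 / 200
        assert math.isclose(lr_pathogenic(counts).lr, sens / (1 - spec))

    def test_label_swap_inverts_lr_exactly(self):
        counts = ZoneCounts(
            lof_path=17, lof_gray=3, lof_benign=5, func_path=8, func_gray=12, func_benign=55
        )
        swapped = ZoneCounts(
            lof_path=8, lof_gray=12, lof_benign=55, func_path=17, func_gray=3, func_benign=5
        )
        assert math.isclose(
            lr_pathogenic(counts).lr * lr_pathogenic(swapped).lr, 1.0, rel_tol=1e-12
        )

    def test_zone_lr_normalisation_identity(self):
        counts = ZoneCounts(
            lof_path=17, lof_gray=3, lof_benign=5, func_path=8, func_gray=12, func_benign=55
        )
        total = sum(
            est.lr * x2 / counts.n_func
            for est, x2 in [
                (lr_pathogenic(counts), counts.func_path),
                (lr_gray(counts), counts.func_gray),
                (lr_benign(counts), counts.func_benign),
            ]
        )
        assert math.isclose(total, 1.0, abs_tol=1e-12)
        p_sum = (counts.lof_path + counts.lof_gray + counts.lof_benign) / counts.n_lof
        assert math.isclose(p_sum, 1.0, abs_tol=1e-12)


class TestConfidenceInterval:
    def test_wider_level_strictly_contains_narrower(self):
        lo95, hi95 = log2_lr_ci(30, 100, 20, 200, 0.95)
        lo99, hi99 = log2_lr_ci(30, 100, 20, 200, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_degenerate_full_proportions_give_zero_width_at_null(self):
        lo, hi = log2_lr_ci(50, 50, 70, 70, 0.95)
        assert lo == hi == 0.0

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            log2_lr_ci(0, 10, 5, 10)
        with pytest.raises(ValidationError):
            log2_lr_ci(5, 10, 5, 10, level=1.0)


class TestStrengthMapping:
    @pytest.mark.parametrize(
        "log2_lr,direction,tier,points",
        [
            (2.810, EvidenceDirection.PATHOGENIC, StrengthTier.MODERATE, 2),
            (0.4, EvidenceDirection.NONE, StrengthTier.NONE, 0),
            (-4.603, EvidenceDirection.BENIGN, StrengthTier.STRONG, -4),
            (0.5, EvidenceDirection.PATHOGENIC, StrengthTier.SUPPORTING, 1),
            (1.5, EvidenceDirection.PATHOGENIC, StrengthTier.SUPPORTING, 1),  # tie → lower
            (3.0, EvidenceDirection.PATHOGENIC, StrengthTier.MODERATE, 2),  # tie → lower
            (-6.0, EvidenceDirection.BENIGN, StrengthTier.STRONG, -4),  # tie → lower
            (7.1, EvidenceDirection.PATHOGENIC, StrengthTier.VERY_STRONG, 8),
        ],
    )
    def test_nearest_point_mapping(self, log2_lr, direction, tier, points):
        est = _lr_from_counts(284, 337, 142, 1182)
        est.log2_lr = log2_lr
        est.ci95_log2 = (log2_lr - 0.1, log2_lr + 0.1)
        strength = map_strength(est)
        assert (strength.direction, strength.strength, strength.points) == (
            direction,
            tier,
            points,
        )

    def test_ci_spanning_null_demotes_to_none_when_required(self):
        est = _lr_from_counts(284, 337, 142, 1182)
        est.ci95_log2 = (-0.5, est.log2_lr + 1)
        assert map_strength(est, require_ci_excludes_null=True).points == 0
        assert map_strength(est, require_ci_excludes_null=False).points != 0


class TestEvaluateTool:
    def test_single_class_cohort_errors(self):
        cohort = make_cohort([0.9, 0.1], [])
        with pytest.raises(ValidationError):
            evaluate_tool(cohort, ThreeZone("AM", 0.65, 0.75))

    def test_widening_gray_zone_never_decreases_gray_fraction(self, synthetic_cohort):
        grays = []
        for t_b, t_p in [(0.6, 0.8), (0.5, 0.85), (0.4, 0.9)]:
            counts = count_zones(synthetic_cohort, ThreeZone("AM", t_b, t_p))
            grays.append(counts.gray_fraction)
        assert grays == sorted(grays)


class TestThresholdSearch:
    def test_front_is_undominated_and_meets_constraints(self, synthetic_cohort):
        grid = [round(0.05 * k, 2) for k in range(1, 20)]
        outcome = search_thresholds(
            synthetic_cohort,
            "AM",
            grid,
            constraints={"min_abs_log2_each_side": 1.5, "max_gray_fraction": 0.25},
        )
        assert outcome.front, "expected at least one admissible pair"
        best = outcome.front[0]
        assert best.tier_points >= 2  # Moderate on both sides is achievable
        for c in outcome.front:
            assert c.min_abs_log2 >= 1.5 and c.gray_fraction <= 0.25
            assert not any(
                (o.min_abs_log2 >= c.min_abs_log2 and o.gray_fraction < c.gray_fraction)
                or (o.min_abs_log2 > c.min_abs_log2 and o.gray_fraction <= c.gray_fraction)
                for o in outcome.front
            )

    def test_impossible_constraint_gives_empty_front_with_diagnostics(
        self, synthetic_cohort
    ):
        outcome = search_thresholds(
            synthetic_cohort,
            "AM",
            [0.3, 0.5, 0.7],
            constraints={"min_abs_log2_each_side": float("inf")},
        )
        assert outcome.front == []
        assert outcome.n_pairs == outcome.n_failed_constraints + outcome.n_unevaluable

    def test_perfectly_separated_cohort_reaches_zero_gray(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.uniform(0.8, 1.0, 40), rng.uniform(0.0, 0.2, 160))
        outcome = search_thresholds(
            cohort, "AM", [0.1, 0.5, 0.9], constraints={"min_abs_log2_each_side": 1.0}
        )
        assert any(c.gray_fraction == 0.0 for c in outcome.front)
        assert all(
            c.report.lr_path.corrected or c.report.lr_benign.corrected
            for c in outcome.front
            if c.gray_fraction == 0.0
        )

    def test_grid_validation(self, synthetic_cohort):
        with pytest.raises(ValidationError, match="empty"):
            search_thresholds(synthetic_cohort, "AM", [])
        with pytest.raises(ValidationError, match="sorted"):
            search_thresholds(synthetic_cohort, "AM", [0.7, 0.3])
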