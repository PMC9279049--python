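"""Feature formulas against exact and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_config
from deeppsy import (
    anomaly_score,
    build_feature_table,
    clean_consumption,
    cluster_dining,
    corrupt_for_preprocessing,
    course_quality,
    dining_distribution,
    dining_entropy,
    fill_missing_credits,
    gpa_average,
    grade_point,
    insomnia_probability,
    simulate_cohort,
)
from deeppsy.features import (
    ImputationError,
    clean_cohort,
    dining_feature_matrix,
    N_BINS,
)
from deeppsy.cohort import StudentRecord
from oracle_utils import entropy_oracle, gpa_oracle, kmeans_sse_oracle_fast


def _student(meals=(), sessions=(), courses=(), nights=0, label="none", sid="S1"):
    return StudentRecord(
        student_id=sid,
        level="junior",
        gender="F",
        meal_events=list(meals),
        net_sessions=list(sessions),
        courses=list(courses),
        insomnia_nights=nights,
        label=label,
    )


class TestGradeFormulas:
    @pytest.mark.parametrize("score,expected", [(50, 0.0), (100, 5.0), (73, 2.3)])
    def test_grade_point(self, score, expected):
        assert grade_point(score) == pytest.approx(expected, abs=1e-12)

    def test_grade_point_range_check(self):
        with pytest.raises(ValueError):
            grade_point(101)

    @pytest.mark.parametrize(
        "credit,gpa,expected", [(0, 3.7, 0.0), (3, 2.0, 6.0), (1, 4.2, 4.2)]
    )
    def test_course_quality(self, credit, gpa, expected):
        assert course_quality(credit, gpa) == pytest.approx(expected, abs=1e-12)

    def test_course_quality_negative_credit(self):
        with pytest.raises(ValueError):
            course_quality(-1, 2.0)

    def test_gpa_single_course(self):
        # one course, quality 6 over score 60
        assert gpa_average([("A", 60, 6)]) == pytest.approx(0.1, abs=1e-12)

    def test_gpa_two_courses_hand_sum(self):
        # qualities 6 and 4 over scores 60 and 80 -> 10/140
        courses = [("A", 60, 6), ("B", 80, 4 / 3)]
        assert gpa_average(courses) == pytest.approx(10 / 140, abs=1e-12)

    def test_gpa_all_zero_quality(self):
        assert gpa_average([("A", 50, 3), ("B", 50, 2)]) == 0.0

    @given(
        st.lists(
            st.tuples(
                st.integers(50, 100),  # integer scores
                st.integers(1, 5),  # integer credits
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_gpa_matches_exact_rational_oracle(self, rows):
        courses = [(f"C{i}", s, c) for i, (s, c) in enumerate(rows)]
        for denom in ("score", "credit"):
            got = gpa_average(courses, denominator=denom)
            assert got == pytest.approx(float(gpa_oracle(courses, denom)), abs=1e-12)

    def test_credit_denominator_differs(self):
        courses = [("A", 80, 2), ("B", 90, 3)]
        assert gpa_average(courses, "score") != gpa_average(courses, "credit")


class TestDining:
    @pytest.mark.parametrize(
        "minutes,expected",
        [
            ((400, 700, 1100), (1 / 3, 1 / 3, 1 / 3, 0)),
            ((400, 401, 402, 403), (1, 0, 0, 0)),
            ((400, 401, 700, 1100), (0.5, 0.25, 0.25, 0)),
        ],
    )
    def test_distribution(self, minutes, expected):
        events = [(0, m) for m in minutes]
        probs = dining_distribution(events)
        assert probs == pytest.approx(expected, abs=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_profile_sentinel(self):
        assert dining_distribution([]) is None
        assert dining_entropy(None) == 0.0

    @pytest.mark.parametrize(
        "probs,expected",
        [
            ((1, 0, 0), 0.0),
            ((1 / 3, 1 / 3, 1 / 3), math.log(3)),
            ((0.5, 0.25, 0.25), 1.0397207708399179),
        ],
    )
    def test_entropy_values(self, probs, expected):
        assert dining_entropy(probs) == pytest.approx(expected, abs=1e-6)

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_entropy_bounds(self, weights):
        p = np.asarray(weights) / sum(weights)
        e = dining_entropy(p)
        assert -1e-12 <= e <= math.log(len(p)) + 1e-12
        assert e == pytest.approx(entropy_oracle(weights), abs=1e-9)


class TestClustering:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        clouds = [rng.normal(c, 0.05, size=(10, 3)) for c in ((0, 0, 0), (5, 0, 0), (0, 5, 0))]
        x = np.vstack(clouds)
        labels, centroids, sizes, z = cluster_dining(x, k=3, seed=0)
        # each cloud lands in exactly one cluster
        for i in range(3):
            assert len(set(labels[10 * i : 10 * (i + 1)])) == 1
        assert sorted(sizes) == [10, 10, 10]

    def test_matches_enumeration_optimum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 2))
        labels, centroids, sizes, z = cluster_dining(x, k=3, seed=0)
        sse = sum(
            ((z[i] - centroids[labels[i]]) ** 2).sum() for i in range(len(z))
        )
        best = kmeans_sse_oracle_fast(z, k=3)
        assert sse == pytest.approx(best, rel=1e-9)

    def test_identical_points_zero_distance(self):
        x = np.ones((8, 3))
        labels, centroids, sizes, z = cluster_dining(x, k=3, seed=0)
        for i in range(8):
            assert np.allclose(z[i], centroids[labels[i]])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cluster_dining(np.ones((2, 3)), k=3)


class TestAnomalyScore:
    def test_at_centroid_zero(self):
        assert anomaly_score((1, 2), (1, 2), 5, 100) == 0.0

    def test_direct_substitution(self):
        # distance 2, cluster of 10 in a cohort of 100 -> 2 * 0.9
        assert anomaly_score((0, 0), (0, 2), 10, 100) == pytest.approx(1.8, abs=1e-12)

    def test_whole_cohort_cluster_scores_zero(self):
        assert anomaly_score((0, 0), (3, 4), 50, 50) == 0.0

    def test_smaller_cluster_scores_higher(self):
        small = anomaly_score((0, 0), (0, 2), 5, 100)
        large = anomaly_score((0, 0), (0, 2), 50, 100)
        assert small > large

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            anomaly_score((0,), (1,), 10, 5)

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=4),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_covariance(self, point, alpha):
        centroid = [p + 1.0 for p in point]
        m1 = anomaly_score(point, centroid, 3, 10)
        m2 = anomaly_score(
            [alpha * p for p in point], [alpha * c for c in centroid], 3, 10
        )
        assert m2 == pytest.approx(alpha * m1, rel=1e-9)


class TestInsomnia:
    @pytest.mark.parametrize("t,T,expected", [(0, 30, 0.0), (30, 30, 1.0), (3, 30, 0.1)])
    def test_probability(self, t, T, expected):
        assert insomnia_probability(t, T) == pytest.approx(expected, abs=1e-12)

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            insomnia_probability(0, 0)


class TestPreprocessing:
    def test_duplicate_dropped(self):
        events = [(0, 450), (0, 450), (1, 700)]
        assert clean_consumption(events) == [(0, 450), (1, 700)]

    def test_clean_input_unchanged(self):
        events = [(0, 450), (1, 700)]
        assert clean_consumption(events) == events

    def test_out_of_range_dropped(self):
        assert clean_consumption([(0, 1500), (0, 450)]) == [(0, 450)]

    def test_corrupted_cohort_restored_exactly(self, default_cohort):
        """Cleaning removes all and only the ledger-flagged noise events."""
        corrupted, ledger = corrupt_for_preprocessing(default_cohort, 0.05, 0.1, seed=9)
        cleaned = clean_cohort(corrupted)
        for orig, back in zip(default_cohort, cleaned):
            assert back.meal_events == orig.meal_events
        # every credit restored to a positive value
        for r in cleaned:
            assert all(c == c and c > 0 for _, _, c in r.courses)

    def test_median_imputation(self):
        cohort = [
            _student(courses=[("A", 80, 2)], sid="S1"),
            _student(courses=[("A", 70, 2)], sid="S2"),
            _student(courses=[("A", 60, float("nan"))], sid="S3"),
            _student(courses=[("A", 90, 4)], sid="S4"),
        ]
        filled = fill_missing_credits(cohort)
        assert filled[2].courses[0][2] == 2.0

    def test_no_missing_is_identity(self):
        cohort = [_student(courses=[("A", 80, 2), ("B", 60, 3)])]
        assert fill_missing_credits(cohort)[0].courses == cohort[0].courses

    def test_unobserved_course_credit_raises(self):
        cohort = [_student(courses=[("A", 80, float("nan"))])]
        with pytest.raises(ImputationError):
            fill_missing_credits(cohort)


class TestFeatureTable:
    def test_full_cohort_no_missing(self, default_cohort):
        table = build_feature_table(clean_cohort(default_cohort), 60, seed=0)
        assert len(table) == 210
        assert not table.drop(columns="student_id").isna().any().any()

    def test_null_cohort_features_uncorrelated(self, null_large_cohort):
        table = build_feature_table(clean_cohort(null_large_cohort), 60, seed=0)
        y = table["label"].to_numpy().astype(float)
        from deeppsy.features import FEATURE_COLUMNS

        for col in FEATURE_COLUMNS:
            x = table[col].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            assert abs(r) < 0.1, f"{col}: point-biserial r={r}"

    def test_strong_cohort_entropy_gap(self, strong_cohort):
        table = build_feature_table(clean_cohort(strong_cohort), 60, seed=0)
        md = table["label"] == 1
        assert (
            table.loc[md, "dining_entropy"].mean()
            > table.loc[~md, "dining_entropy"].mean()
        )
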