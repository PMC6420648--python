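import numpy as np
import pytest

from crn import (
    DataKind,
    ExpressionDataset,
    MeasureSpec,
    NotApplicableError,
    association_matrix,
    correlation,
    distance_to_similarity,
    dtw_distance,
    minkowski_distance,
    qualitative_distance,
    qualitative_trend,
    symbolic_similarity,
    symbolize,
)
from crn.association import (
    DTWInfeasibleError,
    Trend,
    UndefinedCorrelationError,
    default_alpha,
    pair_association,
)

import oracles


class TestCorrelation:
    def test_pearson_exact_linearity(self):
        assert correlation([1, 2, 3], [2, 4, 6], "pearson") == pytest.approx(1.0)

    def test_kendall_hand_count(self):
        # pairs (1,2),(1,3) concordant; (2,3) discordant -> (2-1)*2/(3*2)
        assert correlation([1, 2, 3], [1, 3, 2], "kendall") == pytest.approx(1 / 3)

    def test_kendall_matches_pair_enumeration_oracle(self, rng):
        for _ in range(30):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert correlation(x, y, "kendall") == pytest.approx(
                oracles.kendall_tau_a(x, y)
            )

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=15)
        y = np.exp(2 * x) + 1  # strictly increasing nonlinear transform
        assert correlation(x, y, "spearman") == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "pearson")


class TestDistances:
    @pytest.mark.parametrize(
        "x, y, s, expected",
        [((0, 0), (1, 1), 1, 2.0), ((0, 0), (3, 4), 2, 5.0), ((1, 2, 3), (1, 2, 3), 10, 0.0)],
    )
    def test_minkowski_norms(self, x, y, s, expected):
        assert minkowski_distance(x, y, s) == pytest.approx(expected)

    def test_similarity_mapping(self):
        assert distance_to_similarity(0.0) == 1.0
        assert distance_to_similarity(1.0) == 0.5
        deltas = [0.0, 0.3, 1.7, 9.0]
        sims = [distance_to_similarity(d) for d in deltas]
        assert sims == sorted(sims, reverse=True)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_to_similarity(-0.1)


class TestDTW:
    def test_self_distance_zero(self, rng):
        x = rng.normal(size=6)
        for pattern in ("symmetric1", "symmetric2", "asymmetric"):
            assert dtw_distance(x, x, pattern) == pytest.approx(0.0)

    @pytest.mark.parametrize("pattern", ["symmetric1", "symmetric2", "asymmetric"])
    def test_matches_path_enumeration_oracle(self, rng, pattern):
        for _ in range(15):
            n, m = rng.integers(2, 6, size=2)
            if pattern == "asymmetric" and m > 2 * n - 1:
                continue
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            assert dtw_distance(x, y, pattern) == pytest.approx(
                oracles.dtw_brute_force(x, y, pattern)
            )

    def test_symmetric2_at_least_symmetric1(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=4)
            assert dtw_distance(x, y, "symmetric2") >= dtw_distance(x, y, "symmetric1") - 1e-12

    def test_symmetric_patterns_are_symmetric(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=7)
        for pattern in ("symmetric1", "symmetric2"):
            assert dtw_distance(x, y, pattern) == pytest.approx(dtw_distance(y, x, pattern))

    def test_asymmetric_infeasible_alignment(self):
        # each query point consumes at most 2 reference points
        with pytest.raises(DTWInfeasibleError):
            dtw_distance([0.0, 1.0], [0.0, 0.5, 1.0, 1.5], "asymmetric")


class TestSymbolic:
    @pytest.mark.parametrize(
        "a, b, tol, expected",
        [
            (1.0, 2.0, 0.0, Trend.INCREASE),
            (2.0, 2.0, 0.0, Trend.NO_CHANGE),
            (2.0, 1.0, 0.0, Trend.DECREASE),
            (1.00, 1.005, 0.01, Trend.NO_CHANGE),
        ],
    )
    def test_trend_categories(self, a, b, tol, expected):
        assert qualitative_trend(a, b, tol) is expected

    def test_qd_identical_series(self, rng):
        x = rng.normal(size=8)
        assert qualitative_distance(x, x) == 0.0

    def test_qd_opposite_monotone_series(self):
        assert qualitative_distance([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_qd_single_pair_table_lookup(self):
        # one pair: increase vs no-change -> Diff = 0.5
        assert qualitative_distance([1, 2], [5, 5]) == pytest.approx(0.5)

    def test_step_symbols(self):
        sx = symbolize([1, 2, 3, 2], alpha=1)
        assert sx.steps == [Trend.INCREASE, Trend.INCREASE, Trend.DECREASE]

    def test_alpha_rule(self):
        assert default_alpha(12) == 5
        assert default_alpha(6) == 2

    def test_alpha_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="reducing"):
            sx = symbolize([1, 2, 3], alpha=5)
        assert sx.alpha == 2

    def test_sequence_similarity_limits(self, rng):
        x = rng.normal(size=9)
        sx = symbolize(x, alpha=2)
        assert symbolic_similarity(sx, sx, "sequence") == 1.0
        sy = symbolize(-x, alpha=2)  # every trend flipped
        assert symbolic_similarity(sx, sy, "sequence") == 0.0

    def test_combined_mode_limits(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        sx, sy = symbolize(x, alpha=2), symbolize(y, alpha=2)
        seq = symbolic_similarity(sx, sy, "sequence")
        mi_part = symbolic_similarity(sx, sy, "combined", weight=0.0)
        assert symbolic_similarity(sx, sy, "combined", weight=1.0) == pytest.approx(seq)
        assert 0.0 <= mi_part <= 1.0

    def test_alpha_mismatch_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="alpha"):
            symbolic_similarity(symbolize(x, alpha=2), symbolize(x, alpha=3))


class TestAssociationMatrix:
    SPECS = [
        MeasureSpec.make("correlation", "pearson"),
        MeasureSpec.make("correlation", "kendall"),
        MeasureSpec.make("information", "mi", estimator="mm", discretization="equal_freq"),
        MeasureSpec.make("distance", "s2"),
        MeasureSpec.make("dtw", "symmetric2"),
        MeasureSpec.make("symbolic", "qd"),
        MeasureSpec.make("symbolic", "combined", symbolization="equal_width"),
    ]

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: f"{s.family.value}-{s.variant}")
    def test_matches_pairwise_loop_oracle(self, small_ts_dataset, spec):
        W = association_matrix(small_ts_dataset, spec)
        assert W.symmetric
        m = small_ts_dataset.m
        for i in range(m):
            for j in range(m):
                if i == j:
                    assert np.isnan(W.scores[i, j])
                    continue
                want = pair_association(
                    small_ts_dataset.values[i], small_ts_dataset.values[j], spec
                )
                assert W.scores[i, j] == pytest.approx(want)
                assert W.scores[i, j] >= 0

    def test_duplicated_profiles_score_maximal(self):
        v = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        ds = ExpressionDataset(
            gene_ids=["a", "b", "c"],
            values=np.vstack([v, v, v[::-1]]),
            kind="time_series",
        )
        for spec in (MeasureSpec.make("correlation", "pearson"), MeasureSpec.make("distance", "s1")):
            W = association_matrix(ds, spec)
            assert W.scores[0, 1] == pytest.approx(1.0)

    def test_time_only_measures_reject_steady_state(self, small_ss_dataset):
        for family, variant in (("dtw", "symmetric1"), ("symbolic", "qd")):
            with pytest.raises(NotApplicableError):
                association_matrix(small_ss_dataset, MeasureSpec.make(family, variant))

    def test_zero_variance_profile_warns_and_scores_zero(self):
        ds = ExpressionDataset(
            gene_ids=["a", "b", "c"],
            values=np.array([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [4, 2, 3, 1]]),
            kind="time_series",
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            W = association_matrix(ds, MeasureSpec.make("correlation", "spearman"))
        assert W.scores[0, 1] == 0.0 and W.scores[0, 2] == 0.0
        assert W.scores[1, 2] > 0

    def test_correlation_affine_invariance(self, small_ts_dataset):
        spec = MeasureSpec.make("correlation", "pearson")
        W1 = association_matrix(small_ts_dataset, spec)
        ds2 = ExpressionDataset(
            gene_ids=small_ts_dataset.gene_ids,
            values=3.0 * small_ts_dataset.values + 7.0,
            kind=DataKind.TIME_SERIES,
        )
        W2 = association_matrix(ds2, spec)
        off = ~np.eye(small_ts_dataset.m, dtype=bool)
        np.testing.assert_allclose(W1.scores[off], W2.scores[off], atol=1e-12)
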