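"""Discretisation, mutual information and mRMR selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import mutual_info_score

from strandclass import (
    FeatureMatrix,
    StrandclassError,
    discretize,
    mrmr_rank,
    mutual_information,
    relevance_scores,
    threshold_select,
)
from strandclass.select import entropy, threshold_sweep

from oracles import discretize_oracle, entropy_oracle, mi_oracle, mrmr_greedy_oracle

state_vectors = st.lists(st.integers(0, 3), min_size=2, max_size=40)


def make_matrix(columns, y, names=None):
    columns = np.asarray(columns, dtype=float)
    n, p = columns.shape
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        labels=["SSB" if v else "DSB" for v in y],
        columns=names or [f"f{j}" for j in range(p)],
        values=columns,
    )


class TestDiscretize:
    def test_constant_column_single_state(self):
        assert discretize(np.zeros(4)).tolist() == [1, 1, 1, 1]

    def test_three_state_arithmetic(self):
        assert discretize(np.array([-10.0, 0.0, 0.0, 10.0])).tolist() == [0, 1, 1, 2]

    def test_deterministic(self, rng):
        col = rng.standard_normal(50)
        assert discretize(col).tolist() == discretize(col).tolist()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(col=st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    def test_matches_plain_python_oracle(self, col):
        assert discretize(np.array(col)).tolist() == discretize_oracle(col)


class TestMutualInformation:
    def test_identical_binary_vectors(self):
        a = np.array([0, 1, 0, 1])
        assert mutual_information(a, a) == pytest.approx(1.0)

    def test_independent_joint_is_zero(self):
        assert mutual_information(
            np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])
        ) == pytest.approx(0.0)

    def test_hand_computed_joint(self):
        # joint counts: (0,0)=2, (1,0)=1, (1,1)=1 over n=4
        got = mutual_information(np.array([0, 0, 1, 1]), np.array([0, 0, 0, 1]))
        assert got == pytest.approx(mi_oracle([0, 0, 1, 1], [0, 0, 0, 1]))
        assert got == pytest.approx(0.31127812445913283)

    def test_length_mismatch(self):
        with pytest.raises(StrandclassError, match="shape"):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=state_vectors, b=state_vectors)
    def test_symmetry_and_entropy_bound(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        iab = mutual_information(a, b)
        assert iab == pytest.approx(mutual_information(b, a))
        assert iab <= min(entropy(a), entropy(b)) + 1e-12
        assert iab >= -1e-12

    def test_self_information_is_entropy(self, rng):
        a = rng.integers(0, 3, size=60)
        assert mutual_information(a, a) == pytest.approx(entropy_oracle(a.tolist()))

    def test_agrees_with_sklearn_in_nats(self, rng):
        a = rng.integers(0, 3, size=80)
        b = rng.integers(0, 4, size=80)
        ours_nats = mutual_information(a, b) * np.log(2)
        assert ours_nats == pytest.approx(mutual_info_score(a, b), abs=1e-12)


class TestMrmrRank:
    def test_label_copy_ranked_first(self, rng):
        y = rng.integers(0, 2, size=40)
        noise = rng.standard_normal((40, 3))
        cols = np.column_stack([noise[:, 0], y * 10.0, noise[:, 1:]])
        res = mrmr_rank(make_matrix(cols, y), k=2)
        assert res.ranked_columns[0] == "f1"

    def test_duplicate_of_top_column_demoted(self):
        """With two identical copies of the most relevant column, the second
        pick must be the weaker independent column: the duplicate's redundancy
        with the first pick (its full entropy) swamps its relevance."""
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 20)
        strong = y.astype(float)
        flip = rng.choice(40, 4, replace=False)
        strong[flip] = 1 - strong[flip]  # strong but imperfect label correlate
        weak = y.astype(float)
        flip2 = rng.choice(40, 12, replace=False)
        weak[flip2] = 1 - weak[flip2]  # weaker, independently corrupted
        noise = rng.standard_normal(40)
        cols = np.column_stack([strong * 10, strong * 10, weak * 5, noise])
        res = mrmr_rank(make_matrix(cols, y), k=2)
        assert res.ranked_columns == ["f0", "f2"]
        # brute-force check of the step-2 criterion: duplicate scores rel - H < 0
        from strandclass import discretize
        disc = [discretize(cols[:, j]).tolist() for j in range(4)]
        assert mrmr_greedy_oracle(disc, y.tolist(), 2) == [0, 2]

    def test_k_equals_all_columns_is_permutation(self, rng):
        y = rng.integers(0, 2, size=30)
        cols = rng.standard_normal((30, 6))
        res = mrmr_rank(make_matrix(cols, y), k=6)
        assert sorted(res.ranked_columns) == [f"f{j}" for j in range(6)]

    def test_k1_equals_argmax_relevance(self, rng):
        y = rng.integers(0, 2, size=50)
        cols = rng.standard_normal((50, 8))
        m = make_matrix(cols, y)
        res = mrmr_rank(m, k=1)
        rel = relevance_scores(m)
        assert res.ranked_columns[0] == max(m.columns, key=lambda c: rel[c])

    def test_single_class_rejected(self, rng):
        cols = rng.standard_normal((10, 3))
        with pytest.raises(StrandclassError, match="both classes"):
            mrmr_rank(make_matrix(cols, np.ones(10, dtype=int)), k=1)

    def test_matches_brute_force_oracle(self, rng):
        """Greedy selection equals an independently coded oracle on small
        random matrices (<= 8 columns, <= 30 samples)."""
        for trial in range(10):
            n = int(rng.integers(12, 31))
            p = int(rng.integers(3, 9))
            y = rng.integers(0, 2, size=n)
            while len(set(y.tolist())) < 2:
                y = rng.integers(0, 2, size=n)
            cols = rng.standard_normal((n, p))
            cols[:, 0] += y  # ensure some signal
            m = make_matrix(cols, y)
            k = int(rng.integers(1, p + 1))
            res = mrmr_rank(m, k)
            disc = [discretize(cols[:, j]).tolist() for j in range(p)]
            expected = mrmr_greedy_oracle(disc, y.tolist(), k)
            assert res.ranked_columns == [f"f{j}" for j in expected]


class TestThresholdSelect:
    def test_zero_threshold_keeps_positive_relevance(self, rng):
        y = rng.integers(0, 2, size=40)
        cols = np.column_stack([y * 1.0, rng.standard_normal(40)])
        m = make_matrix(cols, y)
        rel = relevance_scores(m)
        sel = threshold_select(m, 0.0)
        assert sel.matrix.columns == [c for c in m.columns if rel[c] > 0]

    def test_threshold_above_max_gives_empty(self, rng, caplog):
        y = rng.integers(0, 2, size=20)
        m = make_matrix(rng.standard_normal((20, 3)), y)
        with caplog.at_level("WARNING"):
            sel = threshold_select(m, 10.0)
        assert sel.retained == 0 and sel.matrix.n_columns == 0
        assert "retains no columns" in caplog.text

    def test_direct_comparison_with_known_relevances(self):
        m = make_matrix(np.zeros((4, 3)), [0, 1, 0, 1])
        rel = {"f0": 0.5, "f1": 0.001, "f2": 0.3}
        sel = threshold_select(m, 0.005, relevance=rel)
        assert sel.matrix.columns == ["f0", "f2"]
        assert (sel.threshold, sel.retained) == (0.005, 2)

    def test_sweep_counts_are_monotone(self, rng):
        y = rng.integers(0, 2, size=40)
        m = make_matrix(rng.standard_normal((40, 10)), y)
        sweep = threshold_sweep(m, [0.0, 0.01, 0.1, 1.0])
        counts = [c for _, c in sweep]
        assert counts == sorted(counts, reverse=True)
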