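import numpy as np
import pytest

from tests.conftest import brute_force_tomek_links
from toxbalance.sampling import (
    DegeneratePoolError,
    SamplePool,
    find_tomek_links,
    is_danger,
    its,
    its_sampling_step,
    random_oversample,
    random_undersample,
    smote,
    tomek_clean,
)


def _pool(minority, majority):
    minority = np.asarray(minority, dtype=float)
    majority = np.asarray(majority, dtype=float)
    features = np.vstack([minority, majority])
    labels = np.r_[np.ones(len(minority), dtype=int),
                   np.zeros(len(majority), dtype=int)]
    return SamplePool(features=features, labels=labels)


def _row_multiset(x):
    return sorted(map(tuple, np.round(x, 12)))


class TestSamplePool:
    def test_roles_from_counts_not_polarity(self):
        # positive class is the MAJORITY here; roles must follow counts
        pool = SamplePool(features=np.zeros((5, 1)),
                          labels=np.array([1, 1, 1, 1, 0]))
        assert pool.minority_label == 0
        assert pool.n_minority == 1

    def test_tie_prefers_positive_as_minority(self):
        pool = SamplePool(features=np.zeros((4, 1)),
                          labels=np.array([1, 1, 0, 0]))
        assert pool.minority_label == 1


class TestRandomUnderOver:
    def test_rus_equalizes_table_counts(self, overlap_pool):
        out = random_undersample(overlap_pool, seed=1)
        assert out.n_minority == out.n_majority == overlap_pool.n_minority

    def test_rus_majority_subset_of_input(self, overlap_pool):
        out = random_undersample(overlap_pool, seed=2)
        orig = set(_row_multiset(overlap_pool.features[overlap_pool.majority_indices]))
        kept = _row_multiset(out.features[out.majority_indices])
        assert all(row in orig for row in kept)

    def test_rus_minority_untouched(self, overlap_pool):
        out = random_undersample(overlap_pool, seed=3)
        assert _row_multiset(out.features[out.minority_indices]) == \
            _row_multiset(overlap_pool.features[overlap_pool.minority_indices])

    def test_ros_equalizes(self, overlap_pool):
        out = random_oversample(overlap_pool, seed=1)
        assert out.n_minority == out.n_majority == overlap_pool.n_majority

    def test_ros_new_rows_duplicate_originals(self, overlap_pool):
        out = random_oversample(overlap_pool, seed=4)
        orig = set(_row_multiset(overlap_pool.features[overlap_pool.minority_indices]))
        assert all(row in orig
                   for row in _row_multiset(out.features[out.minority_indices]))

    def test_balanced_input_identity(self):
        pool = _pool([[0.0], [1.0]], [[5.0], [6.0]])
        for fn in (random_undersample, random_oversample):
            out = fn(pool, seed=0)
            assert _row_multiset(out.features) == _row_multiset(pool.features)

    def test_determinism(self, overlap_pool):
        for fn in (random_undersample, random_oversample):
            a, b = fn(overlap_pool, seed=9), fn(overlap_pool, seed=9)
            np.testing.assert_array_equal(a.features, b.features)

    def test_degenerate_pool(self):
        pool = SamplePool(features=np.zeros((3, 1)), labels=np.array([0, 0, 0]))
        with pytest.raises(DegeneratePoolError):
            random_undersample(pool, seed=0)


class TestSmote:
    def test_equalizes_and_reconstructs(self, overlap_pool):
        out, records = smote(overlap_pool, k_neighbors=3, seed=1,
                             return_records=True)
        assert out.n_minority == out.n_majority
        n_orig = overlap_pool.n_samples
        assert len(records) == out.n_samples - n_orig
        for t, rec in enumerate(records):
            base = overlap_pool.features[rec.base_index]
            neigh = overlap_pool.features[rec.neighbor_index]
            expected = base + rec.delta * (neigh - base)
            np.testing.assert_allclose(out.features[n_orig + t], expected,
                                       rtol=0, atol=0)
            assert 0.0 <= rec.delta <= 1.0

    def test_interpolation_formula_midpoint(self):
        # delta = 0.5 between (0,0) and (2,4) must give (1,2)
        x_i = np.array([0.0, 0.0])
        x_hat = np.array([2.0, 4.0])
        np.testing.assert_array_equal(x_i + 0.5 * (x_hat - x_i), [1.0, 2.0])

    def test_delta_endpoints(self):
        x_i, x_hat = np.array([3.0]), np.array([7.0])
        np.testing.assert_array_equal(x_i + 0.0 * (x_hat - x_i), x_i)
        np.testing.assert_array_equal(x_i + 1.0 * (x_hat - x_i), x_hat)

    def test_majority_rows_untouched(self, overlap_pool):
        out = smote(overlap_pool, seed=2)
        assert _row_multiset(out.features[out.majority_indices]) == \
            _row_multiset(overlap_pool.features[overlap_pool.majority_indices])

    def test_synthetic_on_minority_segments(self, overlap_pool):
        out, records = smote(overlap_pool, k_neighbors=3, seed=3,
                             return_records=True)
        minority_rows = {tuple(r) for r in
                         overlap_pool.features[overlap_pool.minority_indices]}
        for rec in records:
            assert tuple(overlap_pool.features[rec.base_index]) in minority_rows
            assert tuple(overlap_pool.features[rec.neighbor_index]) in minority_rows

    def test_single_minority_fallback(self):
        pool = _pool([[0.0, 0.0]], [[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.warns(UserWarning, match="replication"):
            out = smote(pool, seed=0)
        assert out.n_minority == out.n_majority == 3

    def test_determinism(self, overlap_pool):
        a = smote(overlap_pool, seed=5)
        b = smote(overlap_pool, seed=5)
        np.testing.assert_array_equal(a.features, b.features)


class TestIsDanger:
    def test_majority_point_surrounded_by_minority(self):
        pool = _pool([[0.0, 0.1], [0.1, 0.0], [0.0, -0.1]],
                     [[0.0, 0.0], [5.0, 5.0], [5.1, 5.0], [5.0, 5.1], [5.1, 5.1]])
        # majority point at the origin: 3 nearest are all minority
        assert is_danger(pool, index=3, k=3) is True

    def test_majority_point_deep_in_cluster(self):
        pool = _pool([[0.0, 0.0]],
                     [[5.0, 5.0], [5.1, 5.0], [5.0, 5.1], [5.1, 5.1]])
        assert is_danger(pool, index=1, k=3) is False

    def test_even_k_tie_is_not_danger(self):
        # query at origin, one minority and one majority equidistant
        pool = _pool([[1.0, 0.0], [9.0, 9.0]],
                     [[0.0, 0.0], [-1.0, 0.0], [9.0, 8.0]])
        assert is_danger(pool, index=2, k=2) is False

    def test_k_bounds(self):
        pool = _pool([[0.0]], [[1.0]])
        with pytest.raises(ValueError):
            is_danger(pool, 0, k=0)
        with pytest.raises(ValueError):
            is_danger(pool, 0, k=2)


class TestItsSamplingStep:
    def test_postcondition_equality(self, overlap_pool):
        out, _ = its_sampling_step(overlap_pool, k_init=15, seed=0)
        assert out.n_minority == out.n_majority

    def test_already_balanced_identity(self):
        pool = _pool([[0.0, 0.0], [0.1, 0.1]], [[5.0, 5.0], [5.1, 5.1]])
        out, trace = its_sampling_step(pool, k_init=5, seed=0)
        assert _row_multiset(out.features) == _row_multiset(pool.features)
        assert trace.iterations == []

    def test_separated_blobs_minority_doubles(self):
        # 3 minority + 9 majority, far apart: no majority sample is Danger,
        # every minority sample sits in a minority-dominated neighborhood at
        # k=2, so each iteration replicates the whole minority class:
        # 3 -> 6 -> 9 (hand-simulated loop on 12 points)
        minority = [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1]]
        majority = [[10 + i, 10 + j] for i in range(3) for j in range(3)]
        pool = _pool(minority, majority)
        out, trace = its_sampling_step(pool, k_init=2, seed=0)
        assert out.n_minority == out.n_majority == 9
        assert [it["replicated"] for it in trace.iterations] == [3, 3]
        assert all(it["removed"] == 0 for it in trace.iterations)

    def test_trace_monotonicity(self, overlap_pool):
        _, trace = its_sampling_step(overlap_pool, k_init=15, seed=1)
        maj = [it["n_majority_before"] for it in trace.iterations]
        mino = [it["n_minority_before"] for it in trace.iterations]
        assert maj == sorted(maj, reverse=True)
        assert mino == sorted(mino)

    def test_forced_balance_warning(self):
        # far-apart classes, k_init=1 with neighborhoods too mixed to close
        # the gap in one iteration
        rng = np.random.default_rng(0)
        pool = _pool(rng.normal(size=(5, 2)), rng.normal(size=(40, 2)) + 0.5)
        with pytest.warns(UserWarning, match="forcing balance"):
            out, trace = its_sampling_step(pool, k_init=1, seed=0)
        assert out.n_minority == out.n_majority
        assert trace.forced_balance

    def test_determinism(self, overlap_pool):
        a, _ = its_sampling_step(overlap_pool, k_init=15, seed=6)
        b, _ = its_sampling_step(overlap_pool, k_init=15, seed=6)
        np.testing.assert_array_equal(a.features, b.features)

    def test_empty_minority_rejected(self):
        pool = SamplePool(features=np.zeros((4, 1)), labels=np.zeros(4, dtype=int))
        with pytest.raises(DegeneratePoolError):
            its_sampling_step(pool, seed=0)


class TestTomekLinks:
    def test_one_sample_per_class_is_link(self):
        pool = _pool([[0.0, 0.0]], [[1.0, 1.0]])
        links = find_tomek_links(pool)
        assert len(links) == 1
        assert {links[0].i, links[0].j} == {0, 1}

    def test_blocked_by_closer_same_class_neighbor(self):
        # 1-D: minority {0}, majority {1, 1.1}; d(1, 1.1) < d(0, 1) blocks
        # the cross pair
        pool = _pool([[0.0]], [[1.0], [1.1]])
        assert find_tomek_links(pool) == []

    def test_single_class_empty(self):
        pool = SamplePool(features=np.zeros((3, 1)), labels=np.ones(3, dtype=int))
        assert find_tomek_links(pool) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pool = SamplePool(features=rng.normal(size=(20, 3)),
                          labels=rng.integers(0, 2, size=20))
        if pool.n_minority == 0:
            pytest.skip("degenerate draw")
        got = sorted((l.i, l.j) for l in find_tomek_links(pool))
        assert got == sorted(brute_force_tomek_links(pool))


class TestTomekClean:
    def test_no_links_identity(self):
        pool = _pool([[0.0], [0.1]], [[10.0], [10.1]])
        out, removed = tomek_clean(pool)
        assert _row_multiset(out.features) == _row_multiset(pool.features)
        assert removed == {0: 0, 1: 0}

    def test_idempotent(self, overlap_pool):
        once, _ = tomek_clean(overlap_pool)
        twice, removed = tomek_clean(once)
        assert _row_multiset(twice.features) == _row_multiset(once.features)
        assert removed == {0: 0, 1: 0}

    def test_interleaved_line_fully_cleaned(self):
        # interleaved 1-D points of alternating class, anchored by tight
        # same-class clusters so cleaning can terminate with no links
        xs = np.array([0.0, 1.0, 2.0, 3.0, 20.0, 20.1, 40.0, 40.1])[:, None]
        labels = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        pool = SamplePool(features=xs, labels=labels)
        out, removed = tomek_clean(pool)
        assert find_tomek_links(out) == []
        assert removed[0] == removed[1] == 2

    def test_equal_per_class_removal(self, overlap_pool):
        balanced, _ = its_sampling_step(overlap_pool, k_init=15, seed=0)
        cleaned, removed = tomek_clean(balanced)
        assert removed[0] == removed[1]
        assert cleaned.n_minority == cleaned.n_majority

    def test_never_empties_a_class(self):
        pool = _pool([[0.0]], [[0.5]])
        with pytest.warns(UserWarning, match="emptied"):
            out, _ = tomek_clean(pool)
        assert out.n_minority >= 1 and out.n_majority >= 1


class TestItsFull:
    def test_no_links_after(self, overlap_pool):
        out, _ = its(overlap_pool, k_init=15, seed=0)
        assert find_tomek_links(out) == []

    def test_counts_equal_after_cleaning(self, overlap_pool):
        out, _ = its(overlap_pool, k_init=15, seed=0)
        assert out.n_minority == out.n_majority

    def test_overlap_fixture_shrinks_after_cleaning(self):
        from toxbalance.synthetic import table2_fixture

        pool = table2_fixture("mutagenic", separation=1.5,
                              overlap_fraction=0.3, seed=1)
        balanced, _ = its_sampling_step(pool, k_init=15, seed=1)
        cleaned, trace = its(pool, k_init=15, seed=1)
        assert cleaned.n_samples < balanced.n_samples
        assert trace.cleaning["removed_minority"] == trace.cleaning["removed_majority"] > 0

    def test_determinism(self, overlap_pool):
        a, ta = its(overlap_pool, k_init=15, seed=8)
        b, tb = its(overlap_pool, k_init=15, seed=8)
        np.testing.assert_array_equal(a.features, b.features)
        assert ta.to_json() == tb.to_json()
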