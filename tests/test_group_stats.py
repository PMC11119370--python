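import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectrl import (
    ControllabilityProfile,
    bh_fdr,
    compare_groups,
    mann_whitney,
    top_k,
    two_sample_t,
)


def brute_force_u(x, y):
    """U for the first sample: count of (x > y) pairs plus half-ties."""
    x, y = np.asarray(x), np.asarray(y)
    return float(((x[:, None] > y[None, :]).sum()) + 0.5 * (x[:, None] == y[None, :]).sum())


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_pooled_formula_by_hand(self):
        # means 2 and 3, pooled sd 1 -> t = -1 / sqrt(2/3)
        t, _ = two_sample_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.0 / np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_large_df_tail_probability(self):
        """Two-sided p of t = 3.1404 at df = 284 is 0.0019 to 2 significant
        figures (the regime of a 130 + 156 subject comparison)."""
        from scipy import stats

        p = 2 * stats.t.sf(3.1404, df=284)
        assert p == pytest.approx(0.0019, abs=5e-5)

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_midranks(self):
        u, _ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == 4.5  # n^2 / 2 with midrank ties

    @pytest.mark.parametrize("seed", range(6))
    def test_u_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 13, size=2)
        x = rng.integers(0, 8, size=nx).astype(float)  # integers force ties
        y = rng.integers(0, 8, size=ny).astype(float)
        u, _ = mann_whitney(x, y)
        assert u == pytest.approx(brute_force_u(x, y))

    def test_empty_group(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=20))
    @settings(max_examples=30, deadline=None)
    def test_p_invariant_under_monotone_transform(self, pooled):
        x = np.array(pooled[: len(pooled) // 2])
        y = np.array(pooled[len(pooled) // 2:])
        _, p1 = mann_whitney(x, y)
        # power-of-two scaling: exactly representable, strictly increasing,
        # and preserves float ties exactly
        _, p2 = mann_whitney(4.0 * x, 4.0 * y)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_dominates_raw_p(self, ps):
        adjusted = bh_fdr(ps)
        assert np.all(adjusted >= np.asarray(ps) - 1e-12)
        assert np.all(adjusted <= 1.0 + 1e-12)


def profiles_from(values_a, values_b, labels):
    out = []
    for i, v in enumerate(values_a):
        out.append(ControllabilityProfile(f"a{i}", 0, np.asarray(v, float), labels))
    for i, v in enumerate(values_b):
        out.append(ControllabilityProfile(f"b{i}", 1, np.asarray(v, float), labels))
    return out


class TestCompareGroups:
    def test_diff_is_mean_difference(self, small_table, small_profiles):
        import numpy as np

        a = np.array([p.values for p in small_profiles if p.group_label == 0])
        b = np.array([p.values for p in small_profiles if p.group_label == 1])
        for j, row in enumerate(small_table.rows):
            assert row.diff == pytest.approx(a[:, j].mean() - b[:, j].mean(), abs=1e-12)
            if row.diff != 0:
                assert np.sign(row.t_value) == np.sign(row.diff)
            assert row.p_fdr >= row.p_t - 1e-12

    def test_swapping_groups_negates_diff_and_t(self, small_profiles):
        table = compare_groups(small_profiles)
        swapped = [
            ControllabilityProfile(p.subject_id, 1 - p.group_label, p.values, p.region_labels)
            for p in small_profiles
        ]
        table2 = compare_groups(swapped)
        for r1, r2 in zip(table.rows, table2.rows):
            assert r2.diff == pytest.approx(-r1.diff, abs=1e-12)
            assert r2.t_value == pytest.approx(-r1.t_value, abs=1e-10)
            assert r2.p_t == pytest.approx(r1.p_t, abs=1e-12)

    def test_constant_shift_leaves_tests_unchanged(self, small_profiles):
        table = compare_groups(small_profiles)
        shifted = [
            ControllabilityProfile(p.subject_id, p.group_label, p.values + 2.5, p.region_labels)
            for p in small_profiles
        ]
        table2 = compare_groups(shifted)
        for r1, r2 in zip(table.rows, table2.rows):
            assert r2.t_value == pytest.approx(r1.t_value, abs=1e-8)
            assert r2.u_value == pytest.approx(r1.u_value)

    def test_label_mismatch_reported(self):
        labels = ["A", "B"]
        profs = profiles_from([[1.0, 2.0]], [[1.1, 2.1]], labels)
        profs.append(ControllabilityProfile("c0", 1, np.array([1.0, 2.0]), ["A", "C"]))
        with pytest.raises(ValueError, match="c0"):
            compare_groups(profs)

    def test_empty_group_rejected(self):
        labels = ["A"]
        with pytest.raises(ValueError):
            compare_groups(profiles_from([[1.0], [1.2]], [], labels))


class TestTopK:
    def test_max_selection(self, small_table):
        diffs = {r.region_name: r.diff for r in small_table.rows}
        [name] = top_k(small_table, 1, "decreased-in-B")
        assert diffs[name] == max(diffs.values())

    def test_full_ordering_matches_sort(self, small_table):
        names = top_k(small_table, len(small_table.rows), "elevated-in-B")
        diffs = [next(r.diff for r in small_table.rows if r.region_name == n) for n in names]
        assert diffs == sorted(diffs)

    def test_invalid_direction(self, small_table):
        with pytest.raises(ValueError, match="direction"):
            top_k(small_table, 3, "sideways")

    def test_k_out_of_range(self, small_table):
        with pytest.raises(ValueError):
            top_k(small_table, 0, "elevated-in-B")
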