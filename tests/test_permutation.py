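"""Permutation null for top-cell overlap: contracts and calibration."""

import numpy as np
import pytest

from miniens import (
    InvalidInputError,
    PermutationParams,
    group_p,
    p_value,
    permutation_test,
    real_top_overlap,
    shuffle_null,
)


class TestRealOverlap:
    def test_identical_ranks_without_exclusion(self, rng):
        rates = rng.uniform(0.1, 1, 100)
        params = PermutationParams(exclude_triple=False)
        res = real_top_overlap(rates, rates, rates, params)
        assert res["A-B"][0] == pytest.approx(1.0)
        assert res["HC-B"][0] == pytest.approx(1.0)

    def test_triple_cells_removed_from_both_comparisons(self):
        # cell 0 tops every session; cells 1/2/3 differ
        a = np.array([10.0, 9.0] + [1.0] * 18)
        hc = np.array([10.0, 0.5, 9.0] + [1.0] * 17)
        b = np.array([10.0, 9.0] + [1.0] * 18)
        params = PermutationParams(q=0.10)  # top-2 sets of 20 cells
        res = real_top_overlap(a, b, hc, params)
        # triple = {0}; top_b after exclusion = {1}; A-B shares {1}, HC-B none
        assert res["A-B"] == (1.0, 1)
        assert res["HC-B"] == (0.0, 1)

    def test_disjoint_tops_zero(self):
        a = np.array([10.0] + [1.0] * 19)
        b = np.array([1.0, 10.0] + [1.0] * 18)
        res = real_top_overlap(a, b, None, PermutationParams(q=0.05))
        assert res["A-B"][0] == 0.0

    def test_two_session_form_has_single_comparison(self, rng):
        res = real_top_overlap(rng.uniform(0.1, 1, 50), rng.uniform(0.1, 1, 50))
        assert set(res) == {"A-B"}

    def test_mismatched_universe_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            real_top_overlap(rng.uniform(0.1, 1, 50), rng.uniform(0.1, 1, 40))


class TestShuffleNull:
    def test_null_values_on_count_grid(self, rng):
        rates = rng.uniform(0.1, 1, 100)
        params = PermutationParams(n_shuffles=50, q=0.10, seed=1, exclude_triple=False)
        null = shuffle_null(rates, rates, rates, params)["A-B"]
        np.testing.assert_allclose(null * 10, np.round(null * 10), atol=1e-12)

    def test_null_mean_near_q_for_large_universe(self, rng):
        a = rng.uniform(0.1, 1, 2000)
        b = rng.uniform(0.1, 1, 2000)
        params = PermutationParams(n_shuffles=300, q=0.10, seed=2)
        null = shuffle_null(a, b, None, params)["A-B"]
        # E|topA ∩ perm(topB)| / |topB| = q under random assignment
        assert null.mean() == pytest.approx(0.10, abs=0.01)

    def test_same_seed_identical_null(self, rng):
        a, b = rng.uniform(0.1, 1, (2, 100))
        params = PermutationParams(n_shuffles=20, seed=7)
        n1 = shuffle_null(a, b, None, params)["A-B"]
        n2 = shuffle_null(a, b, None, params)["A-B"]
        np.testing.assert_array_equal(n1, n2)


class TestPValue:
    def test_real_above_all_null_gives_zero(self):
        assert p_value(0.9, np.full(100, 0.1)) == 0.0

    def test_real_at_minimum_gives_one(self):
        null = np.linspace(0.1, 0.9, 100)
        assert p_value(0.1, null) == 1.0

    def test_plus_one_correction_bounds_away_from_zero(self):
        assert p_value(0.9, np.full(99, 0.1), plus_one_correction=True) == pytest.approx(
            1 / 100
        )

    def test_probability_integral_transform_near_uniform(self, rng):
        # real drawn from its own null -> p approximately uniform on the grid
        ps = []
        for _ in range(400):
            null = rng.binomial(20, 0.3, size=100) / 20
            real = rng.binomial(20, 0.3) / 20
            ps.append(p_value(real, null))
        ps = np.array(ps)
        # mean of p for the ">=" estimator sits near 0.5 + half the tie mass
        assert 0.45 < ps.mean() < 0.65
        assert (ps <= 0.2).mean() < 0.25

    def test_empty_null_rejected(self):
        with pytest.raises(InvalidInputError):
            p_value(0.5, np.array([]))


class TestGroupP:
    def test_single_subject_reduces_to_subject_p(self, rng):
        a, b = rng.uniform(0.1, 1, (2, 200))
        params = PermutationParams(n_shuffles=100, seed=3)
        res = permutation_test(a, b, None, params)["A-B"]
        gp = group_p(np.array([res.real_overlap]), res.null_overlaps[None, :])
        assert gp == res.p_value

    def test_real_at_null_median_gives_half(self, rng):
        n_subj, n_shuf = 8, 200
        nulls = rng.normal(0.1, 0.02, (n_subj, n_shuf))
        reals = np.median(nulls, axis=1)
        gp = group_p(reals, nulls)
        assert gp == pytest.approx(0.5, abs=0.1)

    def test_nan_subjects_excluded(self, rng):
        nulls = rng.normal(0.1, 0.02, (3, 50))
        reals = np.array([np.nan, 0.5, 0.5])
        gp = group_p(reals, nulls)
        assert 0.0 <= gp <= 1.0

    def test_pooled_variant_runs(self, rng):
        nulls = rng.normal(0.1, 0.02, (4, 50))
        reals = np.full(4, 0.12)
        assert 0.0 <= group_p(reals, nulls, method="pooled") <= 1.0


class TestCalibrationAndPower:
    def test_type_i_error_within_band(self, rng):
        """Independent ranks: rejection at alpha=0.05 stays near nominal."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            a, hc, b = rng.uniform(0.01, 1.0, (3, 500))
            params = PermutationParams(
                n_shuffles=100, q=0.10, seed=int(rng.integers(2**31))
            )
            res = permutation_test(a, b, hc, params)
            rejections += res["A-B"].p_value < 0.05
        rate = rejections / reps
        assert 0.02 <= rate <= 0.08  # wider CI at 300 replicates

    def test_power_increases_with_shared_top_fraction(self, rng):
        """Designed ensemble reuse makes rejections monotonically more likely."""
        rates_power = []
        for reuse in (0.0, 0.5, 1.0):
            rej = 0
            reps = 60
            for _ in range(reps):
                u = 300
                a = rng.uniform(0.01, 1.0, u)
                b = rng.uniform(0.01, 1.0, u)
                n_top = 30
                top_a = np.argsort(-a)[:n_top]
                boost = top_a[: int(reuse * n_top)]
                b[boost] = b.max() + rng.uniform(0.1, 1.0, boost.size)
                hc = rng.uniform(0.01, 1.0, u)
                params = PermutationParams(
                    n_shuffles=100, q=0.10, seed=int(rng.integers(2**31))
                )
                rej += permutation_test(a, b, hc, params)["A-B"].p_value < 0.05
            rates_power.append(rej / reps)
        assert rates_power[0] < rates_power[2]
        assert rates_power[0] <= rates_power[1] <= rates_power[2] + 1e-9

    def test_p_invariant_to_relabeling(self, rng):
        a, hc, b = rng.uniform(0.01, 1.0, (3, 200))
        params = PermutationParams(n_shuffles=100, seed=5)
        p0 = permutation_test(a, b, hc, params)["A-B"].p_value
        perm = rng.permutation(200)
        p1 = permutation_test(a[perm], b[perm], hc[perm], params)["A-B"].p_value
        assert p0 == pytest.approx(p1, abs=0.05)
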