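"""Quantile normalization, two-group tests, BH FDR and the SAM analysis."""

import itertools

import numpy as np
import pytest

from helpers_oracles import bh_stepup, quantile_norm_small, sam_d, welch_t
from mdr21 import de
from mdr21.synth import simulate_mirna_dataset


def dataset(tum, nor, ids=None):
    tum, nor = np.atleast_2d(tum), np.atleast_2d(nor)
    values = np.concatenate([tum, nor], axis=1)
    return de.ExpressionDataset(
        values=values,
        feature_ids=ids or [f"f{i}" for i in range(values.shape[0])],
        groups=np.array(["tumor"] * tum.shape[1] + ["normal"] * nor.shape[1]),
    )


class TestQuantileNormalize:
    def test_rank_means_by_hand(self):
        m = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = de.quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        m = np.column_stack([col, col, col])
        np.testing.assert_allclose(de.quantile_normalize(m), m)

    def test_sorted_columns_exactly_equal_afterwards(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (40, 5))
        out = de.quantile_normalize(m)
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = rng.normal(5, 2, (25, 4))
        once = de.quantile_normalize(m)
        twice = de.quantile_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_matches_reference_without_ties(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1, (30, 4))
        np.testing.assert_allclose(
            de.quantile_normalize(m), quantile_norm_small(m), atol=1e-12
        )

    def test_ties_share_the_mean_of_their_rank_means(self):
        m = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = de.quantile_normalize(m)
        assert out[0, 0] == out[1, 0]  # tied inputs, equal outputs

    def test_single_column_warns_and_returns_copy(self):
        m = np.array([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = de.quantile_normalize(m)
        np.testing.assert_array_equal(out, m)

    def test_missing_cells_stay_missing(self):
        m = np.array([[1.0, 4.0], [np.nan, 5.0], [3.0, 6.0], [2.0, 3.0]])
        out = de.quantile_normalize(m)
        assert np.isnan(out[1, 0]) and not np.isnan(out[1, 1])


class TestWelch:
    def test_closed_form_example(self):
        res = de.welch_t_test(dataset([[4.0, 5.0, 6.0]], [[1.0, 2.0, 3.0]]))
        assert res.loc[0, "effect"] == pytest.approx(3.0)
        assert res.loc[0, "t"] == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-3)

    def test_identical_groups_give_t0_p1(self):
        res = de.welch_t_test(dataset([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]]))
        assert res.loc[0, "t"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_swapping_labels_negates_t_keeps_p(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, (4, 6)), rng.normal(1, 1, (4, 5))
        fwd = de.welch_t_test(dataset(a, b))
        rev = de.welch_t_test(dataset(b, a))
        np.testing.assert_allclose(fwd["t"], -rev["t"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_matches_scalar_bruteforce_to_1e10(self):
        rng = np.random.default_rng(4)
        tum, nor = rng.normal(0, 1, (60, 5)), rng.normal(0.4, 2, (60, 7))
        res = de.welch_t_test(dataset(tum, nor))
        for i in range(60):
            t, _, p = welch_t(tum[i], nor[i])
            assert abs(res.loc[i, "t"] - t) < 1e-10
            assert abs(res.loc[i, "p"] - p) < 1e-10

    def test_degenerate_zero_variance_unequal_means_flagged(self):
        res = de.welch_t_test(dataset([[2.0, 2.0, 2.0]], [[1.0, 1.0, 1.0]]))
        assert res.loc[0, "p"] == 0.0
        assert res.loc[0, "flag"] == "degenerate"


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(de.bh_fdr([0.05]), [0.05])

    def test_stepup_arithmetic_example(self):
        np.testing.assert_allclose(
            de.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_equals_textbook_stepup_on_all_permutations(self):
        base = [0.011, 0.28, 0.94, 0.0003, 0.11, 0.049]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(
                de.bh_fdr(list(perm)), bh_stepup(perm), atol=1e-12
            )

    def test_random_sets_up_to_eight(self):
        rng = np.random.default_rng(5)
        for n in range(1, 9):
            for _ in range(20):
                p = rng.random(n)
                np.testing.assert_allclose(de.bh_fdr(p), bh_stepup(p),
                                           atol=1e-12)

    def test_q_dominates_p_and_is_capped(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        q = de.bh_fdr(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.5, 1.2])


class TestSam:
    def test_pooled_standard_error_example(self):
        ds = dataset([[4.0, 5.0, 6.0]], [[1.0, 2.0, 3.0]])
        frame, s0 = de.sam_statistic(ds, s0_quantile=0.0)
        # with a single feature the s0 quantile equals s itself; check the
        # raw pieces against the defining formula instead
        d_ref, s_ref = sam_d([4, 5, 6], [1, 2, 3], s0=0.0)
        assert frame.loc[0, "s"] == pytest.approx(s_ref, abs=1e-10)
        assert s_ref == pytest.approx(0.8165, abs=1e-4)
        assert d_ref == pytest.approx(3.674, abs=1e-3)

    def test_identical_means_give_d0(self):
        ds = dataset([[1.0, 2.0, 3.0]], [[2.0, 1.0, 3.0]])
        frame, _ = de.sam_statistic(ds)
        assert frame.loc[0, "d"] == pytest.approx(0.0)

    def test_d_shrinks_as_s0_grows(self):
        rng = np.random.default_rng(7)
        ds = dataset(rng.normal(1, 1, (20, 5)), rng.normal(0, 1, (20, 5)))
        mags = []
        for q in (0.0, 0.5, 1.0):
            frame, _ = de.sam_statistic(ds, s0_quantile=q)
            mags.append(np.abs(frame["d"]).to_numpy())
        assert np.all(mags[1] <= mags[0] + 1e-12)
        assert np.all(mags[2] <= mags[1] + 1e-12)

    def test_matches_bruteforce_d(self):
        rng = np.random.default_rng(8)
        tum, nor = rng.normal(0, 1, (30, 6)), rng.normal(0, 1, (30, 8))
        frame, s0 = de.sam_statistic(ds := dataset(tum, nor))
        for i in range(30):
            d_ref, _ = sam_d(tum[i], nor[i], s0=s0)
            assert abs(frame.loc[i, "d"] - d_ref) < 1e-10


class TestSamPermutationFdr:
    def test_null_data_has_high_q(self):
        rng = np.random.default_rng(9)
        ds = dataset(rng.normal(0, 1, (150, 8)), rng.normal(0, 1, (150, 8)))
        res = de.sam_permutation_fdr(ds, n_perm=100, seed=1)
        assert np.median(res["q"]) > 0.5

    def test_same_seed_identical(self):
        rng = np.random.default_rng(10)
        ds = dataset(rng.normal(0, 1, (40, 6)), rng.normal(0, 1, (40, 6)))
        a = de.sam_permutation_fdr(ds, n_perm=80, seed=3)
        b = de.sam_permutation_fdr(ds, n_perm=80, seed=3)
        np.testing.assert_array_equal(a["q"], b["q"])

    def test_small_designs_enumerate_all_assignments(self):
        ds = dataset(np.random.default_rng(11).normal(0, 1, (20, 3)),
                     np.random.default_rng(12).normal(0, 1, (20, 3)))
        a = de.sam_permutation_fdr(ds, n_perm=500, seed=1)
        b = de.sam_permutation_fdr(ds, n_perm=500, seed=99)
        # C(6,3)=20 < n_perm: exhaustive, so the seed cannot matter
        np.testing.assert_array_equal(a["q"], b["q"])

    def test_planted_feature_recovered_across_seeds(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            ds, _ = simulate_mirna_dataset(
                n_features=120, n_tumor=15, n_normal=15,
                down_features={"M0010": -2.0}, noise_sd=0.3, seed=1000 + s,
            )
            res = de.sam_permutation_fdr(ds, n_perm=200, seed=s)
            row = res.set_index("feature_id").loc["M0010"]
            hits += (row["q"] < 0.05) and (row["effect"] < 0)
        assert hits >= int(0.95 * n_seeds)


def test_downregulated_helper_applies_both_conditions():
    import pandas as pd

    frame = pd.DataFrame(
        {
            "feature_id": ["a", "b", "c", "d"],
            "effect": [-1.0, -1.0, 1.0, -0.5],
            "q": [0.01, 0.2, 0.01, 0.04],
        }
    )
    assert de.downregulated(frame) == {"a", "d"}
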