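"""Sparse CCA: thresholding, singular-vector limits, oracles, bootstrap VIP."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rvscca import (
    SparseCCA,
    bootstrap_vip,
    calibrate_penalty_to_fraction,
    cv_select_penalty,
    default_penalty_grid,
    scca_fit,
    select_refined_sets,
    soft_threshold,
)
from rvscca.scca import VIPTable
import pandas as pd


class TestSoftThreshold:
    def test_zero_penalty_is_identity(self):
        v = np.array([0.5, -0.2, 0.0, 3.0])
        np.testing.assert_array_equal(soft_threshold(v, 0.0), v)

    def test_printed_example(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([0.5, -0.2, 0.1]), 0.15),
            [0.35, -0.05, 0.0],
        )

    def test_large_penalty_zeroes_everything(self):
        v = np.array([0.5, -0.2, 0.1])
        np.testing.assert_array_equal(soft_threshold(v, 0.5), np.zeros(3))

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
        st.floats(0, 6, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shrinks_toward_zero_without_sign_flips(self, vals, lam):
        v = np.array(vals)
        out = soft_threshold(v, lam)
        assert (np.abs(out) <= np.abs(v) + 1e-12).all()
        assert ((out == 0) | (np.sign(out) == np.sign(v))).all()


def brute_force_scca_objective(K, lambda_u, step=0.1):
    """Grid-search oracle for the penalized criterion a'Kb - lambda*||a||_1.

    Enumerates soft-thresholded unit a-directions on a coarse grid (4x3
    problems only); b is the optimal dense unit response K'a / ||K'a||.
    The grid value lower-bounds the global maximum, which the alternating
    fit must therefore match or beat.
    """
    p = K.shape[0]
    axis = np.arange(-1.0, 1.0 + step, step)
    A = np.stack(np.meshgrid(*[axis] * p, indexing="ij"), axis=-1).reshape(-1, p)
    norms = np.linalg.norm(A, axis=1)
    A = A[norms > 1e-12] / norms[norms > 1e-12, None]
    A = soft_threshold(A, lambda_u)
    norms = np.linalg.norm(A, axis=1)
    A = A[norms > 1e-12] / norms[norms > 1e-12, None]
    B = A @ K  # each row: K'a
    nb = np.linalg.norm(B, axis=1)
    ok = nb > 1e-12
    objectives = nb[ok] - lambda_u * np.abs(A[ok]).sum(axis=1)
    return float(objectives.max(initial=0.0))


class TestSparseCCAFit:
    def test_zero_penalty_recovers_rank_one_factors(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(6)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(4)
        v /= np.linalg.norm(v)
        model = scca_fit(2.7 * np.outer(u, v), lambda_u=0.0)
        assert abs(model.x_weights_ @ u) == pytest.approx(1.0, abs=1e-8)
        assert abs(model.y_weights_ @ v) == pytest.approx(1.0, abs=1e-8)

    def test_zero_penalty_matches_leading_singular_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            K = rng.standard_normal((8, 5))
            model = scca_fit(K, lambda_u=0.0)
            U, s, Vt = np.linalg.svd(K)
            assert abs(model.x_weights_ @ U[:, 0]) > 1 - 1e-8
            assert abs(model.y_weights_ @ Vt[0]) > 1 - 1e-8
            assert model.objective_ == pytest.approx(s[0], rel=1e-8)

    def test_matches_grid_search_oracle_on_small_problems(self):
        rng = np.random.default_rng(2)
        K = rng.standard_normal((4, 3)) * 0.5
        for lam in (0.0, 0.1, 0.25):
            model = scca_fit(K, lambda_u=lam)
            oracle = brute_force_scca_objective(K, lam, step=0.1)
            assert model.penalized_objective_ >= oracle - 0.02

    def test_penalized_objective_nondecreasing_across_iterations(self):
        # each half-step solves its subproblem exactly, so the penalized
        # criterion a'Kb - lam*||a||_1 rises monotonically (a'Kb alone
        # need not)
        rng = np.random.default_rng(3)
        K = rng.standard_normal((10, 6))
        lam = 0.3
        _, _, vt = np.linalg.svd(K, full_matrices=False)
        b = vt[0]
        prev = -np.inf
        for _ in range(50):
            a = soft_threshold(K @ b, lam)
            if np.linalg.norm(a) == 0:
                break
            a /= np.linalg.norm(a)
            b = K.T @ a
            b /= np.linalg.norm(b)
            obj = a @ K @ b - lam * np.abs(a).sum()
            assert obj >= prev - 1e-10
            prev = obj

    def test_full_thresholding_flags_empty_model(self):
        K = np.full((5, 3), 0.1)
        model = scca_fit(K, lambda_u=10.0)
        assert model.empty_
        assert not model.support_.any()
        np.testing.assert_array_equal(model.x_weights_, 0.0)

    def test_support_nonincreasing_in_penalty(self):
        rng = np.random.default_rng(4)
        K = rng.standard_normal((40, 8))
        sizes = [
            scca_fit(K, lambda_u=lam).support_.sum()
            for lam in np.linspace(0.0, np.sqrt((K**2).sum(1)).max(), 30)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_sign_convention_largest_coefficient_positive(self):
        rng = np.random.default_rng(5)
        K = rng.standard_normal((6, 4))
        model = scca_fit(K, lambda_u=0.05)
        assert model.x_weights_[np.argmax(np.abs(model.x_weights_))] > 0

    def test_sklearn_params_round_trip(self):
        model = SparseCCA(lambda_u=0.2, tol=1e-5)
        assert model.get_params()["lambda_u"] == 0.2
        model.set_params(lambda_u=0.4)
        assert model.lambda_u == 0.4


class TestPenaltyCalibration:
    def test_target_one_gives_zero_penalty(self):
        K = np.random.default_rng(6).standard_normal((20, 4))
        assert calibrate_penalty_to_fraction(K, target_fraction=1.0) == 0.0

    def test_hits_ten_percent_on_synthetic_k(self):
        rng = np.random.default_rng(7)
        p = 1000
        sparse_signal = np.where(rng.random(p) < 0.1, rng.standard_normal(p) * 0.3, 0.0)
        K = rng.standard_normal((p, 20)) * 0.05 + np.outer(
            sparse_signal, rng.standard_normal(20) * 0.3
        )
        lam = calibrate_penalty_to_fraction(K, target_fraction=0.10, tol_fraction=0.01)
        frac = scca_fit(K, lambda_u=lam).support_.mean()
        assert 0.09 <= frac <= 0.11

    def test_unreachable_resolution_warns(self):
        K = np.random.default_rng(8).standard_normal((5, 3))
        with pytest.warns(UserWarning, match="resolution"):
            calibrate_penalty_to_fraction(K, target_fraction=0.05, tol_fraction=0.001)


class TestCVSelect:
    def test_single_value_grid_returned(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 3))
        lam, table = cv_select_penalty(X, Y, grid=[0.07], folds=5, seed=0)
        assert lam == 0.07
        assert len(table) == 1

    def test_pure_noise_ties_break_to_smallest_penalty(self):
        # without signal all grid values perform comparably; exact ties
        # (e.g. grid so large every model is empty) resolve to the smallest
        rng = np.random.default_rng(10)
        X = rng.standard_normal((24, 4))
        Y = rng.standard_normal((24, 3))
        lam, table = cv_select_penalty(X, Y, grid=[5.0, 8.0], folds=4, seed=1)
        assert lam == 5.0
        assert (table["cv_correlation_sum"] == 0).all()

    def test_default_grid_structure(self):
        grid = default_penalty_grid()
        assert grid[0] == 0.0
        assert grid[1] == pytest.approx(1e-4)
        assert grid[2] == pytest.approx(6e-4)
        assert grid[-1] <= 0.1 + 1e-12

    def test_diffuse_signal_keeps_nearly_all_variables(self):
        # prediction-optimal penalty under diffuse signal barely selects:
        # the chosen penalty leaves the large majority of columns active
        rng = np.random.default_rng(11)
        n, p, q = 60, 40, 4
        latent = rng.standard_normal(n)
        X = rng.standard_normal((n, p)) + np.outer(latent, rng.choice([-1, 1], p) * 0.5)
        Y = rng.standard_normal((n, q)) + np.outer(latent, rng.choice([-1, 1], q) * 0.9)
        lam, _ = cv_select_penalty(
            X, Y, grid=[0.0, 0.02, 0.05, 0.1, 0.3], folds=5, seed=2
        )
        from rvscca import weighted_cross_correlation

        K = weighted_cross_correlation(X, Y)
        frac = scca_fit(K, lambda_u=lam).support_.mean()
        assert frac >= 0.9


class TestBootstrapVIP:
    def test_single_replicate_gives_binary_vips(self, unlinked_cohort):
        from rvscca import build_weighted_cohort

        g, pheno, covar, truth = unlinked_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coh = build_weighted_cohort(
                g, pheno, covar,
                {"CN": 0.875, "MCI": 0.05, "AD": 0.075},
                n_coords=3, rate_method="ols",
            )
        vip = bootstrap_vip(
            coh.X, coh.Y, coh.weights.weights, coh.groups,
            lambda_u=0.5, n_bootstrap=1, seed=0,
        )
        assert set(np.unique(vip.vip)) <= {0.0, 1.0}

    def test_vip_bounds_and_vep_complement(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((40, 10))
        Y = rng.standard_normal((40, 3))
        groups = np.repeat(["CN", "MCI"], 20)
        vip = bootstrap_vip(X, Y, None, groups, lambda_u=0.3, n_bootstrap=25, seed=3)
        assert ((vip.vip >= 0) & (vip.vip <= 1)).all()
        np.testing.assert_allclose(vip.vip + vip.vep, 1.0)

    def test_all_null_vips_are_exchangeable_without_standouts(self):
        # with no signal, selection at the calibrated penalty hits each SNP
        # roughly at random: VIPs stay in a band around the selection
        # fraction (bootstrap duplication shrinks the effective sample and
        # inflates resampled correlations, so the band sits somewhat above
        # the full-data fraction) and no SNP approaches certain selection
        rng = np.random.default_rng(13)
        n, p, q = 80, 40, 4
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        groups = np.repeat(["CN", "MCI"], n // 2)
        from rvscca import weighted_cross_correlation

        f = 0.25
        lam = calibrate_penalty_to_fraction(
            weighted_cross_correlation(X, Y), target_fraction=f,
        )
        vip = bootstrap_vip(X, Y, None, groups, lambda_u=lam, n_bootstrap=150, seed=4)
        assert 0.5 * f <= vip.vip.mean() <= 3.0 * f
        assert vip.vip.std() < 0.15
        assert vip.vip.max() < 0.9


class TestRefinedSets:
    def make_table(self, vips):
        return VIPTable(
            table=pd.DataFrame(
                {
                    "snp_id": [f"rs{i}" for i in range(len(vips))],
                    "vip": vips,
                    "vep": 1 - np.asarray(vips),
                    "n_selected": np.asarray(vips) * 10,
                }
            ),
            n_bootstrap=10,
            lambda_u=0.1,
        )

    def test_thresholds_are_inclusive(self):
        sets = select_refined_sets(self.make_table([0.95, 0.6, 0.1, 0.5, 0.9]))
        assert sets.priority == ["rs0", "rs1", "rs3", "rs4"]
        assert sets.top_hit == ["rs0", "rs4"]

    def test_top_hits_are_subset_of_priority(self):
        rng = np.random.default_rng(14)
        sets = select_refined_sets(self.make_table(rng.random(30)))
        assert set(sets.top_hit) <= set(sets.priority)

    def test_empty_result_warns_but_returns(self):
        with pytest.warns(UserWarning, match="empty"):
            sets = select_refined_sets(self.make_table([0.1, 0.2]))
        assert sets.priority == [] and sets.top_hit == []

    def test_invalid_cuts_rejected(self):
        with pytest.raises(ValueError):
            select_refined_sets(self.make_table([0.5]), priority_cut=0.9, top_cut=0.5)
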