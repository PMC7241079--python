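"""Solver, projection and similarity-matrix checks against oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import smccnet as sm
from smccnet.smcca import _standardize_cols
from oracles import grid_search_smcca, project_oracle


def _standardize(M):
    return _standardize_cols(np.asarray(M, dtype=float))


# --------------------------------------------------------------------------
# correlation range report
# --------------------------------------------------------------------------
class TestCorrelationRange:
    def test_self_block_max_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        rep = sm.correlation_range_report(X, X, rng.normal(size=30))
        assert rep["omics_omics"][1] == pytest.approx(1.0)

    def test_orthogonal_phenotype_near_zero(self):
        rng = np.random.default_rng(1)
        n = 400
        X = rng.normal(size=(n, 5))
        y = rng.normal(size=n)
        rep = sm.correlation_range_report(X, rng.normal(size=(n, 5)), y)
        lo1, hi1 = rep["omics1_phenotype"]
        assert abs(lo1) < 2 / np.sqrt(n) + 0.05 and abs(hi1) < 2 / np.sqrt(n) + 0.05

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        n = 25
        X1 = rng.normal(size=(n, 5))
        X2 = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        rep = sm.correlation_range_report(X1, X2, y)
        cross = [
            np.corrcoef(X1[:, a], X2[:, b])[0, 1]
            for a in range(5) for b in range(3)
        ]
        assert rep["omics_omics"][0] == pytest.approx(min(cross), abs=1e-12)
        assert rep["omics_omics"][1] == pytest.approx(max(cross), abs=1e-12)
        r1 = [np.corrcoef(X1[:, a], y)[0, 1] for a in range(5)]
        assert rep["omics1_phenotype"] == pytest.approx((min(r1), max(r1)), abs=1e-12)

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError):
            sm.correlation_range_report(
                np.ones((2, 2)), np.ones((2, 2)), np.ones(2)
            )


# --------------------------------------------------------------------------
# the L1/L2 projection
# --------------------------------------------------------------------------
class TestProjectL1L2:
    def test_inactive_constraint_returns_unit_vector(self):
        v = np.array([3.0, 4.0])
        w = sm.project_l1_l2(v, c=np.sqrt(2))
        np.testing.assert_allclose(w, v / 5.0, atol=1e-12)

    def test_c_one_gives_one_hot_lowest_index_tie(self):
        w = sm.project_l1_l2(np.array([2.0, -2.0, 1.0]), c=1.0)
        np.testing.assert_array_equal(w, [1.0, 0.0, 0.0])

    def test_zero_vector_flagged(self):
        with pytest.warns(RuntimeWarning):
            w = sm.project_l1_l2(np.zeros(4), c=1.5)
        assert not np.any(w)

    def test_c_below_one_errors(self):
        with pytest.raises(ValueError):
            sm.project_l1_l2(np.ones(3), c=0.5)

    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12
        ),
        st.floats(1.0, 3.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_projection_feasible_and_dominates_one_hot(self, vals, c):
        """Property: the projection always satisfies both norm constraints
        and its objective is at least that of the best feasible one-hot
        vector (which is feasible for every c >= 1)."""
        v = np.array(vals)
        assume(np.any(v))
        w = sm.project_l1_l2(v, c)
        assert np.linalg.norm(w) <= 1 + 1e-8
        assert np.abs(w).sum() <= c + 1e-8
        assert w @ v >= np.max(np.abs(v)) - 1e-8

    def test_constraints_satisfied_and_beats_oracle(self):
        """On 1000 random 10-vectors at c=1.8 the projection's objective
        matches an independent dense-scan oracle to 1e-4 and respects both
        norm constraints."""
        rng = np.random.default_rng(42)
        c = 1.8
        worst = 0.0
        for _ in range(1000):
            v = rng.normal(size=10)
            w = sm.project_l1_l2(v, c)
            assert np.linalg.norm(w) <= 1 + 1e-8
            assert np.abs(w).sum() <= c + 1e-8
            w_oracle = project_oracle(v, c, n_grid=4000)
            worst = max(worst, float(w_oracle @ v) - float(w @ v))
        assert worst < 1e-4


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------
class TestWeightedObjective:
    def test_one_hot_reduces_to_pairwise_correlations(self):
        rng = np.random.default_rng(3)
        n = 40
        X1 = _standardize(rng.normal(size=(n, 4)))
        X2 = _standardize(rng.normal(size=(n, 3)))
        y = _standardize(rng.normal(size=(n, 1)))[:, 0]
        i, j, s = 2, 1, 7.0
        w1 = np.eye(4)[i]
        w2 = np.eye(3)[j]
        J = sm.weighted_objective(w1, w2, X1, X2, y, sm.ScalingScheme(s))
        r12 = np.corrcoef(X1[:, i], X2[:, j])[0, 1]
        r1y = np.corrcoef(X1[:, i], y)[0, 1]
        r2y = np.corrcoef(X2[:, j], y)[0, 1]
        assert J == pytest.approx(r12 + s * (r1y + r2y), abs=1e-10)

    def test_hand_dataset(self):
        X1 = _standardize([[1, 2], [2, 1], [3, 5], [4, 3], [5, 4], [6, 6]])
        X2 = _standardize([[2, 1], [1, 3], [4, 2], [3, 6], [6, 4], [5, 5]])
        y = _standardize([[1], [3], [2], [5], [4], [6]])[:, 0]
        w1 = np.array([0.6, 0.8])
        w2 = np.array([-0.8, 0.6])
        s = 2.0
        n = 6
        S12 = X1.T @ X2 / (n - 1)
        expected = w1 @ S12 @ w2 + s * (w1 @ X1.T @ y + w2 @ X2.T @ y) / (n - 1)
        J = sm.weighted_objective(w1, w2, X1, X2, y, sm.ScalingScheme(s))
        assert J == pytest.approx(expected, abs=1e-12)

    def test_misaligned_dimensions_error(self):
        with pytest.raises(ValueError):
            sm.weighted_objective(
                np.ones(3), np.ones(2), np.ones((5, 2)), np.ones((5, 2)),
                np.ones(5), sm.ScalingScheme(1),
            )


# --------------------------------------------------------------------------
# the solver
# --------------------------------------------------------------------------
class TestFitSmcca:
    def test_univariate_blocks_sign_enumeration(self):
        """p1 = p2 = 1: the optimum is one of the four sign combinations."""
        rng = np.random.default_rng(5)
        n = 30
        X1 = _standardize(rng.normal(size=(n, 1)))
        X2 = _standardize(rng.normal(size=(n, 1)))
        y = _standardize(rng.normal(size=(n, 1)))[:, 0]
        scheme = sm.ScalingScheme(3.0)
        pen = sm.PenaltyPair(1.0, 1.0)
        fit = sm.fit_smcca(X1, X2, y, scheme, pen)
        best = max(
            sm.weighted_objective(
                np.array([a]), np.array([b]), X1, X2, y, scheme
            )
            for a, b in itertools.product([1.0, -1.0], repeat=2)
        )
        assert fit.objective_value == pytest.approx(best, abs=1e-8)

    def test_svd_closed_form_unpenalized_whitened(self):
        """s=0 with no active L1 constraint on whitened blocks: the optimum
        is the leading singular pair of S12 and J its largest singular value."""
        rng = np.random.default_rng(6)
        n, p1, p2 = 200, 5, 4
        X1 = rng.normal(size=(n, p1))
        X2 = rng.normal(size=(n, p2))
        # whiten within blocks so the CCA reduces to an SVD of the cross-cov
        for X in (X1, X2):
            X -= X.mean(axis=0)
        X1 = X1 @ np.linalg.inv(np.linalg.cholesky(np.cov(X1.T, ddof=1)).T)
        X2 = X2 @ np.linalg.inv(np.linalg.cholesky(np.cov(X2.T, ddof=1)).T)
        y = rng.normal(size=n)
        S12 = X1.T @ X2 / (n - 1)
        sigma_max = np.linalg.svd(S12, compute_uv=False)[0]
        fit = sm.fit_smcca(
            X1, X2, y, sm.ScalingScheme(0.0), sm.PenaltyPair(1.0, 1.0), tol=1e-10
        )
        assert fit.objective_value == pytest.approx(sigma_max, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        """p1 = p2 = 3: the fitted objective agrees with a brute-force
        maximization over a 0.05-step grid of unit-norm feasible pairs."""
        rng = np.random.default_rng(20)
        n = 20
        X1 = _standardize(rng.normal(size=(n, 3)))
        X2 = _standardize(rng.normal(size=(n, 3)))
        y = _standardize(rng.normal(size=(n, 1)))[:, 0]
        s, l = 1.0, 0.9
        c = max(1.0, l * np.sqrt(3))
        fit = sm.fit_smcca(
            X1, X2, y, sm.ScalingScheme(s), sm.PenaltyPair(l, l), tol=1e-10
        )
        S12 = X1.T @ X2 / (n - 1)
        s1y = X1.T @ y / (n - 1)
        s2y = X2.T @ y / (n - 1)
        best = grid_search_smcca(S12, s1y, s2y, s, c, c, step=0.05)
        assert abs(fit.objective_value - best) < 1e-3
        assert fit.objective_value >= best - 1e-9

    def test_scale_invariance_in_phenotype(self, standardized_small):
        """Multiplying y by a positive constant before standardization
        leaves the fitted weights unchanged."""
        _, X1, X2, y = standardized_small
        scheme = sm.ScalingScheme(5.0)
        pen = sm.PenaltyPair(0.35, 0.35)
        f1 = sm.fit_smcca(X1.to_numpy(), X2.to_numpy(), y.to_numpy(), scheme, pen)
        y2 = sm.standardize_phenotype(y * 37.0)
        f2 = sm.fit_smcca(X1.to_numpy(), X2.to_numpy(), y2.to_numpy(), scheme, pen)
        np.testing.assert_allclose(f1.w1, f2.w1, atol=1e-8)
        np.testing.assert_allclose(f1.w2, f2.w2, atol=1e-8)

    def test_phenotype_share_increases_with_s(self, standardized_small):
        _, X1, X2, y = standardized_small
        X1a, X2a, ya = X1.to_numpy(), X2.to_numpy(), y.to_numpy()
        pen = sm.PenaltyPair(0.35, 0.35)
        n = X1a.shape[0]
        shares = []
        for s in (1.0, 5.0, 10.0, 20.0):
            fit = sm.fit_smcca(X1a, X2a, ya, sm.ScalingScheme(s), pen)
            pheno = s * (
                (X1a @ fit.w1) @ ya + (X2a @ fit.w2) @ ya
            ) / (n - 1)
            shares.append(pheno / fit.objective_value)
        assert all(b >= a - 1e-9 for a, b in zip(shares, shares[1:]))

    def test_sparsity_monotone_in_penalty(self, standardized_small):
        _, X1, X2, y = standardized_small
        X1a, X2a, ya = X1.to_numpy(), X2.to_numpy(), y.to_numpy()
        sizes = []
        for l in (0.55, 0.45, 0.35, 0.25, 0.15, 0.05):
            fit = sm.fit_smcca(
                X1a, X2a, ya, sm.ScalingScheme(10.0), sm.PenaltyPair(l, l)
            )
            sizes.append(fit.support_1().size + fit.support_2().size)
        assert sizes == sorted(sizes, reverse=True)

    def test_norm_constraints_hold(self, standardized_small):
        _, X1, X2, y = standardized_small
        l1, l2 = 0.25, 0.45
        fit = sm.fit_smcca(
            X1.to_numpy(), X2.to_numpy(), y.to_numpy(),
            sm.ScalingScheme(10.0), sm.PenaltyPair(l1, l2),
        )
        p1, p2 = X1.shape[1], X2.shape[1]
        assert np.linalg.norm(fit.w1) <= 1 + 1e-8
        assert np.linalg.norm(fit.w2) <= 1 + 1e-8
        assert np.abs(fit.w1).sum() <= max(1, l1 * np.sqrt(p1)) + 1e-8
        assert np.abs(fit.w2).sum() <= max(1, l2 * np.sqrt(p2)) + 1e-8


# --------------------------------------------------------------------------
# cross-validated penalty selection
# --------------------------------------------------------------------------
class TestCvSelect:
    def test_full_grid_is_36_pairs(self, standardized_small):
        _, X1, X2, y = standardized_small
        cv = sm.cv_select_penalties(
            X1.to_numpy()[:100], X2.to_numpy()[:100], y.to_numpy()[:100],
            sm.ScalingScheme(10.0), seed=1,
        )
        assert len(cv.grid) == 36
        assert cv.mean_errors.shape == (36,)
        assert cv.mean_errors.min() == pytest.approx(
            cv.mean_errors[cv.grid.index(cv.chosen)]
        )

    def test_low_noise_chosen_support_covers_signal(self):
        """With clearly recoverable planted signal (low but nonzero noise,
        which keeps the planted features from being exactly collinear) the
        CV-chosen pair keeps every planted feature in the fitted support."""
        config = sm.SyntheticConfig(
            n_subjects=150, p_proteins=15, p_metabolites=15,
            n_signal_1=4, n_signal_2=4, latent_loading_range=(1.0, 1.0),
            noise_sd=0.2, n_covariates=0, covariate_effect_sd=0.0,
            missing_rate=0.0, n_run_days=1, run_day_scale_sd=0.0, seed=13,
        )
        ds = sm.generate_multiomics(config)
        X1 = _standardize(np.log(ds.proteins.values))
        X2 = _standardize(np.log(ds.metabolites.values))
        y = _standardize(ds.phenotype.to_numpy()[:, None])[:, 0]
        scheme = sm.ScalingScheme(10.0)
        cv = sm.cv_select_penalties(X1, X2, y, scheme, seed=2)
        fit = sm.fit_smcca(X1, X2, y, scheme, cv.chosen)
        assert set(ds.signal_idx_1) <= set(fit.support_1().tolist())
        assert set(ds.signal_idx_2) <= set(fit.support_2().tolist())

    def test_single_pair_grid_returned(self, standardized_small):
        _, X1, X2, y = standardized_small
        cv = sm.cv_select_penalties(
            X1.to_numpy()[:60], X2.to_numpy()[:60], y.to_numpy()[:60],
            sm.ScalingScheme(5.0), grid_values=(0.3,), seed=0,
        )
        assert cv.chosen == sm.PenaltyPair(0.3, 0.3)

    def test_fold_sizes_balanced(self, standardized_small):
        _, X1, X2, y = standardized_small
        cv = sm.cv_select_penalties(
            X1.to_numpy()[:83], X2.to_numpy()[:83], y.to_numpy()[:83],
            sm.ScalingScheme(5.0), grid_values=(0.3,), seed=3,
        )
        sizes = np.bincount(cv.fold_assignments)
        assert sizes.max() - sizes.min() <= 1


# --------------------------------------------------------------------------
# similarity matrix
# --------------------------------------------------------------------------
class TestBuildSimilarity:
    def test_single_full_fit_equals_outer_product(self, standardized_small):
        _, X1, X2, y = standardized_small
        scheme = sm.ScalingScheme(10.0)
        pen = sm.PenaltyPair(0.35, 0.35)
        sim = sm.build_similarity(
            X1.to_numpy(), X2.to_numpy(), y.to_numpy(), scheme, pen,
            sm.SubsampleScheme(1.0, 1.0, 1, seed=0),
        )
        fit = sm.fit_smcca(X1.to_numpy(), X2.to_numpy(), y.to_numpy(), scheme, pen)
        w = np.concatenate([fit.w1, fit.w2])
        expected = np.abs(np.outer(w, w))
        np.fill_diagonal(expected, 0.0)
        expected /= expected.max()
        np.testing.assert_allclose(sim.values, expected, atol=1e-10)

    def test_contract_symmetric_bounded_zero_diagonal(self, standardized_small):
        _, X1, X2, y = standardized_small
        sim = sm.build_similarity(
            X1.to_numpy(), X2.to_numpy(), y.to_numpy(),
            sm.ScalingScheme(10.0), sm.PenaltyPair(0.35, 0.35),
            sm.SubsampleScheme(0.7, 0.7, 10, seed=4),
        )
        V = sim.values
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert V.min() >= 0 and V.max() <= 1
        assert np.all(np.diag(V) == 0)
        assert np.all(np.abs(sim.signs) == 1)

    def test_stability_across_seeds(self, standardized_recovery):
        """Two independent 200-replicate consensus matrices on planted-signal
        data differ by < 10% in relative Frobenius distance."""
        _, X1, X2, y = standardized_recovery
        mats = []
        for seed in (0, 1):
            sim = sm.build_similarity(
                X1.to_numpy(), X2.to_numpy(), y.to_numpy(),
                sm.ScalingScheme(10.0), sm.PenaltyPair(0.35, 0.35),
                sm.SubsampleScheme(0.7, 0.7, 200, seed=seed),
            )
            mats.append(sim.values)
        dist = np.linalg.norm(mats[0] - mats[1])
        assert dist < 0.1 * np.linalg.norm(mats[0])

    def test_subsample_too_small_errors(self, standardized_small):
        _, X1, X2, y = standardized_small
        with pytest.raises(ValueError):
            sm.build_similarity(
                X1.to_numpy()[:, :2], X2.to_numpy(), y.to_numpy(),
                sm.ScalingScheme(1.0), sm.PenaltyPair(0.5, 0.5),
                sm.SubsampleScheme(0.4, 0.7, 5, seed=0),
            )
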