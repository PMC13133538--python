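"""EFA engine: parallel analysis, principal-axis factoring, promax,
variance accounting, salience and weighted scores."""

import numpy as np
import pandas as pd
import pytest

from hyperdim.datatypes import FactorSolution, ItemResponseMatrix
from hyperdim.efa import (
    PrincipalAxisFactorAnalysis,
    match_factors,
    parallel_analysis,
    principal_axis_factor,
    promax_rotate,
    salience_map,
    tucker_congruence,
    variance_explained,
    weighted_factor_scores,
)


class TestParallelAnalysis:
    def test_identity_matrix_suggests_zero(self):
        pa = parallel_analysis(np.eye(20), n_obs=1000, seed=1)
        assert np.allclose(pa.observed_eigenvalues, 1.0)
        assert pa.suggested_n_factors == 0

    def test_pure_noise_suggests_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1000, 20))
        pa = parallel_analysis(np.corrcoef(X.T), n_obs=1000, seed=2)
        assert pa.suggested_n_factors == 0

    def test_three_factor_data_suggests_three(self):
        rng = np.random.default_rng(1)
        lam = np.zeros((15, 3))
        for j in range(3):
            lam[j * 5 : (j + 1) * 5, j] = 0.7
        hits = 0
        for rep in range(10):
            f = rng.standard_normal((1000, 3))
            X = f @ lam.T + rng.standard_normal((1000, 15)) * np.sqrt(1 - 0.49)
            pa = parallel_analysis(np.corrcoef(X.T), n_obs=1000, seed=rep)
            hits += pa.suggested_n_factors == 3
        assert hits >= 9

    def test_seeded_determinism(self):
        R = np.eye(10)
        a = parallel_analysis(R, 500, seed=42)
        b = parallel_analysis(R, 500, seed=42)
        assert np.array_equal(
            a.simulated_eigenvalue_quantiles, b.simulated_eigenvalue_quantiles
        )

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="n_reps"):
            parallel_analysis(np.eye(5), 100, n_reps=10)


class TestPrincipalAxis:
    def test_exact_one_factor_recovery(self):
        lam = np.full(10, 0.8)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        L, psi, eig, conv, heywood = principal_axis_factor(R, 1)
        assert conv and not heywood
        assert np.abs(np.abs(L[:, 0]) - 0.8).max() < 1e-4
        assert np.abs(psi - 0.36).max() < 1e-4

    def test_rank_two_reconstruction(self):
        rng = np.random.default_rng(3)
        lam = rng.uniform(0.25, 0.6, size=(12, 2))  # communalities stay < 1
        R = lam @ lam.T
        np.fill_diagonal(R, 1.0)
        L, psi, *_ = principal_axis_factor(R, 2)
        Rhat = L @ L.T + np.diag(psi)
        off = ~np.eye(12, dtype=bool)
        assert np.abs(Rhat - R)[off].max() < 1e-4

    def test_overfactored_model_clips_heywood(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((30, 6))
        R = np.corrcoef(A)
        L, psi, *_rest = principal_axis_factor(R, 5)
        h2 = (L**2).sum(axis=1)
        assert (h2 <= 1.0 + 1e-8).all()

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            principal_axis_factor(np.eye(5), 5)


class TestPromax:
    def test_perfect_simple_structure_is_fixed_point(self):
        L = np.zeros((9, 3))
        L[:3, 0], L[3:6, 1], L[6:, 2] = 0.8, 0.7, 0.6
        sol = promax_rotate(L, n_obs=100)
        _, cong = match_factors(sol.pattern.to_numpy(), L)
        assert (cong > 1 - 1e-9).all()
        assert np.abs(sol.phi.to_numpy() - np.eye(3)).max() < 1e-9

    def test_oblique_two_factor_phi_recovery(self):
        P = np.zeros((10, 2))
        P[:5, 0] = P[5:, 1] = 0.7
        phi_true = np.array([[1.0, 0.5], [0.5, 1.0]])
        R = P @ phi_true @ P.T
        np.fill_diagonal(R, 1.0)
        L, psi, eig, *_ = principal_axis_factor(R, 2)
        sol = promax_rotate(L, uniquenesses=psi, eigenvalues=eig, n_obs=5000)
        assert sol.phi.iloc[0, 1] == pytest.approx(0.5, abs=0.07)

    def test_low_power_stays_near_varimax(self):
        rng = np.random.default_rng(8)
        L = np.zeros((12, 2))
        L[:6, 0], L[6:, 1] = 0.7, 0.6
        L += rng.normal(0, 0.05, L.shape)
        m1 = promax_rotate(L, power=1, n_obs=100)
        m4 = promax_rotate(L, power=4, n_obs=100)
        # power 1 produces a milder obliqueness than power 4
        assert abs(m1.phi.iloc[0, 1]) <= abs(m4.phi.iloc[0, 1]) + 1e-8

    def test_fit_invariance_under_rotation(self):
        rng = np.random.default_rng(13)
        lam = rng.uniform(0.3, 0.8, size=(14, 3))
        L, psi, eig, *_ = principal_axis_factor(
            np.corrcoef(rng.standard_normal((200, 14)).T), 3
        )
        sol = promax_rotate(L, uniquenesses=psi, eigenvalues=eig, n_obs=200)
        before = L @ L.T
        pat, phi = sol.pattern.to_numpy(), sol.phi.to_numpy()
        after = pat @ phi @ pat.T
        assert np.abs(before - after).max() < 1e-8

    def test_sign_convention(self):
        L = np.zeros((6, 2))
        L[:3, 0], L[3:, 1] = -0.8, 0.7
        sol = promax_rotate(L, n_obs=50)
        top = sol.pattern.to_numpy()[
            np.argmax(np.abs(sol.pattern.to_numpy()), axis=0),
            np.arange(2),
        ]
        assert (top > 0).all()


class TestVarianceExplained:
    def test_one_factor_closed_form(self):
        lam = np.full(10, 0.8)
        sol = FactorSolution(
            pattern=pd.DataFrame(lam[:, None], columns=["F1"]),
            phi=pd.DataFrame([[1.0]], index=["F1"], columns=["F1"]),
            uniquenesses=pd.Series(np.full(10, 0.36)),
            eigenvalues=np.array([6.4]),
            rotation="none",
            n_obs=100,
        )
        ve = variance_explained(sol)
        assert ve["proportion"].iloc[0] == pytest.approx(0.64)
        assert ve["proportion_communality"].iloc[0] == pytest.approx(0.64)

    def test_orthogonal_equals_pattern_ss(self):
        rng = np.random.default_rng(2)
        pat = rng.uniform(-0.7, 0.7, size=(8, 2))
        sol = FactorSolution(
            pattern=pd.DataFrame(pat, columns=["F1", "F2"]),
            phi=pd.DataFrame(np.eye(2), index=["F1", "F2"], columns=["F1", "F2"]),
            uniquenesses=pd.Series(np.clip(1 - (pat**2).sum(1), 0, 1)),
            eigenvalues=np.array([2.0, 1.0]),
            rotation="varimax",
            n_obs=100,
        )
        ve = variance_explained(sol)
        assert np.allclose(ve["proportion"], (pat**2).sum(axis=0) / 8)

    def test_cumulative_nondecreasing_and_bounded(self, preset_solution):
        ve = variance_explained(preset_solution)
        assert (np.diff(ve["cumulative"]) >= -1e-12).all()
        assert ve["cumulative_communality"].iloc[-1] <= 1.0 + 1e-8


class TestSalienceAndScores:
    def test_salience_map_reproducible_by_filtering(self, preset_solution):
        sm = salience_map(preset_solution, threshold=0.32)
        for fac in preset_solution.factor_names:
            expect = preset_solution.pattern[fac][
                preset_solution.pattern[fac].abs() >= 0.32
            ]
            assert dict(sm[fac]) == expect.to_dict()

    def test_one_hot_loadings_select_items(self):
        df = pd.DataFrame(
            {"a": [1.0, 2, 3], "b": [3.0, 1, 2], "c": [2.0, 2, 2]}
        )
        data = ItemResponseMatrix(df, pd.Series({"a": 5, "b": 5, "c": 5}))
        pat = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]],
            index=["a", "b", "c"],
            columns=["F1", "F2"],
        )
        sol = FactorSolution(
            pattern=pat,
            phi=pd.DataFrame(np.eye(2), index=["F1", "F2"], columns=["F1", "F2"]),
            uniquenesses=pd.Series([0.0, 0.0, 1.0], index=["a", "b", "c"]),
            eigenvalues=np.array([1.0, 1.0]),
            rotation="none",
            n_obs=3,
        )
        scores = weighted_factor_scores(data, sol)
        assert np.array_equal(scores["F1"].to_numpy(), df["a"].to_numpy())
        assert np.array_equal(scores["F2"].to_numpy(), df["b"].to_numpy())

    def test_matches_hand_matrix_product(self):
        df = pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1], "c": [1.0, 1]})
        data = ItemResponseMatrix(df, pd.Series({"a": 4, "b": 4, "c": 4}))
        pat = pd.DataFrame(
            [[0.5, 0.1], [0.2, 0.6], [0.1, 0.2]],
            index=["a", "b", "c"],
            columns=["F1", "F2"],
        )
        sol = FactorSolution(
            pattern=pat,
            phi=pd.DataFrame(np.eye(2), index=["F1", "F2"], columns=["F1", "F2"]),
            uniquenesses=pd.Series([0.5, 0.5, 0.5], index=["a", "b", "c"]),
            eigenvalues=np.array([1.0, 0.5]),
            rotation="none",
            n_obs=2,
        )
        scores = weighted_factor_scores(data, sol)
        # person 0: F1 = 1*0.5 + 2*0.2 + 1*0.1 = 1.0; F2 = 0.1+1.2+0.2 = 1.5
        assert scores.iloc[0].to_numpy() == pytest.approx([1.0, 1.5])

    def test_missing_salient_item_propagates(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 2.0]})
        data = ItemResponseMatrix(df, pd.Series({"a": 4, "b": 4}))
        pat = pd.DataFrame(
            [[0.8, 0.0], [0.0, 0.8]], index=["a", "b"], columns=["F1", "F2"]
        )
        sol = FactorSolution(
            pattern=pat,
            phi=pd.DataFrame(np.eye(2), index=["F1", "F2"], columns=["F1", "F2"]),
            uniquenesses=pd.Series([0.36, 0.36], index=["a", "b"]),
            eigenvalues=np.array([1.0, 1.0]),
            rotation="none",
            n_obs=2,
        )
        scores = weighted_factor_scores(data, sol)
        assert np.isnan(scores.loc[1, "F1"])
        assert not np.isnan(scores.loc[1, "F2"])


class TestEndToEndRecovery:
    def test_preset_tucker_congruence(self, preset_solution, preset_cfg):
        _, cong = match_factors(
            preset_solution.pattern.to_numpy(),
            preset_cfg.loading_matrix.to_numpy(),
        )
        assert (cong >= 0.95).all()

    def test_tucker_congruence_of_identical_matrices(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((10, 3))
        C = tucker_congruence(A, A)
        assert np.allclose(np.diag(C), 1.0)
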