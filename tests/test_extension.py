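"""Factor extension: duplicate-item identity, linearity, selection rule,
indicator scoring and validity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hyperdim.datatypes import FactorSolution, ItemResponseMatrix
from hyperdim.efa import PrincipalAxisFactorAnalysis
from hyperdim.extension import (
    ExtensionLoadings,
    extend_loadings,
    score_indicators,
    select_indicators,
    validate_indicators,
)


def _random_solution(rng, p=12, k=3):
    """A correlated-factor solution with its implied item correlations."""
    lam = np.zeros((p, k))
    per = p // k
    for f in range(k):
        lam[f * per : (f + 1) * per, f] = rng.uniform(0.5, 0.8, per)
    A = rng.uniform(-0.3, 0.5, (k, k))
    phi = A @ A.T + k * np.eye(k)
    d = np.sqrt(np.diag(phi))
    phi = phi / np.outer(d, d)
    R = lam @ phi @ lam.T
    np.fill_diagonal(R, 1.0)
    items = [f"i{j}" for j in range(p)]
    names = [f"F{f + 1}" for f in range(k)]
    sol = FactorSolution(
        pattern=pd.DataFrame(lam, index=items, columns=names),
        phi=pd.DataFrame(phi, index=names, columns=names),
        uniquenesses=pd.Series(
            np.clip(1 - np.einsum("if,fg,ig->i", lam, phi, lam), 0, 1),
            index=items,
        ),
        eigenvalues=np.array([]),
        rotation="promax",
        n_obs=500,
    )
    return sol, pd.DataFrame(R, index=items, columns=items)


class TestExtendLoadings:
    @pytest.mark.parametrize("k", [2, 7])
    def test_duplicate_item_identity(self, k):
        """An external item identical to an analyzed item reproduces that
        item's pattern row for any positive-definite Phi."""
        rng = np.random.default_rng(k)
        sol, R = _random_solution(rng, p=2 * k + 4, k=k)
        for j in [0, 3]:
            R_eo = R.iloc[[j]].copy()
            R_eo.index = ["dup"]
            ext = extend_loadings(R, sol, R_eo)
            expect = sol.pattern.iloc[j].to_numpy()
            assert np.abs(ext.pattern.loc["dup"].to_numpy() - expect).max() < 1e-6

    def test_uncorrelated_external_item_gets_zero_row(self):
        rng = np.random.default_rng(1)
        sol, R = _random_solution(rng)
        R_eo = pd.DataFrame(
            np.zeros((1, R.shape[0])), index=["null"], columns=R.columns
        )
        ext = extend_loadings(R, sol, R_eo)
        assert np.abs(ext.pattern.to_numpy()).max() < 1e-12

    def test_linearity_in_cross_correlations(self):
        rng = np.random.default_rng(2)
        sol, R = _random_solution(rng)
        a = rng.uniform(-0.3, 0.3, R.shape[0])
        b = rng.uniform(-0.3, 0.3, R.shape[0])
        R_eo = pd.DataFrame(
            [a, b, (a + b) / 2], index=["x", "y", "avg"], columns=R.columns
        )
        ext = extend_loadings(R, sol, R_eo)
        mean_rows = (ext.pattern.loc["x"] + ext.pattern.loc["y"]) / 2
        assert np.abs(ext.pattern.loc["avg"] - mean_rows).max() < 1e-12

    def test_planted_external_loading_recovered(self):
        """External variable built as 0.7 x factor 2 + noise recovers a
        (0, 0.7, 0) extension row from sampled data (orthogonal factors)."""
        rng = np.random.default_rng(42)
        k, per, lam0, n = 3, 12, 0.9, 5000
        p = k * per
        lam = np.zeros((p, k))
        for f in range(k):
            lam[f * per : (f + 1) * per, f] = lam0
        f = rng.standard_normal((n, k))
        X = f @ lam.T + rng.standard_normal((n, p)) * np.sqrt(1 - lam0**2)
        e = 0.7 * f[:, 1] + rng.standard_normal(n) * np.sqrt(1 - 0.49)
        cols = [f"i{j}" for j in range(p)]
        R_oo = pd.DataFrame(np.corrcoef(X.T), index=cols, columns=cols)
        model = PrincipalAxisFactorAnalysis(n_factors=k, corr="precomputed").fit(
            R_oo, n_obs=n
        )
        sol = model.solution_
        r_eo = np.array([np.corrcoef(e, X[:, j])[0, 1] for j in range(p)])
        R_eo = pd.DataFrame(r_eo[None, :], index=["ext"], columns=cols)
        ext = extend_loadings(R_oo, sol, R_eo)
        row = ext.pattern.loc["ext"].abs().to_numpy()
        primary = row.max()
        assert abs(primary - 0.7) < 0.05
        assert np.sort(row)[:-1].max() < 0.1

    def test_misaligned_labels_rejected(self):
        rng = np.random.default_rng(3)
        sol, R = _random_solution(rng)
        R_eo = pd.DataFrame(
            np.zeros((1, R.shape[0])), index=["x"],
            columns=list(R.columns[::-1]),
        )
        with pytest.raises(ValueError, match="align"):
            extend_loadings(R, sol, R_eo)


class TestSelection:
    def _ext(self, rows, labels):
        pat = pd.DataFrame(
            rows, index=labels, columns=[f"F{i + 1}" for i in range(len(rows[0]))]
        )
        return ExtensionLoadings(
            pattern=pat,
            structure=pat,
            cross_correlations=pd.DataFrame(),
            reference_rotation="promax",
        )

    def test_rule_applied_verbatim(self):
        ext = self._ext(
            [
                [0.50, 0.10, 0.00],   # selected for F1
                [0.50, 0.40, 0.00],   # rejected: cross-loading
                [0.44, 0.10, 0.00],   # rejected: primary below threshold
                [-0.60, 0.20, 0.10],  # selected (absolute loading)
            ],
            ["good", "crossed", "weak", "negative"],
        )
        spec = select_indicators(ext, min_items=1)
        assert spec.selected["F1"] == ["good", "negative"]
        assert not spec.selected["F2"] and not spec.selected["F3"]

    def test_representable_flag_needs_min_items(self):
        ext = self._ext(
            [[0.6, 0.0], [0.55, 0.1], [0.5, 0.0], [0.0, 0.6]],
            ["a", "b", "c", "d"],
        )
        spec = select_indicators(ext, min_items=3)
        assert spec.representable == {"F1": True, "F2": False}

    def test_raising_primary_threshold_never_adds(self):
        rng = np.random.default_rng(5)
        ext = self._ext(
            rng.uniform(-0.7, 0.7, size=(30, 3)).tolist(),
            [f"e{j}" for j in range(30)],
        )
        lo = select_indicators(ext, primary_min=0.40, min_items=1)
        hi = select_indicators(ext, primary_min=0.55, min_items=1)
        for f in lo.selected:
            assert set(hi.selected[f]) <= set(lo.selected[f])

    def test_bad_thresholds_rejected(self):
        ext = self._ext([[0.5, 0.1]], ["a"])
        with pytest.raises(ValueError):
            select_indicators(ext, primary_min=0.3, cross_max=0.4)


class TestIndicatorScores:
    def test_scoring_and_missing_items_drop_out(self):
        df = pd.DataFrame(
            {"a": [4.0, 4.0], "b": [2.0, np.nan], "c": [1.0, 1.0]}
        )
        data = ItemResponseMatrix(df, pd.Series({"a": 4, "b": 4, "c": 4}))
        from hyperdim.extension import IndicatorSpec

        spec = IndicatorSpec(
            selected={"F1": ["a", "b", "c"]},
            rescale_bounds={k: (1.0, 4.0) for k in "abc"},
            representable={"F1": True},
        )
        scores = score_indicators(data, spec)
        # rescaled to 0-4: a -> 4, b -> 4/3, c -> 0
        assert scores.loc[0, "F1"] == pytest.approx((4 + 4 / 3 + 0) / 3)
        # missing item excluded from the person's mean, not propagated
        assert scores.loc[1, "F1"] == pytest.approx((4 + 0) / 2)

    def test_validation_identity_and_misalignment(self):
        rng = np.random.default_rng(6)
        ref = pd.DataFrame({"F1": rng.normal(size=300)})
        r_same = validate_indicators(ref, ref)
        assert r_same["F1"] == pytest.approx(1.0)
        perm = ref.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r_perm = validate_indicators(perm, ref)
        assert abs(r_perm["F1"]) < 0.15

    def test_preset_indicator_validity(self, preset_data, preset_solution, preset_polychoric):
        """External indicator estimates track the short-form scores of the
        dimensions they represent (the study saw r = 0.75-0.85)."""
        from hyperdim.polychoric import cross_polychoric
        from hyperdim.shortform import select_markers, score_short_form
        from hyperdim.simulate import MARKER_COUNTS

        R_eo = cross_polychoric(
            preset_data.external_responses, preset_data.responses
        )
        ext = extend_loadings(preset_polychoric.rho, preset_solution, R_eo)
        spec = select_indicators(
            ext, preset_data.external_responses.category_counts
        )
        assert sum(spec.representable.values()) == 3
        ind = score_indicators(preset_data.external_responses, spec)
        sf_spec = select_markers(
            preset_solution,
            preset_data.responses.category_counts,
            tuple(MARKER_COUNTS.values()),
        )
        sf = score_short_form(preset_data.responses, sf_spec)
        r = validate_indicators(ind, sf[list(ind.columns)])
        assert (r >= 0.7).all()
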