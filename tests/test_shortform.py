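"""Short-form marker selection, 0-4 scoring and full-battery consistency."""

import numpy as np
import pandas as pd
import pytest

from hyperdim.datatypes import FactorSolution, ItemResponseMatrix
from hyperdim.efa import weighted_factor_scores
from hyperdim.shortform import (
    ShortFormSpec,
    consistency_with_full,
    rescale_responses,
    score_short_form,
    select_markers,
)


def _solution(pattern, phi=None):
    pat = pd.DataFrame(pattern)
    pat.columns = [f"F{i + 1}" for i in range(pat.shape[1])]
    k = pat.shape[1]
    phi = np.eye(k) if phi is None else np.asarray(phi)
    names = list(pat.columns)
    h2 = np.einsum("if,fg,ig->i", pat.to_numpy(), phi, pat.to_numpy())
    return FactorSolution(
        pattern=pat,
        phi=pd.DataFrame(phi, index=names, columns=names),
        uniquenesses=pd.Series(np.clip(1 - h2, 0, 1), index=pat.index),
        eigenvalues=np.array([]),
        rotation="promax",
        n_obs=100,
    )


class TestSelectMarkers:
    def test_clean_item_eligible(self):
        pat = pd.DataFrame(
            [[0.70, 0.10], [0.65, 0.05], [0.05, 0.72], [0.02, 0.66]],
            index=["a", "b", "c", "d"],
        )
        sol = _solution(pat)
        spec = select_markers(sol, pd.Series(5, index=pat.index), (2, 2))
        assert spec.markers == {"F1": ["a", "b"], "F2": ["c", "d"]}

    def test_cross_loaded_item_excluded_at_cap(self):
        pat = pd.DataFrame(
            [[0.50, 0.40], [0.60, 0.10], [0.55, 0.05],
             [0.05, 0.72], [0.02, 0.66]],
            index=list("abcde"),
        )
        sol = _solution(pat)
        spec = select_markers(sol, pd.Series(5, index=pat.index), (2, 2))
        assert "a" not in spec.markers["F1"]

    def test_planted_marker_set_recovered_exactly(self):
        """On a solution with planted markers (0.8 primary, <= 0.1 cross)
        amid weaker distractors, selection returns exactly the planted set."""
        rng = np.random.default_rng(7)
        rows, labels = [], []
        planted = {"F1": [], "F2": [], "F3": []}
        for f in range(3):
            for m in range(3):
                lab = f"marker_{f}_{m}"
                row = rng.uniform(-0.1, 0.1, 3)
                row[f] = 0.8
                rows.append(row)
                labels.append(lab)
                planted[f"F{f + 1}"].append(lab)
            for d in range(2):
                row = rng.uniform(-0.1, 0.1, 3)
                row[f] = 0.45
                rows.append(row)
                labels.append(f"distractor_{f}_{d}")
        pat = pd.DataFrame(rows, index=labels)
        sol = _solution(pat)
        spec = select_markers(sol, pd.Series(5, index=pat.index), (3, 3, 3))
        assert {f: sorted(v) for f, v in spec.markers.items()} == {
            f: sorted(v) for f, v in planted.items()
        }

    def test_preset_selection_aligns_with_true_factors(
        self, preset_solution, preset_cfg, preset_data
    ):
        """End to end on the study-like preset, every selected marker items
        measures the true factor it is selected for."""
        from hyperdim.efa import match_factors
        from hyperdim.simulate import MARKER_COUNTS

        perm, _ = match_factors(
            preset_solution.pattern.to_numpy(), preset_cfg.loading_matrix.to_numpy()
        )
        true_names = list(preset_cfg.factor_correlations.columns)
        recovered_to_true = {
            preset_solution.factor_names[perm[i]]: true_names[i]
            for i in range(len(true_names))
        }
        counts = tuple(
            MARKER_COUNTS[recovered_to_true[f]]
            for f in preset_solution.factor_names
        )
        spec = select_markers(
            preset_solution, preset_data.responses.category_counts, counts
        )
        for fac, items in spec.markers.items():
            true_fac = recovered_to_true[fac]
            for it in items:
                assert it.startswith(true_fac + "_"), (fac, true_fac, it)

    def test_relaxation_recorded_when_pool_thin(self):
        pat = pd.DataFrame(
            [[0.70, 0.40], [0.60, 0.35], [0.05, 0.72], [0.02, 0.66]],
            index=list("abcd"),
        )
        sol = _solution(pat)
        spec = select_markers(sol, pd.Series(5, index=pat.index), (2, 2))
        assert "F1" in spec.relaxed_caps
        assert len(spec.markers["F1"]) == 2

    def test_counts_outside_range_rejected(self):
        pat = pd.DataFrame([[0.7, 0.0], [0.6, 0.0], [0.0, 0.7], [0.0, 0.6]])
        sol = _solution(pat)
        with pytest.raises(ValueError):
            select_markers(sol, pd.Series(5, index=pat.index), (6, 2))

    def test_markers_disjoint_across_factors(self):
        with pytest.raises(ValueError, match="assigned to both"):
            ShortFormSpec(
                markers={"F1": ["a", "b"], "F2": ["b", "c"]},
                rescale_bounds={"a": (1, 5), "b": (1, 5), "c": (1, 5)},
            )


class TestScoring:
    def _data(self, values, cats):
        df = pd.DataFrame(values)
        return ItemResponseMatrix(df, pd.Series(cats))

    def test_extremes_map_to_bounds(self):
        data = self._data(
            {"a": [5.0, 1.0], "b": [5.0, 1.0], "c": [2.0, 1.0]},
            {"a": 5, "b": 5, "c": 2},
        )
        spec = ShortFormSpec(
            markers={"F1": ["a", "b", "c"]},
            rescale_bounds={"a": (1, 5), "b": (1, 5), "c": (1, 2)},
        )
        scores = score_short_form(data, spec)
        assert scores.loc[0, "F1"] == pytest.approx(4.0)
        assert scores.loc[1, "F1"] == pytest.approx(0.0)

    def test_hand_computed_mean(self):
        data = self._data(
            {"a": [1.0], "b": [3.0], "c": [5.0], "d": [5.0]},
            {"a": 5, "b": 5, "c": 5, "d": 5},
        )
        spec = ShortFormSpec(
            markers={"F1": ["a", "b", "c", "d"]},
            rescale_bounds={k: (1, 5) for k in "abcd"},
        )
        assert score_short_form(data, spec).loc[0, "F1"] == pytest.approx(2.5)

    def test_rescaling_invariant_to_coding_range(self):
        # a 4-level item coded 1-4 vs the same responses coded 0-3
        x14 = pd.Series([1.0, 2, 3, 4])
        x03 = x14 - 1
        r1 = rescale_responses(x14, (1, 4))
        r2 = rescale_responses(x03, (0, 3))
        assert np.allclose(r1, r2)

    def test_marker_order_irrelevant(self):
        data = self._data(
            {"a": [2.0, 4.0], "b": [3.0, 1.0]}, {"a": 5, "b": 5}
        )
        s1 = score_short_form(
            data,
            ShortFormSpec({"F1": ["a", "b"]}, {"a": (1, 5), "b": (1, 5)}),
        )
        s2 = score_short_form(
            data,
            ShortFormSpec({"F1": ["b", "a"]}, {"a": (1, 5), "b": (1, 5)}),
        )
        assert s1.equals(s2)

    def test_missing_marker_blanks_factor(self):
        data = self._data(
            {"a": [2.0, np.nan], "b": [3.0, 3.0]}, {"a": 5, "b": 5}
        )
        spec = ShortFormSpec({"F1": ["a", "b"]}, {"a": (1, 5), "b": (1, 5)})
        scores = score_short_form(data, spec)
        assert np.isnan(scores.loc[1, "F1"])

    def test_out_of_bounds_response_rejected(self):
        data = self._data({"a": [6.0], "b": [1.0]}, {"a": 7, "b": 5})
        spec = ShortFormSpec({"F1": ["a", "b"]}, {"a": (1, 5), "b": (1, 5)})
        with pytest.raises(ValueError, match="outside declared bounds"):
            score_short_form(data, spec)

    def test_scores_within_response_scale(self, preset_data, preset_solution):
        from hyperdim.simulate import MARKER_COUNTS

        spec = select_markers(
            preset_solution,
            preset_data.responses.category_counts,
            tuple(MARKER_COUNTS.values()),
        )
        scores = score_short_form(preset_data.responses, spec)
        arr = scores.to_numpy()
        ok = ~np.isnan(arr)
        assert arr[ok].min() >= 0.0 and arr[ok].max() <= 4.0


class TestConsistency:
    def test_affine_transform_gives_unit_r(self):
        rng = np.random.default_rng(0)
        full = pd.DataFrame({"F1": rng.normal(size=100)})
        short = full * 0.3 + 1.7
        assert consistency_with_full(short, full)["F1"] == pytest.approx(1.0)

    def test_independent_columns_give_near_zero(self):
        rng = np.random.default_rng(1)
        full = pd.DataFrame({"F1": rng.normal(size=2000)})
        short = pd.DataFrame({"F1": rng.normal(size=2000)})
        assert abs(consistency_with_full(short, full)["F1"]) < 0.07

    def test_preset_end_to_end_consistency(self, preset_data, preset_solution):
        """Short-form scores track the full-battery weighted scores for
        every dimension (the study reported 0.82-0.92)."""
        from hyperdim.simulate import MARKER_COUNTS

        spec = select_markers(
            preset_solution,
            preset_data.responses.category_counts,
            tuple(MARKER_COUNTS.values()),
        )
        short = score_short_form(preset_data.responses, spec)
        full = weighted_factor_scores(preset_data.responses, preset_solution)
        r = consistency_with_full(short, full)
        assert (r >= 0.8).all()
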