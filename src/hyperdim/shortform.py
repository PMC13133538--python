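"""Short-form instrument construction and 0-4 scoring.

Two to five marker items are chosen per factor by highest pattern loading
among items free of cross-loadings; responses are rescaled to a common 0-4
range and averaged within each factor, so every dimension score lives on
the same interpretable scale regardless of the source items' responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datatypes import FactorSolution, ItemResponseMatrix
from .efa import SALIENCE_THRESHOLD

# Per-factor marker counts of the default seven-dimension instrument:
# five factors carry 4 items, the somatic factor 5, the vigilant factor 2.
DEFAULT_PER_FACTOR_COUNTS = (4, 5, 4, 4, 4, 2, 4)


@dataclass
class ShortFormSpec:
    """Marker items per factor plus each item's rescaling bounds."""

    markers: dict[str, list]                    # factor -> ordered item list
    rescale_bounds: dict[str, tuple[float, float]]  # item -> (min_code, max_code)
    response_scale: tuple[float, float] = (0.0, 4.0)
    relaxed_caps: dict[str, float] = field(default_factory=dict)
    overridden: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = {}
        for fac, items in self.markers.items():
            if not 2 <= len(items) <= 5:
                raise ValueError(
                    f"factor {fac!r} has {len(items)} markers; 2-5 required"
                )
            for it in items:
                if it in seen:
                    raise ValueError(
                        f"item {it!r} assigned to both {seen[it]!r} and {fac!r}"
                    )
                seen[it] = fac

    def to_json_dict(self) -> dict:
        return {
            "markers": {f: list(v) for f, v in self.markers.items()},
            "rescale_bounds": {k: list(v) for k, v in self.rescale_bounds.items()},
            "response_scale": list(self.response_scale),
            "relaxed_caps": dict(self.relaxed_caps),
            "overridden": {f: list(v) for f, v in self.overridden.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ShortFormSpec":
        return cls(
            markers={f: list(v) for f, v in d["markers"].items()},
            rescale_bounds={k: tuple(v) for k, v in d["rescale_bounds"].items()},
            response_scale=tuple(d.get("response_scale", (0.0, 4.0))),
            relaxed_caps=dict(d.get("relaxed_caps", {})),
            overridden={f: list(v) for f, v in d.get("overridden", {}).items()},
        )


def select_markers(
    solution: FactorSolution,
    category_counts: pd.Series,
    per_factor_counts=DEFAULT_PER_FACTOR_COUNTS,
    cross_loading_cap: float = SALIENCE_THRESHOLD,
    salience_threshold: float = SALIENCE_THRESHOLD,
    manual_overrides: dict[str, list] | None = None,
) -> ShortFormSpec:
    """Choose the highest-loading cross-loading-free markers per factor.

    An item is eligible for a factor when its pattern loading there is
    salient and its largest |loading| on any other factor stays at or below
    ``cross_loading_cap``.  If a factor cannot fill its requested count the
    cap is relaxed in recorded steps of 0.05; fewer than 2 eligible items
    even at a fully relaxed cap is an error.  ``manual_overrides`` replaces
    a factor's data-driven list outright (recorded in the spec), standing in
    for content-based judgment.
    """
    factors = solution.factor_names
    counts = dict(zip(factors, per_factor_counts))
    pattern = solution.pattern
    taken: set = set()
    markers: dict[str, list] = {}
    relaxed: dict[str, float] = {}
    overridden: dict[str, list] = {}
    manual_overrides = manual_overrides or {}

    for fac in factors:
        want = counts[fac]
        if not 2 <= want <= 5:
            raise ValueError(f"per-factor count {want} outside [2, 5]")
        if fac in manual_overrides:
            chosen = list(manual_overrides[fac])
            overridden[fac] = chosen
        else:
            cap = cross_loading_cap
            chosen = []
            while True:
                abs_load = pattern[fac].abs()
                others = pattern.drop(columns=[fac]).abs().max(axis=1)
                eligible = pattern.index[
                    (abs_load >= salience_threshold)
                    & (others <= cap)
                    & (~pattern.index.isin(taken))
                ]
                ranked = abs_load.loc[eligible].sort_values(ascending=False)
                chosen = list(ranked.index[:want])
                if len(chosen) >= want or cap >= 1.0:
                    break
                cap = round(cap + 0.05, 10)
                relaxed[fac] = cap
            if len(chosen) < 2:
                raise ValueError(
                    f"factor {fac!r}: fewer than 2 eligible markers even after "
                    "relaxing the cross-loading cap"
                )
        taken.update(chosen)
        markers[fac] = chosen

    bounds = {
        item: (1.0, float(category_counts[item]))
        for items in markers.values()
        for item in items
    }
    return ShortFormSpec(
        markers=markers,
        rescale_bounds=bounds,
        relaxed_caps=relaxed,
        overridden=overridden,
    )


def rescale_responses(col: pd.Series, bounds: tuple[float, float],
                      scale: tuple[float, float] = (0.0, 4.0)) -> pd.Series:
    lo, hi = bounds
    if hi <= lo:
        raise ValueError("rescale bounds must satisfy max > min")
    obs = col.dropna()
    if ((obs < lo) | (obs > hi)).any():
        raise ValueError(f"response outside declared bounds [{lo}, {hi}]")
    smin, smax = scale
    return (col - lo) / (hi - lo) * (smax - smin) + smin


def score_short_form(data: ItemResponseMatrix, spec: ShortFormSpec) -> pd.DataFrame:
    """Mean of 0-4-rescaled marker responses per factor.

    A person missing any marker of a factor gets a missing score on that
    factor (the short form is brief enough that imputation by available-item
    means would change its meaning).
    """
    missing = [
        it for items in spec.markers.values() for it in items
        if it not in data.values.columns
    ]
    if missing:
        raise ValueError(f"spec items not present in data: {missing}")
    out = {}
    for fac, items in spec.markers.items():
        resc = pd.concat(
            [
                rescale_responses(
                    data.values[it], spec.rescale_bounds[it], spec.response_scale
                )
                for it in items
            ],
            axis=1,
        )
        score = resc.mean(axis=1)
        score[resc.isna().any(axis=1)] = np.nan
        out[fac] = score
    return pd.DataFrame(out, index=data.values.index)


def consistency_with_full(short: pd.DataFrame, full: pd.DataFrame) -> pd.Series:
    """Per-factor Pearson r between short-form and full-battery scores."""
    if list(short.columns) != list(full.columns):
        raise ValueError("factor columns do not align")
    out = {}
    for fac in short.columns:
        a, b = short[fac], full[fac]
        ok = a.notna() & b.notna()
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for factor {fac!r}")
        out[fac] = pearsonr(a[ok], b[ok]).statistic
    return pd.Series(out)
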