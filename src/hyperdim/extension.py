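"""Factor extension: loadings of items outside the analyzed battery.

Dwyer's extension estimates what external items *would* have loaded on an
existing factor solution, from nothing more than their correlations with
the analyzed items: the extension structure is
``S_e = R_eo R_oo^{-1} (Lambda Phi)`` and the extension pattern
``Lambda_e = S_e Phi^{-1}``.  This variant satisfies the duplicate-item
identity — an external item identical to an analyzed item reproduces that
item's pattern row exactly — which is adopted here as the defining contract
of the method.  Selected high-loading, cross-loading-free external items
then form indicator measures for the dimensions they represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datatypes import FactorSolution, ItemResponseMatrix
from .shortform import rescale_responses

PRIMARY_MIN = 0.45
CROSS_MAX = 0.32


@dataclass
class ExtensionLoadings:
    pattern: pd.DataFrame       # external items x factors
    structure: pd.DataFrame
    cross_correlations: pd.DataFrame   # R_eo used
    reference_rotation: str


def extend_loadings(
    R_oo: pd.DataFrame,
    solution: FactorSolution,
    R_eo: pd.DataFrame,
) -> ExtensionLoadings:
    """Extension pattern/structure loadings of external items.

    ``R_oo``: correlations among the analyzed (original) items;
    ``R_eo``: external x original cross-correlation block, columns aligned
    with the solution's items.
    """
    items = list(solution.pattern.index)
    if list(R_eo.columns) != items or list(R_oo.columns) != items:
        raise ValueError("correlation blocks must align with the solution's items")
    Roo = np.asarray(R_oo, dtype=float)
    Reo = np.asarray(R_eo, dtype=float)
    try:
        Roo_inv = np.linalg.inv(Roo)
    except np.linalg.LinAlgError as err:
        raise ValueError("original-item correlation matrix is singular") from err
    lam = solution.pattern.to_numpy()
    phi = solution.phi.to_numpy()
    S_e = Reo @ Roo_inv @ (lam @ phi)
    L_e = S_e @ np.linalg.inv(phi)
    ext_items = list(R_eo.index)
    names = solution.factor_names
    return ExtensionLoadings(
        pattern=pd.DataFrame(L_e, index=ext_items, columns=names),
        structure=pd.DataFrame(S_e, index=ext_items, columns=names),
        cross_correlations=pd.DataFrame(Reo, index=ext_items, columns=items),
        reference_rotation=solution.rotation,
    )


@dataclass
class IndicatorSpec:
    """External items selected to indicate each dimension."""

    selected: dict[str, list]                      # factor -> items
    rescale_bounds: dict[str, tuple[float, float]]
    representable: dict[str, bool] = field(default_factory=dict)
    primary_min: float = PRIMARY_MIN
    cross_max: float = CROSS_MAX
    min_items: int = 3

    def to_json_dict(self) -> dict:
        return {
            "selected": {f: list(v) for f, v in self.selected.items()},
            "rescale_bounds": {k: list(v) for k, v in self.rescale_bounds.items()},
            "representable": dict(self.representable),
            "primary_min": self.primary_min,
            "cross_max": self.cross_max,
            "min_items": self.min_items,
        }


def select_indicators(
    ext: ExtensionLoadings,
    category_counts: pd.Series | None = None,
    primary_min: float = PRIMARY_MIN,
    cross_max: float = CROSS_MAX,
    min_items: int = 3,
) -> IndicatorSpec:
    """Apply the specificity rule: primary |loading| > primary_min on exactly
    one factor and no other |loading| > cross_max.  Dimensions reaching
    ``min_items`` selected items are flagged representable."""
    if not (0 < cross_max < primary_min < 1):
        raise ValueError("thresholds must satisfy 0 < cross_max < primary_min < 1")
    pat = ext.pattern
    selected: dict[str, list] = {f: [] for f in pat.columns}
    for item in pat.index:
        row = pat.loc[item].abs()
        top = row.idxmax()
        others = row.drop(index=top)
        if row[top] > primary_min and (others <= cross_max).all():
            selected[top].append(item)
    representable = {f: len(v) >= min_items for f, v in selected.items()}
    bounds = {}
    if category_counts is not None:
        for items in selected.values():
            for it in items:
                bounds[it] = (1.0, float(category_counts[it]))
    return IndicatorSpec(
        selected=selected,
        rescale_bounds=bounds,
        representable=representable,
        primary_min=primary_min,
        cross_max=cross_max,
        min_items=min_items,
    )


def score_indicators(
    responses: ItemResponseMatrix,
    spec: IndicatorSpec,
    representable_only: bool = True,
) -> pd.DataFrame:
    """Indicator dimension scores: mean of 0-4-rescaled available items.

    Unlike short-form scoring, a person's missing items simply drop out of
    the mean (external-cohort refusal codes are excluded item-wise); a
    person with no available item in a dimension gets a missing score.
    """
    out = {}
    for fac, items in spec.selected.items():
        if representable_only and not spec.representable.get(fac, False):
            continue
        if not items:
            continue
        missing = [it for it in items if it not in responses.values.columns]
        if missing:
            raise ValueError(f"indicator items not in responses: {missing}")
        resc = pd.concat(
            [
                rescale_responses(responses.values[it], spec.rescale_bounds[it])
                for it in items
            ],
            axis=1,
        )
        out[fac] = resc.mean(axis=1)  # skipna: available items only
    return pd.DataFrame(out, index=responses.values.index)


def validate_indicators(
    indicator: pd.DataFrame, reference: pd.DataFrame
) -> pd.Series:
    """Pearson r between indicator estimates and reference dimension scores."""
    out = {}
    for fac in indicator.columns:
        if fac not in reference.columns:
            raise ValueError(f"reference scores lack dimension {fac!r}")
        a, b = indicator[fac], reference[fac]
        ok = a.notna() & b.notna()
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for {fac!r}")
        out[fac] = pearsonr(a[ok], b[ok]).statistic
    return pd.Series(out)
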