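"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ItemResponseMatrix:
    """Persons x items ordinal responses coded ``1..n_categories`` per item.

    Missing entries are represented by NaN in ``values`` and mirrored in
    ``missing_mask``.  ``category_counts`` records the theoretical number of
    response options per item (2, 4 or 5 in the hyperarousal battery);
    observed codes must lie in ``[1, category_count]``.
    """

    values: pd.DataFrame
    category_counts: pd.Series
    scale_provenance: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.category_counts = pd.Series(self.category_counts).reindex(
            self.values.columns
        )
        if self.category_counts.isna().any():
            missing = self.category_counts.index[self.category_counts.isna()]
            raise ValueError(f"missing category counts for items: {list(missing)}")
        self.category_counts = self.category_counts.astype(int)
        if self.scale_provenance is not None:
            self.scale_provenance = pd.Series(self.scale_provenance).reindex(
                self.values.columns
            )
        self._validate_codes()

    def _validate_codes(self) -> None:
        for item in self.values.columns:
            col = self.values[item]
            obs = col.dropna()
            if len(obs) == 0:
                continue
            top = self.category_counts[item]
            bad = obs[(obs < 1) | (obs > top) | (obs != np.round(obs))]
            if len(bad) > 0:
                person = bad.index[0]
                raise ValueError(
                    f"response code {bad.iloc[0]:g} out of range [1, {top}] "
                    f"at person {person}, item {item!r}"
                )

    @property
    def item_ids(self) -> list:
        return list(self.values.columns)

    @property
    def person_ids(self) -> list:
        return list(self.values.index)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subset(self, items) -> "ItemResponseMatrix":
        """Return a copy restricted to ``items`` (order preserved)."""
        items = list(items)
        prov = (
            self.scale_provenance.loc[items]
            if self.scale_provenance is not None
            else None
        )
        return ItemResponseMatrix(
            self.values.loc[:, items],
            self.category_counts.loc[items],
            prov,
        )


@dataclass
class PolychoricResult:
    """Latent-correlation matrix of a battery of ordinal items."""

    rho: pd.DataFrame
    thresholds: dict[str, np.ndarray]
    smoothed: bool
    pair_diagnostics: pd.DataFrame  # columns: item_a, item_b, converged, zero_cells_corrected
    n_obs: int

    @property
    def item_ids(self) -> list:
        return list(self.rho.columns)


@dataclass
class FactorSolution:
    """Rotated (or unrotated) exploratory factor solution."""

    pattern: pd.DataFrame          # items x k pattern loadings (Lambda)
    phi: pd.DataFrame              # k x k factor correlations
    uniquenesses: pd.Series        # psi per item
    eigenvalues: np.ndarray        # reduced-matrix eigenvalues (descending)
    rotation: str
    n_obs: int
    converged: bool = True
    heywood_items: list = field(default_factory=list)

    @property
    def structure(self) -> pd.DataFrame:
        """Structure loadings = pattern . Phi (item-factor correlations)."""
        return self.pattern @ self.phi

    @property
    def communalities(self) -> pd.Series:
        return 1.0 - self.uniquenesses

    @property
    def n_factors(self) -> int:
        return self.pattern.shape[1]

    @property
    def factor_names(self) -> list:
        return list(self.pattern.columns)
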