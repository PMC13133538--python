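"""Stepwise redundancy reduction of near-duplicate questionnaire items.

Walking a descending threshold schedule (|0.9| down to |0.5| in steps of
0.05 by default), the procedure repeatedly finds the surviving item pair
with the largest absolute correlation above the current threshold and drops
the pair member whose absolute *median* correlation with the other surviving
items is higher — i.e. the item that carries less unique variance.  Medians
are recomputed on the surviving set after every removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import PolychoricResult


@dataclass
class Removal:
    threshold: float
    removed_item: str
    kept_item: str
    pair_correlation: float
    tie_broken: bool


@dataclass
class ReductionTrace:
    threshold_schedule: list[float]
    removals: list[Removal] = field(default_factory=list)
    surviving_items: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    threshold=r.threshold,
                    removed_item=r.removed_item,
                    kept_item=r.kept_item,
                    pair_correlation=r.pair_correlation,
                    tie_broken=r.tie_broken,
                )
                for r in self.removals
            ],
            columns=[
                "threshold",
                "removed_item",
                "kept_item",
                "pair_correlation",
                "tie_broken",
            ],
        )


def absolute_median_correlation(item, R: pd.DataFrame, surviving_set) -> float:
    """Median of |r| between ``item`` and every *other* surviving item."""
    others = [k for k in surviving_set if k != item]
    if item not in list(surviving_set):
        raise ValueError(f"item {item!r} not in surviving set")
    if not others:
        raise ValueError("surviving set must contain at least two items")
    return float(np.median(np.abs(R.loc[item, others].to_numpy(dtype=float))))


def _threshold_schedule(start: float, stop: float, step: float) -> list[float]:
    if step <= 0:
        raise ValueError("step must be positive")
    if stop > start:
        raise ValueError("stop_threshold must not exceed start_threshold")
    n = int(round((start - stop) / step))
    sched = [round(start - i * step, 10) for i in range(n + 1)]
    if sched[-1] > stop + 1e-12:
        sched.append(stop)
    return sched


def reduce_items(
    R: PolychoricResult | pd.DataFrame,
    start_threshold: float = 0.9,
    stop_threshold: float = 0.5,
    step: float = 0.05,
    priority: pd.Series | dict | None = None,
) -> ReductionTrace:
    """Run the stepwise redundancy-reduction schedule on a labeled matrix.

    ``priority`` optionally ranks items (lower rank = keep on median ties,
    standing in for the content judgment of which item is more trait-like);
    without it ties fall back to lexicographic label order.  Every tie-broken
    removal is flagged in the trace.
    """
    corr = R.rho if isinstance(R, PolychoricResult) else pd.DataFrame(R)
    if list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    if isinstance(corr.columns, pd.RangeIndex):
        raise ValueError("correlation matrix must carry item labels")
    if priority is not None:
        priority = pd.Series(priority)

    schedule = _threshold_schedule(start_threshold, stop_threshold, step)
    surviving = list(corr.columns)
    trace = ReductionTrace(threshold_schedule=schedule)

    for t in schedule:
        while True:
            sub = corr.loc[surviving, surviving].abs().to_numpy()
            np.fill_diagonal(sub, 0.0)
            iu = np.triu_indices(len(surviving), 1)
            if iu[0].size == 0:
                break
            vals = sub[iu]
            exceed = vals > t
            if not exceed.any():
                break
            # deterministic order: descending |r|, ties by label pair
            order = sorted(
                np.flatnonzero(exceed),
                key=lambda q: (-vals[q], str(surviving[iu[0][q]]), str(surviving[iu[1][q]])),
            )
            q = order[0]
            a, b = surviving[iu[0][q]], surviving[iu[1][q]]
            med_a = absolute_median_correlation(a, corr, surviving)
            med_b = absolute_median_correlation(b, corr, surviving)
            tie = False
            if med_a < med_b:
                keep, drop = a, b
            elif med_b < med_a:
                keep, drop = b, a
            else:
                tie = True
                if priority is not None and a in priority.index and b in priority.index:
                    keep, drop = (a, b) if priority[a] <= priority[b] else (b, a)
                else:
                    keep, drop = (a, b) if str(a) <= str(b) else (b, a)
            surviving.remove(drop)
            trace.removals.append(
                Removal(t, drop, keep, float(corr.loc[a, b]), tie)
            )
    trace.surviving_items = surviving
    return trace


class StepwiseRedundancyFilter(BaseEstimator):
    """Sklearn-style wrapper: fit on a labeled correlation matrix, then
    ``transform`` selects the surviving columns of a response table.

    Attributes (after ``fit``)
    --------------------------
    support_ : list of surviving item labels.
    trace_ : :class:`ReductionTrace` of every removal.
    """

    def __init__(
        self,
        start_threshold: float = 0.9,
        stop_threshold: float = 0.5,
        step: float = 0.05,
        priority=None,
    ):
        self.start_threshold = start_threshold
        self.stop_threshold = stop_threshold
        self.step = step
        self.priority = priority

    def fit(self, R, y=None):
        self.trace_ = reduce_items(
            R,
            start_threshold=self.start_threshold,
            stop_threshold=self.stop_threshold,
            step=self.step,
            priority=self.priority,
        )
        self.support_ = list(self.trace_.surviving_items)
        return self

    def transform(self, X):
        if hasattr(X, "subset"):
            return X.subset(self.support_)
        return pd.DataFrame(X).loc[:, self.support_]
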