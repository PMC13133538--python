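"""Polychoric correlation estimation and sampling-adequacy screening.

Two-step maximum likelihood: per-item thresholds are fixed at the inverse
normal CDF of the cumulative margin proportions, then the latent correlation
of each item pair maximizes the bivariate-normal multinomial likelihood of
the pair's contingency table.  Zero cells are replaced by 0.1 as a
continuity correction before the likelihood is evaluated.  The assembled
matrix is eigenvalue-smoothed to positive semidefiniteness when needed.

The estimator class :class:`PolychoricCorrelation` follows the
scikit-learn covariance-estimator idiom (``fit`` + trailing-underscore
attributes); the module functions are the primitive operations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._bvn import bvn_cdf
from .datatypes import ItemResponseMatrix, PolychoricResult

RHO_BOUND = 0.999
ZERO_CELL_CORRECTION = 0.1


def estimate_thresholds(column) -> np.ndarray:
    """Thresholds tau for one ordinal column from its cumulative margins.

    ``tau_c = Phi^{-1}(P(code <= c))`` for every observed category boundary;
    empty categories are collapsed (no threshold is produced for them), so
    the result is strictly increasing with length ``n_observed_categories - 1``.

    Raises ``ValueError`` if fewer than two categories are observed.
    """
    col = pd.Series(column).dropna().to_numpy()
    if col.size == 0:
        raise ValueError("no observed responses")
    codes, counts = np.unique(col, return_counts=True)
    if codes.size < 2:
        raise ValueError("all responses identical: a single observed category")
    cum = np.cumsum(counts)[:-1] / col.size
    return norm.ppf(cum)


def contingency_table(x, y) -> np.ndarray:
    """Two-way table of pairwise-complete responses, empty categories collapsed."""
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    xc = np.unique(x)
    yc = np.unique(y)
    table = np.zeros((xc.size, yc.size))
    xi = np.searchsorted(xc, x)
    yi = np.searchsorted(yc, y)
    np.add.at(table, (xi, yi), 1.0)
    return table


def _cell_probabilities(tau_row: np.ndarray, tau_col: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal between thresholds."""
    a = np.concatenate(([-np.inf], tau_row, [np.inf]))
    b = np.concatenate(([-np.inf], tau_col, [np.inf]))
    F = bvn_cdf(a[:, None], b[None, :], rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-300, None)


@dataclass
class PairDiagnostics:
    converged: bool
    zero_cells_corrected: int


def estimate_polychoric_pair(
    table: np.ndarray,
    tau_row: np.ndarray | None = None,
    tau_col: np.ndarray | None = None,
    *,
    correction: float = ZERO_CELL_CORRECTION,
    tol: float = 1e-6,
) -> tuple[float, PairDiagnostics]:
    """ML polychoric correlation of one pair from its contingency table.

    Thresholds default to the inverse-CDF of the (corrected) table margins.
    Every zero cell is replaced by ``correction`` (0.1) before both the
    margins and the likelihood are computed; rho maximizes
    ``sum_ij n_ij log P_ij(rho)`` on (-0.999, 0.999) by bounded scalar
    minimization.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("contingency table must be nonnegative")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("pair requires >= 2 observed categories per item")
    n_zero = int(np.sum(table == 0))
    if n_zero:
        table = np.where(table == 0, correction, table)
    n = table.sum()
    if tau_row is None:
        tau_row = norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    if tau_col is None:
        tau_col = norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)

    def neg_loglik(rho: float) -> float:
        P = _cell_probabilities(tau_row, tau_col, rho)
        return -float(np.sum(table * np.log(P)))

    res = minimize_scalar(
        neg_loglik,
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": tol},
    )
    rho = float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))
    return rho, PairDiagnostics(bool(res.success), n_zero)


def smooth_correlation(R: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues, reconstruct, rescale to unit diagonal."""
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh(R)
    w = np.clip(w, eig_floor, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def polychoric_matrix(
    data: ItemResponseMatrix,
    *,
    correction: float = ZERO_CELL_CORRECTION,
    smooth: bool = True,
    min_pairs: int = 3,
) -> PolychoricResult:
    """Pairwise-complete polychoric correlation matrix of a battery.

    Thresholds are re-estimated per pair on the pairwise-complete rows
    (the ``global = FALSE`` convention); the per-item thresholds reported in
    the result come from each item's full margin.
    """
    items = data.item_ids
    p = len(items)
    X = data.values.to_numpy()
    for j, item in enumerate(items):
        obs = X[:, j][~np.isnan(X[:, j])]
        if np.unique(obs).size < 2:
            raise ValueError(
                f"item {item!r} has a single observed category"
            )
    R = np.eye(p)
    diag_rows = []
    for i in range(p):
        for j in range(i + 1, p):
            ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if ok.sum() < min_pairs:
                raise ValueError(
                    f"fewer than {min_pairs} pairwise-complete observations "
                    f"for items {items[i]!r}, {items[j]!r}"
                )
            table = contingency_table(X[ok, i], X[ok, j])
            rho, diag = estimate_polychoric_pair(table, correction=correction)
            R[i, j] = R[j, i] = rho
            diag_rows.append(
                dict(
                    item_a=items[i],
                    item_b=items[j],
                    converged=diag.converged,
                    zero_cells_corrected=diag.zero_cells_corrected,
                )
            )
    smoothed = False
    if smooth and np.linalg.eigvalsh(R).min() < -1e-10:
        R = smooth_correlation(R)
        smoothed = True
    thresholds = {item: estimate_thresholds(data.values[item]) for item in items}
    return PolychoricResult(
        rho=pd.DataFrame(R, index=items, columns=items),
        thresholds=thresholds,
        smoothed=smoothed,
        pair_diagnostics=pd.DataFrame(
            diag_rows,
            columns=["item_a", "item_b", "converged", "zero_cells_corrected"],
        ),
        n_obs=data.n_persons,
    )


def cross_polychoric(
    external: ItemResponseMatrix,
    original: ItemResponseMatrix,
    *,
    correction: float = ZERO_CELL_CORRECTION,
) -> pd.DataFrame:
    """External x original block of polychoric correlations (for extension)."""
    rows = {}
    Xe = external.values
    Xo = original.values
    for e in external.item_ids:
        row = {}
        for o in original.item_ids:
            table = contingency_table(Xe[e], Xo[o])
            rho, _ = estimate_polychoric_pair(table, correction=correction)
            row[o] = rho
        rows[e] = row
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        external.item_ids, original.item_ids
    ]


@dataclass
class MsaReport:
    """Kaiser-Meyer-Olkin sampling adequacy of a correlation matrix."""

    overall_kmo: float
    per_item_msa: pd.Series
    retained_items: list
    threshold: float


def kmo_msa(R: pd.DataFrame | np.ndarray, threshold: float = 0.7) -> MsaReport:
    """KMO / per-item MSA from raw vs anti-image (partial) correlations.

    ``MSA_j = sum_k r_jk^2 / (sum_k r_jk^2 + sum_k q_jk^2)`` over ``k != j``,
    with ``q`` the partial correlations from the inverse of R; the overall
    KMO pools all pairs.  Items with ``MSA >= threshold`` are retained.
    """
    labels = list(R.columns) if isinstance(R, pd.DataFrame) else list(range(np.asarray(R).shape[0]))
    A = np.asarray(R, dtype=float)
    try:
        inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise ValueError("correlation matrix is singular; smooth it first") from err
    d = np.sqrt(np.diag(inv))
    Q = -inv / np.outer(d, d)
    np.fill_diagonal(Q, 0.0)
    R_off = A - np.diag(np.diag(A))
    r2 = (R_off**2).sum(axis=0)
    q2 = (Q**2).sum(axis=0)
    msa = r2 / (r2 + q2)
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_item = pd.Series(msa, index=labels)
    retained = [lab for lab in labels if per_item[lab] >= threshold]
    return MsaReport(float(overall), per_item, retained, threshold)


class PolychoricCorrelation(BaseEstimator):
    """Polychoric correlation estimator with the sklearn covariance idiom.

    Parameters
    ----------
    correction : float, default 0.1
        Value substituted for zero cells of each pair's contingency table.
    smooth : bool, default True
        Eigenvalue-clip the assembled matrix to PSD when indefinite.

    Attributes (after ``fit``)
    --------------------------
    correlation_ : DataFrame, items x items latent correlation matrix.
    thresholds_ : dict of per-item threshold vectors.
    smoothed_ : bool, whether PSD smoothing was applied.
    result_ : :class:`PolychoricResult` with pair diagnostics.
    """

    def __init__(self, correction: float = ZERO_CELL_CORRECTION, smooth: bool = True):
        self.correction = correction
        self.smooth = smooth

    def fit(self, X, y=None):
        data = X if isinstance(X, ItemResponseMatrix) else _as_response_matrix(X)
        self.result_ = polychoric_matrix(
            data, correction=self.correction, smooth=self.smooth
        )
        self.correlation_ = self.result_.rho
        self.thresholds_ = self.result_.thresholds
        self.smoothed_ = self.result_.smoothed
        self.n_features_in_ = data.n_items
        return self


def _as_response_matrix(X) -> ItemResponseMatrix:
    """Coerce a plain array/DataFrame of codes to an ItemResponseMatrix."""
    df = pd.DataFrame(X)
    counts = df.max(axis=0, skipna=True).astype(int)
    return ItemResponseMatrix(df, counts)
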