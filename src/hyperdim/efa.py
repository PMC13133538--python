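"""Exploratory factor analysis: parallel analysis, principal-axis
factoring, promax rotation, salience mapping and loading-weighted scores.

Principal-axis factoring iterates the eigendecomposition of the reduced
correlation matrix (communalities on the diagonal) from squared-multiple-
correlation starting values.  Promax first applies Kaiser-normalized
varimax, then an oblique least-squares fit to the powered varimax target,
yielding correlated factors.  Factor order and sign are fixed by convention
(columns reflected so the largest-magnitude loading is positive; ordered by
descending structure sum of squares) so solutions reproduce across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import FactorSolution, ItemResponseMatrix, PolychoricResult

SALIENCE_THRESHOLD = 0.32


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------

@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    simulated_eigenvalue_quantiles: np.ndarray
    suggested_n_factors: int
    n_reps: int
    quantile: float


def parallel_analysis(
    R: pd.DataFrame | np.ndarray,
    n_obs: int,
    n_reps: int = 200,
    quantile: float = 0.95,
    seed: int | None = None,
) -> ParallelAnalysisResult:
    """Factor retention by comparison with eigenvalues of structureless data.

    Principal-component eigenvalues of the observed correlation matrix are
    compared to the ``quantile`` of eigenvalues from ``n_reps`` simulated
    standard-normal datasets of identical shape; the suggested count is the
    number of *leading* observed eigenvalues above their simulated quantile
    (stopping at the first failure).
    """
    if n_reps < 20:
        raise ValueError("n_reps < 20 gives unstable eigenvalue quantiles")
    A = np.asarray(R, dtype=float)
    p = A.shape[0]
    obs = np.sort(np.linalg.eigvalsh(A))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_reps, p))
    for r in range(n_reps):
        X = rng.standard_normal((n_obs, p))
        sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(X.T)))[::-1]
    qs = np.quantile(sims, quantile, axis=0)
    k = 0
    while k < p and obs[k] > qs[k]:
        k += 1
    return ParallelAnalysisResult(obs, qs, k, n_reps, quantile)


# ---------------------------------------------------------------------------
# Principal-axis factoring
# ---------------------------------------------------------------------------

def principal_axis_factor(
    R: pd.DataFrame | np.ndarray,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, list]:
    """Iterated principal-axis factoring of a correlation matrix.

    Returns ``(loadings, psi, eigenvalues, converged, heywood_items)`` with
    ``loadings`` the items x k unrotated matrix.  Communalities start at the
    squared multiple correlations ``1 - 1/diag(R^-1)`` and iterate until the
    largest change falls below ``tol``.  Heywood cases (communality > 1) are
    clipped and reported.
    """
    A = np.asarray(R, dtype=float)
    p = A.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"number of factors must be in [1, {p - 1}]")
    try:
        inv = np.linalg.inv(A)
        h2 = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 1.0)
    converged = False
    w = V = None
    for _ in range(max_iter):
        reduced = A.copy()
        np.fill_diagonal(reduced, h2)
        w, V = np.linalg.eigh(reduced)
        w, V = w[::-1], V[:, ::-1]
        lam = V[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))
        h2_new = np.clip((lam**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new
    reduced = A.copy()
    np.fill_diagonal(reduced, h2)
    w, V = np.linalg.eigh(reduced)
    w, V = w[::-1], V[:, ::-1]
    lam = V[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))
    raw_h2 = (lam**2).sum(axis=1)
    heywood = list(np.flatnonzero(raw_h2 > 1.0 + 1e-10))
    psi = np.clip(1.0 - raw_h2, 0.0, 1.0)
    return lam, psi, w, converged, heywood


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def _varimax_criterion(Z: np.ndarray) -> float:
    """Raw varimax objective: summed variance of squared loadings per factor."""
    Z2 = Z**2
    return float(np.sum(Z2.var(axis=0)))


def _varimax_iterate(L: np.ndarray, T0: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    p = L.shape[0]
    T = T0
    d_old = 0.0
    for _ in range(max_iter):
        Z = L @ T
        B = L.T @ (Z**3 - Z * (Z**2).sum(axis=0) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return T


def varimax(L: np.ndarray, normalize: bool = True, max_iter: int = 500,
            tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (with Kaiser row normalization).

    The SVD-based pairwise iteration can stall on saddle points of highly
    symmetric loading patterns, so it is run from the identity plus a few
    deterministic random-orthonormal starts and the solution with the best
    explicit varimax criterion is kept.
    """
    L = np.asarray(L, dtype=float).copy()
    p, k = L.shape
    if normalize:
        norms = np.sqrt((L**2).sum(axis=1))
        norms[norms == 0] = 1.0
        L = L / norms[:, None]
    rng = np.random.default_rng(0)
    starts = [np.eye(k)]
    for _ in range(3):
        Q, _r = np.linalg.qr(rng.standard_normal((k, k)))
        starts.append(Q)
    best_T, best_val = None, -np.inf
    for T0 in starts:
        T = _varimax_iterate(L, T0, max_iter, tol)
        val = _varimax_criterion(L @ T)
        if val > best_val:
            best_val, best_T = val, T
    Lr = L @ best_T
    if normalize:
        Lr = Lr * norms[:, None]
    return Lr, best_T


def _order_and_reflect(pattern: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reflect columns so each factor's largest |loading| is positive, then
    order factors by descending structure sum of squares."""
    signs = np.sign(pattern[np.argmax(np.abs(pattern), axis=0), np.arange(pattern.shape[1])])
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    structure = pattern @ phi
    ss = (structure**2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    return pattern[:, order], phi[np.ix_(order, order)]


def promax_rotate(
    loadings: np.ndarray | pd.DataFrame,
    power: int = 4,
    uniquenesses: np.ndarray | None = None,
    eigenvalues: np.ndarray | None = None,
    n_obs: int = 0,
    item_labels=None,
) -> FactorSolution:
    """Promax oblique rotation of an unrotated loading matrix.

    Kaiser-normalized varimax is applied first; the oblique transform is the
    least-squares fit to the element-wise ``sign * |loading|^power`` target,
    scaled so the implied factor correlation matrix has unit diagonal.
    Falls back to the varimax solution with ``Phi = I`` if the transform is
    singular.
    """
    L = np.asarray(loadings, dtype=float)
    if item_labels is None:
        item_labels = (
            list(loadings.index)
            if isinstance(loadings, pd.DataFrame)
            else list(range(L.shape[0]))
        )
    p, k = L.shape
    if k < 2:
        pattern = L.copy()
        phi = np.eye(1)
        rotation = "none"
    else:
        Lv, _T = varimax(L, normalize=True)
        target = np.sign(Lv) * np.abs(Lv) ** power
        try:
            U = np.linalg.solve(Lv.T @ Lv, Lv.T @ target)
            d = np.diag(np.linalg.inv(U.T @ U))
            U = U * np.sqrt(d)[None, :]
            pattern = Lv @ U
            phi = np.linalg.inv(U.T @ U)
            # clean tiny asymmetries
            phi = (phi + phi.T) / 2.0
            rotation = "promax"
        except np.linalg.LinAlgError:
            pattern, phi, rotation = Lv, np.eye(k), "varimax_fallback"
        pattern, phi = _order_and_reflect(pattern, phi)
    if uniquenesses is None:
        h2 = np.einsum("if,fg,ig->i", pattern, phi, pattern)
        uniquenesses = np.clip(1.0 - h2, 0.0, 1.0)
    if eigenvalues is None:
        eigenvalues = np.sort((L**2).sum(axis=0))[::-1]
    names = [f"F{i + 1}" for i in range(pattern.shape[1])]
    return FactorSolution(
        pattern=pd.DataFrame(pattern, index=item_labels, columns=names),
        phi=pd.DataFrame(phi, index=names, columns=names),
        uniquenesses=pd.Series(np.asarray(uniquenesses, dtype=float), index=item_labels),
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        rotation=rotation,
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def variance_explained(solution: FactorSolution) -> pd.DataFrame:
    """Per-factor and cumulative proportion of item variance explained.

    Under oblique rotation the per-factor contribution is the sum of squared
    *structure* loadings over the item count (this convention is recorded in
    the output); for orthogonal solutions this equals the pattern-based sum.
    """
    structure = solution.structure.to_numpy()
    p = structure.shape[0]
    per = (structure**2).sum(axis=0) / p
    # communality partition: diag(Phi Lambda' Lambda) / p sums to the mean
    # communality, the convention most packages print per factor
    lam = solution.pattern.to_numpy()
    phi = solution.phi.to_numpy()
    part = np.diag(phi @ lam.T @ lam) / p
    out = pd.DataFrame(
        {
            "proportion": per,
            "cumulative": np.cumsum(per),
            "proportion_communality": part,
            "cumulative_communality": np.cumsum(part),
        },
        index=solution.factor_names,
    )
    out.attrs["convention"] = (
        "proportion = structure SS / items; proportion_communality = "
        "diag(Phi L'L) / items (sums to mean communality)"
    )
    return out


def salience_map(solution: FactorSolution, threshold: float = SALIENCE_THRESHOLD) -> dict:
    """Items with |pattern loading| >= threshold, per factor."""
    out = {}
    for fac in solution.factor_names:
        col = solution.pattern[fac]
        sal = col[col.abs() >= threshold]
        out[fac] = list(zip(sal.index, sal.to_numpy()))
    return out


def weighted_factor_scores(
    data: ItemResponseMatrix,
    solution: FactorSolution,
    salience_threshold: float = SALIENCE_THRESHOLD,
) -> pd.DataFrame:
    """Loading-weighted sum scores: responses times pattern loadings.

    All items' loadings contribute.  A person missing any item whose
    |loading| on a factor reaches the salience threshold gets a missing
    score on that factor; missing non-salient items simply drop out of the
    sum.
    """
    if list(data.item_ids) != list(solution.pattern.index):
        raise ValueError("item labels of data and solution do not align")
    X = data.values.to_numpy(dtype=float)
    L = solution.pattern.to_numpy()
    miss = np.isnan(X)
    scores = np.where(miss, 0.0, X) @ L
    salient = np.abs(L) >= salience_threshold
    kill = miss @ salient.astype(float) > 0
    scores[kill] = np.nan
    return pd.DataFrame(
        scores, index=data.values.index, columns=solution.factor_names
    )


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix of Tucker congruence coefficients between loading columns."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = A.T @ B
    den = np.sqrt(np.outer((A**2).sum(axis=0), (B**2).sum(axis=0)))
    return num / den


def match_factors(recovered: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal factor matching by maximal |congruence| assignment.

    Returns ``(permutation, congruences)``: column ``permutation[j]`` of the
    recovered matrix corresponds to truth column ``j``, and ``congruences[j]``
    is the (absolute) Tucker congruence of the matched pair.
    """
    C = tucker_congruence(truth, recovered)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(C.shape[0], dtype=int)
    cong = np.empty(C.shape[0])
    for r, c in zip(rows, cols):
        perm[r] = c
        cong[r] = abs(C[r, c])
    return perm, cong


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class PrincipalAxisFactorAnalysis(BaseEstimator, TransformerMixin):
    """Principal-axis EFA with promax rotation, sklearn style.

    ``fit`` accepts either an :class:`ItemResponseMatrix` / response table
    (with ``corr="pearson"``) or a precomputed correlation matrix
    (``corr="precomputed"`` plus ``n_obs``); ``transform`` returns
    loading-weighted factor scores for response data.

    Attributes (after ``fit``)
    --------------------------
    solution_ : :class:`FactorSolution` (pattern, phi, uniquenesses, ...)
    variance_explained_ : DataFrame of per-factor and cumulative proportions.
    """

    def __init__(
        self,
        n_factors: int = 7,
        rotation: str = "promax",
        power: int = 4,
        corr: str = "pearson",
        max_iter: int = 100,
        tol: float = 1e-6,
    ):
        self.n_factors = n_factors
        self.rotation = rotation
        self.power = power
        self.corr = corr
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None, n_obs: int | None = None):
        if isinstance(X, PolychoricResult):
            R, n_obs = X.rho, X.n_obs
        elif self.corr == "precomputed":
            R = pd.DataFrame(X)
            if n_obs is None:
                raise ValueError("precomputed correlation input requires n_obs")
        else:
            df = X.values if isinstance(X, ItemResponseMatrix) else pd.DataFrame(X)
            R = df.corr()
            n_obs = df.shape[0]
        lam, psi, eig, converged, heywood = principal_axis_factor(
            R, self.n_factors, max_iter=self.max_iter, tol=self.tol
        )
        if self.rotation == "promax" and self.n_factors >= 2:
            sol = promax_rotate(
                lam,
                power=self.power,
                uniquenesses=psi,
                eigenvalues=eig,
                n_obs=int(n_obs),
                item_labels=list(R.columns),
            )
        else:
            names = [f"F{i + 1}" for i in range(self.n_factors)]
            sol = FactorSolution(
                pattern=pd.DataFrame(lam, index=list(R.columns), columns=names),
                phi=pd.DataFrame(np.eye(self.n_factors), index=names, columns=names),
                uniquenesses=pd.Series(psi, index=list(R.columns)),
                eigenvalues=eig,
                rotation="unrotated",
                n_obs=int(n_obs),
            )
        sol.converged = converged
        sol.heywood_items = [list(R.columns)[i] for i in heywood]
        self.solution_ = sol
        self.variance_explained_ = variance_explained(sol)
        self.n_features_in_ = R.shape[0]
        return self

    def transform(self, X):
        data = X if isinstance(X, ItemResponseMatrix) else None
        if data is None:
            from .polychoric import _as_response_matrix

            data = _as_response_matrix(X)
        return weighted_factor_scores(data, self.solution_)
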