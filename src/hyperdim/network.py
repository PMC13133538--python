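"""Regularized partial-correlation networks with EBIC model selection.

The graphical lasso (scikit-learn's coordinate-descent solver) is run over
a descending log-spaced penalty path starting at the smallest penalty that
empties the graph; the Extended Bayesian Information Criterion with
hyperparameter gamma selects the penalty, and edge weights are the
regularized partial correlations ``-omega_ij / sqrt(omega_ii omega_jj)``.
Edge stability is assessed by a nonparametric person-level bootstrap that
refits the whole procedure (including penalty re-selection) per resample
and zeroes edges whose bootstrap interval covers zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso


@dataclass
class PartialCorrelationNetwork:
    nodes: list
    weights: pd.DataFrame              # symmetric, zero diagonal
    precision: np.ndarray
    lambda_selected: float
    ebic_gamma: float
    lambda_path: np.ndarray
    ebic_path: np.ndarray
    n_obs: int
    bootstrap_intervals: pd.DataFrame | None = None   # edge rows: lo, hi, retained
    failures: list = field(default_factory=list)

    @property
    def edge_list(self) -> pd.DataFrame:
        rows = []
        W = self.weights.to_numpy()
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                if W[i, j] != 0.0:
                    rows.append(
                        dict(source=self.nodes[i], target=self.nodes[j], weight=W[i, j])
                    )
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    @property
    def density(self) -> float:
        p = len(self.nodes)
        possible = p * (p - 1) / 2
        return len(self.edge_list) / possible

    def to_graph(self):
        """networkx Graph with nonzero edges (weights as attributes)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edge_list.iterrows():
            g.add_edge(row.source, row.target, weight=float(row.weight))
        return g


def _partial_correlations(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    W = -precision / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def _ebic(precision: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    loglik = (n / 2.0) * (logdet - float(np.sum(S * precision)))
    iu = np.triu_indices(p, 1)
    E = int(np.count_nonzero(precision[iu]))
    return -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def _glasso_path(S, n, gamma, lambdas, tol=1e-3, max_iter=100):
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    best = (np.inf, None, None)
    failures = []
    ebics = np.full(len(lambdas), np.nan)
    for i, lam in enumerate(lambdas):
        try:
            if lam <= 0:
                prec = np.linalg.inv(S)
            else:
                with warnings.catch_warnings():
                    # near-threshold dual gaps at small penalties are benign
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    _cov, prec = graphical_lasso(S, lam, tol=tol, max_iter=max_iter)
        except (FloatingPointError, np.linalg.LinAlgError) as err:
            failures.append((float(lam), str(err)))
            continue
        e = _ebic(prec, S, n, gamma)
        ebics[i] = e
        if e < best[0]:
            best = (e, lam, prec)
    if best[2] is None:
        raise RuntimeError("graphical lasso failed at every penalty")
    return best, ebics, failures


def _prepare(data, nodes=None):
    df = pd.DataFrame(data)
    if nodes is not None:
        df = df.loc[:, list(nodes)]
    df = df.dropna(axis=0)  # listwise for the network point estimate
    return df


def ebic_glasso_network(
    data: pd.DataFrame,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    nodes=None,
) -> PartialCorrelationNetwork:
    """Estimate the EBIC-selected partial-correlation network of ``data``.

    Input correlations are Pearson correlations of the observed columns;
    the penalty path runs from ``lambda_max`` (smallest penalty with an
    empty graph: the largest absolute off-diagonal correlation) down to
    ``lambda_max * lambda_min_ratio`` in ``n_lambdas`` log-spaced steps.
    """
    df = _prepare(data, nodes)
    n, p = df.shape
    if n < 3 * p:
        import warnings

        warnings.warn(
            f"only {n} complete rows for {p} nodes; estimates may be unstable",
            stacklevel=2,
        )
    S = np.corrcoef(df.to_numpy().T)
    lam_max = np.abs(S - np.eye(p)).max()
    lambdas = np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas
    )
    (ebic_best, lam_best, prec), ebics, failures = _glasso_path(
        S, n, gamma, lambdas
    )
    W = _partial_correlations(prec)
    node_labels = list(df.columns)
    return PartialCorrelationNetwork(
        nodes=node_labels,
        weights=pd.DataFrame(W, index=node_labels, columns=node_labels),
        precision=prec,
        lambda_selected=float(lam_best),
        ebic_gamma=gamma,
        lambda_path=lambdas,
        ebic_path=ebics,
        n_obs=n,
        failures=failures,
    )


def bootstrap_threshold(
    data: pd.DataFrame,
    network: PartialCorrelationNetwork | None = None,
    n_boot: int = 2000,
    level: float = 0.05,
    seed: int | None = None,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    nodes=None,
) -> PartialCorrelationNetwork:
    """Bootstrap edge stability and zero unstable edges.

    Persons are resampled with replacement ``n_boot`` times; the full
    estimator (penalty path and EBIC re-selection included) is refit per
    resample.  An edge is retained when its ``(level/2, 1 - level/2)``
    bootstrap quantile interval excludes zero; all other edges are set to
    zero in the returned network.
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unusable quantile intervals")
    df = _prepare(data, nodes)
    if network is None:
        network = ebic_glasso_network(
            df, gamma=gamma, n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio
        )
    n, p = df.shape
    X = df.to_numpy()
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, 1)
    boots = np.empty((n_boot, iu[0].size))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb = X[idx]
        sd = Xb.std(axis=0)
        if np.any(sd == 0):  # degenerate resample: record as all-zero graph
            boots[b] = 0.0
            continue
        Sb = np.corrcoef(Xb.T)
        lam_max = np.abs(Sb - np.eye(p)).max()
        lambdas = np.logspace(
            np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas
        )
        try:
            (_e, _lam, prec), _ebics, _fail = _glasso_path(Sb, n, gamma, lambdas)
            boots[b] = _partial_correlations(prec)[iu]
        except RuntimeError:
            boots[b] = np.nan
    lo = np.nanquantile(boots, level / 2.0, axis=0)
    hi = np.nanquantile(boots, 1.0 - level / 2.0, axis=0)
    retained = (lo > 0) | (hi < 0)

    W = network.weights.to_numpy().copy()
    keep = np.zeros_like(W, dtype=bool)
    keep[iu] = retained
    keep = keep | keep.T
    W[~keep] = 0.0
    intervals = pd.DataFrame(
        {
            "source": [network.nodes[i] for i in iu[0]],
            "target": [network.nodes[j] for j in iu[1]],
            "estimate": network.weights.to_numpy()[iu],
            "lo": lo,
            "hi": hi,
            "retained": retained,
        }
    )
    return PartialCorrelationNetwork(
        nodes=network.nodes,
        weights=pd.DataFrame(W, index=network.nodes, columns=network.nodes),
        precision=network.precision,
        lambda_selected=network.lambda_selected,
        ebic_gamma=network.ebic_gamma,
        lambda_path=network.lambda_path,
        ebic_path=network.ebic_path,
        n_obs=network.n_obs,
        bootstrap_intervals=intervals,
        failures=network.failures,
    )


class EBICGlassoNetwork(BaseEstimator):
    """EBIC-selected graphical-lasso network, sklearn covariance style.

    Attributes (after ``fit``)
    --------------------------
    precision_ : selected precision matrix.
    partial_correlations_ : DataFrame of regularized partial correlations.
    alpha_ : selected penalty (the EBIC-optimal lambda).
    network_ : full :class:`PartialCorrelationNetwork` result.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        n_boot: int = 0,
        level: float = 0.05,
        seed: int | None = None,
    ):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.n_boot = n_boot
        self.level = level
        self.seed = seed

    def fit(self, X, y=None):
        net = ebic_glasso_network(
            X,
            gamma=self.gamma,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
        )
        if self.n_boot:
            net = bootstrap_threshold(
                X,
                net,
                n_boot=self.n_boot,
                level=self.level,
                seed=self.seed,
                gamma=self.gamma,
                n_lambdas=self.n_lambdas,
                lambda_min_ratio=self.lambda_min_ratio,
            )
        self.network_ = net
        self.precision_ = net.precision
        self.partial_correlations_ = net.weights
        self.alpha_ = net.lambda_selected
        self.n_features_in_ = len(net.nodes)
        return self
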