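"""Shared fixtures: one study-like synthetic cohort and its polychoric/EFA
products are computed once per session, since several suites exercise
different stages of the same flow."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from scipy.special import owens_t

from hyperdim.efa import PrincipalAxisFactorAnalysis
from hyperdim.polychoric import polychoric_matrix
from hyperdim.simulate import generate_battery, preset_study_like


# ---------------------------------------------------------------------------
# Independent bivariate-normal CDF oracle (Owen's T construction) used by
# the polychoric likelihood grid-search oracles; shares no code with the
# package's quadrature implementation.
# ---------------------------------------------------------------------------

def bvn_cdf_owen(h, k, r):
    h = np.where(np.asarray(h, float) == 0, 1e-13, np.asarray(h, float))
    k = np.where(np.asarray(k, float) == 0, 1e-13, np.asarray(k, float))
    s = np.sqrt(1.0 - r * r)
    ah = (k - r * h) / (h * s)
    ak = (h - r * k) / (k * s)
    delta = np.where((h * k > 0) | ((h * k == 0) & (h + k >= 0)), 0.0, 0.5)
    return (
        0.5 * (norm.cdf(h) + norm.cdf(k))
        - owens_t(h, ah)
        - owens_t(k, ak)
        - delta
    )


def grid_search_polychoric(table, step=0.001, correction=0.1):
    """Reference estimator: exhaustive likelihood grid search over rho."""
    table = np.asarray(table, dtype=float)
    table = np.where(table == 0, correction, table)
    n = table.sum()
    tr = norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    tc = norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)
    a = np.concatenate(([-30.0], tr, [30.0]))
    b = np.concatenate(([-30.0], tc, [30.0]))
    grid = np.arange(-0.99, 0.99 + step / 2, step)
    best_r, best_ll = 0.0, -np.inf
    for r in grid:
        F = bvn_cdf_owen(a[:, None], b[None, :], r)
        P = np.clip(F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1], 1e-300, None)
        ll = float(np.sum(table * np.log(P)))
        if ll > best_ll:
            best_ll, best_r = ll, r
    return best_r


@pytest.fixture(scope="session")
def owen_oracle():
    return grid_search_polychoric


@pytest.fixture(scope="session")
def preset_cfg():
    return preset_study_like(seed=20260924)


@pytest.fixture(scope="session")
def preset_data(preset_cfg):
    return generate_battery(preset_cfg)


@pytest.fixture(scope="session")
def preset_polychoric(preset_data):
    return polychoric_matrix(preset_data.responses)


@pytest.fixture(scope="session")
def preset_solution(preset_polychoric):
    model = PrincipalAxisFactorAnalysis(n_factors=7, corr="precomputed").fit(
        preset_polychoric.rho, n_obs=preset_polychoric.n_obs
    )
    return model.solution_


def make_ordinal(rng, loadings, phi, n, thresholds):
    """Small helper: draw ordinal data from an explicit factor model."""
    lam = np.asarray(loadings, float)
    phi = np.asarray(phi, float)
    k = phi.shape[0]
    f = rng.standard_normal((n, k)) @ np.linalg.cholesky(phi).T
    h2 = np.einsum("if,fg,ig->i", lam, phi, lam)
    y = f @ lam.T + rng.standard_normal((n, lam.shape[0])) * np.sqrt(1 - h2)
    return np.digitize(y, thresholds) + 1.0, f
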