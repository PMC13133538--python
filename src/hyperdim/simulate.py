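"""Synthetic ordinal questionnaire batteries with known factor structure.

The generator draws latent factor scores ``f ~ MVN(0, Phi)``, forms
continuous item variables ``y = Lambda f + eps`` with uniquenesses chosen so
every item has unit total variance, and discretizes each item at its
threshold vector on the standard-normal scale.  Disorder severity outcomes
are linear in the factors plus normal noise, then affinely mapped onto each
screener's reported scale.  Age and sex covariates and MCAR missingness
complete the emulated cohort.  Everything is reproducible from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import ItemResponseMatrix

FACTOR_NAMES = [
    "anxious",
    "somatic",
    "sensitive",
    "sleep",
    "irritable",
    "vigilant",
    "sudomotor",
]
SEVERITY_NAMES = ["ID", "MDD", "GAD", "SAD", "PD", "PTSD", "ADHD"]

# Screener calibration: (mean, sd) of each severity scale in the emulated
# cohort, and the scale's theoretical maximum (minimum 0 throughout).
SEVERITY_SCALE = {
    "ID": (12.99, 7.04, 28.0),    # Insomnia Severity Index
    "MDD": (8.27, 4.12, 20.0),    # RMT20 depression subscale
    "GAD": (9.78, 4.26, 20.0),
    "SAD": (8.17, 4.07, 20.0),
    "PD": (5.31, 2.49, 20.0),
    "PTSD": (6.48, 4.16, 20.0),
    "ADHD": (2.26, 1.77, 6.0),   # 6-item adult ADHD self-report screener
}


@dataclass
class CovariateSpec:
    """Age (normal, truncated to a plausible adult range) and sex (Bernoulli)."""

    age_mean: float = 58.3
    age_sd: float = 13.8
    age_range: tuple[float, float] = (18.0, 90.0)
    female_prevalence: float = 0.776


@dataclass
class GeneratorConfig:
    """Full parameter set of the latent-factor battery generator."""

    n_persons: int
    loading_matrix: pd.DataFrame          # items x factors, Lambda_true
    factor_correlations: pd.DataFrame     # factors x factors, Phi_true
    item_category_counts: pd.Series       # per item, in {2, 4, 5}
    item_thresholds: dict                 # item -> ordered cut points
    severity_betas: pd.DataFrame          # outcomes x factors, B_true
    severity_noise_sd: pd.Series          # per outcome
    missing_rate: float = 0.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    seed: int = 0
    # optional external (indicator-source) item block driven by the same factors
    external_loading_matrix: pd.DataFrame | None = None
    external_category_counts: pd.Series | None = None
    external_thresholds: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        phi = np.asarray(self.factor_correlations, dtype=float)
        if not np.allclose(phi, phi.T, atol=1e-12):
            raise ValueError("factor correlation matrix must be symmetric")
        if not np.allclose(np.diag(phi), 1.0, atol=1e-12):
            raise ValueError("factor correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 1e-10:
            raise ValueError("factor correlation matrix must be positive definite")
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        psi = self.uniquenesses()
        if (psi < 0).any():
            bad = psi.index[psi < 0][0]
            raise ValueError(
                f"loadings imply negative uniqueness for item {bad!r}; "
                "communality exceeds 1"
            )
        self._check_thresholds(
            self.item_thresholds, self.item_category_counts, "item"
        )
        if self.external_loading_matrix is not None:
            self._check_thresholds(
                self.external_thresholds, self.external_category_counts, "external item"
            )

    @staticmethod
    def _check_thresholds(thresholds, counts, what: str) -> None:
        for item, cats in counts.items():
            tau = np.asarray(thresholds[item], dtype=float)
            if len(tau) != cats - 1:
                raise ValueError(
                    f"{what} {item!r}: {len(tau)} thresholds for {cats} categories"
                )
            if np.any(np.diff(tau) <= 0):
                raise ValueError(f"{what} {item!r}: thresholds not strictly increasing")

    # -- model-implied quantities ------------------------------------------
    def uniquenesses(self) -> pd.Series:
        lam = self.loading_matrix.to_numpy(dtype=float)
        phi = self.factor_correlations.to_numpy(dtype=float)
        h2 = np.einsum("if,fg,ig->i", lam, phi, lam)
        return pd.Series(1.0 - h2, index=self.loading_matrix.index)

    def implied_item_correlations(self) -> pd.DataFrame:
        """Model-implied latent correlation matrix Lambda Phi Lambda' + diag psi."""
        lam = self.loading_matrix.to_numpy(dtype=float)
        phi = self.factor_correlations.to_numpy(dtype=float)
        R = lam @ phi @ lam.T
        np.fill_diagonal(R, 1.0)
        items = self.loading_matrix.index
        return pd.DataFrame(R, index=items, columns=items)

    def severity_signal_sd(self) -> pd.Series:
        """SD of B f + noise per outcome (the standardization denominator)."""
        B = self.severity_betas.to_numpy(dtype=float)
        phi = self.factor_correlations.to_numpy(dtype=float)
        var = np.einsum("of,fg,og->o", B, phi, B) + self.severity_noise_sd.to_numpy() ** 2
        return pd.Series(np.sqrt(var), index=self.severity_betas.index)

    def standardized_severity_betas(self) -> pd.DataFrame:
        """Population standardized coefficients of each factor per outcome."""
        sd = self.severity_signal_sd()
        return self.severity_betas.div(sd, axis=0)

    def severity_r_squared(self) -> pd.Series:
        """Population R^2 of each severity outcome on the true factors."""
        sd2 = self.severity_signal_sd() ** 2
        noise2 = self.severity_noise_sd**2
        return (sd2 - noise2) / sd2


@dataclass
class BatteryData:
    """One generated cohort: responses, ground truth and side tables."""

    responses: ItemResponseMatrix
    factors: pd.DataFrame          # true latent factor scores
    severities: pd.DataFrame
    covariates: pd.DataFrame       # age, sex (1 = female), education, income
    config: GeneratorConfig
    external_responses: ItemResponseMatrix | None = None


def _discretize(latent: np.ndarray, thresholds: dict, items) -> np.ndarray:
    codes = np.empty_like(latent)
    for j, item in enumerate(items):
        tau = np.asarray(thresholds[item], dtype=float)
        codes[:, j] = np.searchsorted(tau, latent[:, j]) + 1
    return codes


def generate_battery(config: GeneratorConfig) -> BatteryData:
    """Draw one cohort from the generator's latent factor model."""
    n = config.n_persons
    items = list(config.loading_matrix.index)
    lam = config.loading_matrix.to_numpy(dtype=float)
    phi = config.factor_correlations.to_numpy(dtype=float)
    psi = config.uniquenesses().to_numpy()

    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_latent = np.random.default_rng(streams[0])
    rng_missing = np.random.default_rng(streams[1])
    rng_sever = np.random.default_rng(streams[2])
    rng_cov = np.random.default_rng(streams[3])
    rng_ext = np.random.default_rng(streams[4])

    L = np.linalg.cholesky(phi)
    f = rng_latent.standard_normal((n, phi.shape[0])) @ L.T
    eps = rng_latent.standard_normal((n, len(items))) * np.sqrt(psi)
    latent = f @ lam.T + eps
    codes = _discretize(latent, config.item_thresholds, items)

    if config.missing_rate > 0:
        mask = rng_missing.random(codes.shape) < config.missing_rate
        codes = np.where(mask, np.nan, codes)

    persons = pd.RangeIndex(n, name="person")
    responses = ItemResponseMatrix(
        pd.DataFrame(codes, index=persons, columns=items),
        config.item_category_counts,
    )

    factors = pd.DataFrame(f, index=persons, columns=config.factor_correlations.index)

    B = config.severity_betas.to_numpy(dtype=float)
    noise = rng_sever.standard_normal((n, B.shape[0])) * config.severity_noise_sd.to_numpy()
    raw = f @ B.T + noise
    sd = config.severity_signal_sd().to_numpy()
    sever = np.empty_like(raw)
    for o, name in enumerate(config.severity_betas.index):
        mean, scale_sd, _mx = SEVERITY_SCALE.get(name, (0.0, 1.0, np.inf))
        sever[:, o] = mean + scale_sd * raw[:, o] / sd[o]
    severities = pd.DataFrame(sever, index=persons, columns=config.severity_betas.index)

    cov = config.covariate_spec
    age = rng_cov.normal(cov.age_mean, cov.age_sd, n)
    lo, hi = cov.age_range
    for _ in range(64):  # redraw out-of-range ages (truncated normal)
        out = (age < lo) | (age > hi)
        if not out.any():
            break
        age[out] = rng_cov.normal(cov.age_mean, cov.age_sd, out.sum())
    age = np.clip(age, lo, hi)
    sex = (rng_cov.random(n) < cov.female_prevalence).astype(int)
    education = np.clip(rng_cov.normal(10.7, 3.6, n), 0, 25)
    income = rng_cov.integers(1, 8, n)  # 7 ordinal income categories
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "education_years": education, "income": income},
        index=persons,
    )

    external = None
    if config.external_loading_matrix is not None:
        lam_e = config.external_loading_matrix.to_numpy(dtype=float)
        h2_e = np.einsum("if,fg,ig->i", lam_e, phi, lam_e)
        if (h2_e > 1).any():
            raise ValueError("external loadings imply communality > 1")
        eps_e = rng_ext.standard_normal((n, lam_e.shape[0])) * np.sqrt(1.0 - h2_e)
        latent_e = f @ lam_e.T + eps_e
        ext_items = list(config.external_loading_matrix.index)
        codes_e = _discretize(latent_e, config.external_thresholds, ext_items)
        external = ItemResponseMatrix(
            pd.DataFrame(codes_e, index=persons, columns=ext_items),
            config.external_category_counts,
        )

    return BatteryData(responses, factors, severities, covariates, config, external)


# ---------------------------------------------------------------------------
# Frozen presets
# ---------------------------------------------------------------------------

# Factor correlations of the study-like preset: moderate, median 0.40,
# spanning 0.14 (vigilant-sudomotor) to 0.57 (somatic-sudomotor).
_PRESET_PHI_UPPER = {
    ("anxious", "somatic"): 0.45,
    ("anxious", "sensitive"): 0.50,
    ("anxious", "sleep"): 0.42,
    ("anxious", "irritable"): 0.40,
    ("anxious", "vigilant"): 0.38,
    ("anxious", "sudomotor"): 0.30,
    ("somatic", "sensitive"): 0.42,
    ("somatic", "sleep"): 0.40,
    ("somatic", "irritable"): 0.28,
    ("somatic", "vigilant"): 0.25,
    ("somatic", "sudomotor"): 0.57,
    ("sensitive", "sleep"): 0.41,
    ("sensitive", "irritable"): 0.44,
    ("sensitive", "vigilant"): 0.40,
    ("sensitive", "sudomotor"): 0.22,
    ("sleep", "irritable"): 0.40,
    ("sleep", "vigilant"): 0.20,
    ("sleep", "sudomotor"): 0.18,
    ("irritable", "vigilant"): 0.26,
    ("irritable", "sudomotor"): 0.16,
    ("vigilant", "sudomotor"): 0.14,
}

# 2-5 marker items per factor: five factors with 4, somatic with 5,
# vigilant with 2 (27 markers total), plus 3 moderately loading
# "distractor" items per factor.
MARKER_COUNTS = {
    "anxious": 4,
    "somatic": 5,
    "sensitive": 4,
    "sleep": 4,
    "irritable": 4,
    "vigilant": 2,
    "sudomotor": 4,
}

_THRESHOLDS_BY_CATS = {
    2: np.array([0.5244]),                       # ~70/30 split
    4: np.array([-0.2533, 0.5244, 1.2816]),      # 40/30/20/10
    5: np.array([-0.3853, 0.2533, 0.8416, 1.4051]),  # 35/25/20/12/8
}


def preset_phi() -> pd.DataFrame:
    phi = pd.DataFrame(
        np.eye(7), index=FACTOR_NAMES, columns=FACTOR_NAMES, dtype=float
    )
    for (a, b), v in _PRESET_PHI_UPPER.items():
        phi.loc[a, b] = phi.loc[b, a] = v
    return phi


def _jitter(tau: np.ndarray, idx: int) -> np.ndarray:
    """Small deterministic per-item shift so margins are not all identical."""
    return tau + 0.06 * ((idx % 3) - 1)


def preset_severity_betas() -> pd.DataFrame:
    """Outcome-by-factor effects echoing the reported regression profiles."""
    B = pd.DataFrame(
        0.0, index=SEVERITY_NAMES, columns=FACTOR_NAMES, dtype=float
    )
    B.loc["ID", ["somatic", "sleep", "irritable"]] = [0.08, 0.70, 0.09]
    B.loc["MDD", ["anxious", "somatic", "sensitive", "sleep", "irritable"]] = [
        0.43, 0.10, -0.10, 0.20, 0.19,
    ]
    B.loc["GAD", ["anxious", "somatic", "sleep", "irritable"]] = [0.51, 0.12, 0.23, 0.10]
    B.loc["SAD", ["anxious", "somatic", "sensitive", "sleep", "irritable", "vigilant"]] = [
        0.32, 0.09, 0.18, 0.11, 0.10, 0.20,
    ]
    B.loc["PD", ["anxious", "somatic", "vigilant"]] = [0.37, 0.22, 0.19]
    B.loc["PTSD", ["anxious", "somatic", "vigilant", "sudomotor"]] = [
        0.31, 0.10, 0.25, 0.12,
    ]
    B.loc["ADHD", ["anxious", "sleep", "irritable"]] = [0.25, 0.14, 0.14]
    return B


def _preset_battery_loadings() -> tuple[pd.DataFrame, pd.Series, dict]:
    rows = {}
    counts = {}
    thresholds = {}
    idx = 0
    for f, fname in enumerate(FACTOR_NAMES):
        # six non-marker items per factor approximate the analyzed battery's
        # item density; dichotomous items are ~5% of it, mirrored here
        distractor_cats = (
            [2, 4, 5, 4, 5, 5] if fname in ("anxious", "somatic", "sleep")
            else [4, 5, 5, 4, 5, 5]
        )
        for m in range(MARKER_COUNTS[fname]):
            item = f"{fname}_m{m + 1}"
            lam = np.zeros(7)
            # heterogeneous marker strengths, as in real batteries
            lam[f] = 0.80 - 0.04 * m
            rows[item] = lam
            counts[item] = 5
            thresholds[item] = _jitter(_THRESHOLDS_BY_CATS[5], idx)
            idx += 1
        for d in range(6):
            item = f"{fname}_d{d + 1}"
            lam = np.zeros(7)
            lam[f] = (0.60, 0.55, 0.50)[d % 3]
            lam[(f + 1) % 7] = 0.15
            rows[item] = lam
            cats = distractor_cats[d]
            counts[item] = cats
            thresholds[item] = _jitter(_THRESHOLDS_BY_CATS[cats], idx)
            idx += 1
    loadings = pd.DataFrame.from_dict(rows, orient="index", columns=FACTOR_NAMES)
    return loadings, pd.Series(counts), thresholds


def _preset_external() -> tuple[pd.DataFrame, pd.Series, dict]:
    """22 external indicator-source items: 8 anxious, 5 irritable, 4 sleep
    qualifying items plus 5 that the selection rule must reject."""
    rows = {}
    idx = 100
    for fname, n_items in [("anxious", 8), ("irritable", 5), ("sleep", 4)]:
        f = FACTOR_NAMES.index(fname)
        for m in range(n_items):
            lam = np.zeros(7)
            lam[f] = 0.70
            rows[f"ext_{fname}_{m + 1}"] = lam
    # cross-loaded items: high on two factors -> rejected by the cross rule
    for pair in [("somatic", "sudomotor"), ("anxious", "sensitive")]:
        lam = np.zeros(7)
        lam[FACTOR_NAMES.index(pair[0])] = 0.45
        lam[FACTOR_NAMES.index(pair[1])] = 0.40
        rows[f"ext_cross_{pair[0]}_{pair[1]}"] = lam
    # weak items: primary below the 0.45 rule
    for fname in ["somatic", "sensitive", "vigilant"]:
        lam = np.zeros(7)
        lam[FACTOR_NAMES.index(fname)] = 0.30
        rows[f"ext_weak_{fname}"] = lam
    loadings = pd.DataFrame.from_dict(rows, orient="index", columns=FACTOR_NAMES)
    counts = pd.Series(4, index=loadings.index)
    thresholds = {
        item: _jitter(_THRESHOLDS_BY_CATS[4], idx + i)
        for i, item in enumerate(loadings.index)
    }
    return loadings, counts, thresholds


def preset_study_like(seed: int = 0) -> GeneratorConfig:
    """Frozen study-like configuration: 7 correlated factors, n = 467,
    27 marker items plus 21 distractors, 22 external indicator-source items,
    screener-calibrated severities and sporadic missingness."""
    loadings, counts, thresholds = _preset_battery_loadings()
    ext_load, ext_counts, ext_thresh = _preset_external()
    B = preset_severity_betas()
    phi = preset_phi()
    # noise chosen for population R^2 = 0.55 of every severity on the factors
    var_signal = pd.Series(
        np.einsum("of,fg,og->o", B.to_numpy(), phi.to_numpy(), B.to_numpy()),
        index=B.index,
    )
    noise_sd = np.sqrt(var_signal * (1 - 0.55) / 0.55)
    return GeneratorConfig(
        n_persons=467,
        loading_matrix=loadings,
        factor_correlations=phi,
        item_category_counts=counts,
        item_thresholds=thresholds,
        severity_betas=B,
        severity_noise_sd=noise_sd,
        missing_rate=0.0006,
        covariate_spec=CovariateSpec(),
        seed=seed,
        external_loading_matrix=ext_load,
        external_category_counts=ext_counts,
        external_thresholds=ext_thresh,
    )


def preset_full_battery(seed: int = 0) -> GeneratorConfig:
    """Frozen configuration mirroring the full 221-item battery:
    12 dichotomous, 91 four-level and 118 five-level items on 7 factors."""
    cats = [2] * 12 + [4] * 91 + [5] * 118
    rows = {}
    counts = {}
    thresholds = {}
    for i, c in enumerate(cats):
        item = f"item_{i + 1:03d}"
        f = i % 7
        lam = np.zeros(7)
        lam[f] = 0.60
        rows[item] = lam
        counts[item] = c
        thresholds[item] = _jitter(_THRESHOLDS_BY_CATS[c], i)
    loadings = pd.DataFrame.from_dict(rows, orient="index", columns=FACTOR_NAMES)
    B = preset_severity_betas()
    phi = preset_phi()
    var_signal = pd.Series(
        np.einsum("of,fg,og->o", B.to_numpy(), phi.to_numpy(), B.to_numpy()),
        index=B.index,
    )
    noise_sd = np.sqrt(var_signal * (1 - 0.55) / 0.55)
    return GeneratorConfig(
        n_persons=467,
        loading_matrix=loadings,
        factor_correlations=phi,
        item_category_counts=pd.Series(counts),
        item_thresholds=thresholds,
        severity_betas=B,
        severity_noise_sd=noise_sd,
        missing_rate=0.0006,
        seed=seed,
    )


def write_battery(data: BatteryData, out_dir: str | Path) -> dict:
    """Write responses, severities, covariates as CSV and the ground-truth
    parameter set as a JSON sidecar; returns the path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    data.responses.values.to_csv(out / "responses.csv")
    paths["responses"] = "responses.csv"
    data.severities.to_csv(out / "severities.csv")
    paths["severities"] = "severities.csv"
    data.covariates.to_csv(out / "covariates.csv")
    paths["covariates"] = "covariates.csv"
    data.factors.to_csv(out / "true_factors.csv")
    paths["true_factors"] = "true_factors.csv"
    meta = {
        "category_counts": data.responses.category_counts.to_dict(),
    }
    (out / "item_metadata.json").write_text(json.dumps(meta, indent=2))
    paths["item_metadata"] = "item_metadata.json"
    if data.external_responses is not None:
        data.external_responses.values.to_csv(out / "external_responses.csv")
        paths["external_responses"] = "external_responses.csv"
        meta_e = {
            "category_counts": data.external_responses.category_counts.to_dict()
        }
        (out / "external_metadata.json").write_text(json.dumps(meta_e, indent=2))
        paths["external_metadata"] = "external_metadata.json"
    cfg = data.config
    truth = {
        "seed": cfg.seed,
        "n_persons": cfg.n_persons,
        "loading_matrix": cfg.loading_matrix.to_dict(),
        "factor_correlations": cfg.factor_correlations.to_dict(),
        "severity_betas": cfg.severity_betas.to_dict(),
        "severity_noise_sd": cfg.severity_noise_sd.to_dict(),
        "item_thresholds": {k: list(map(float, v)) for k, v in cfg.item_thresholds.items()},
        "missing_rate": cfg.missing_rate,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    paths["ground_truth"] = "ground_truth.json"
    return paths
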