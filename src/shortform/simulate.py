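"""Synthetic two-wave, two-group ordinal questionnaire data.

The generator emulates a 14-item perceived-stress questionnaire with two
correlated factors (helplessness and self-efficacy, 7 items each), a retest
wave with latent first-order autoregression, a binary group split for
invariance studies, and continuous covariates calibrated in closed form to
target correlations with the stress-keyed total score.

The population truth is a standard ordinal factor model: latent responses
y* = Lambda eta + epsilon with standardized loadings, discretized at ordered
thresholds into five categories coded 0-4.  All implied moments of the
ordinal codes (variances, covariances, sum-score correlations) are available
in closed form via numeric integration, which is what the covariate
calibration and the test oracles use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._bvnorm import ordinal_cov, ordinal_latent_slope, ordinal_var

__all__ = [
    "CovariateSpec",
    "GroupDeltas",
    "PopulationModel",
    "SimConfig",
    "build_population_model",
    "generate",
    "verify_targets",
    "pss14_model",
    "marker_model",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = np.array([-1.2, -0.4, 0.4, 1.2])

# Calibration targets for covariates of the default stress models, signed
# consistently with a stress-keyed total (higher = more stress): mental
# health problems correlate positively, stressor recovery ability and
# self-efficacy negatively.
DEFAULT_COVARIATE_TARGETS = {
    "mental_health": 0.59,
    "stressor_recovery": -0.53,
    "self_efficacy_cov": -0.44,
}


@dataclass
class CovariateSpec:
    name: str
    target_r: float                      # with the named sum score
    score: str = "total"
    weights: np.ndarray | None = None    # solved during build
    noise_sd: float | None = None


@dataclass
class GroupDeltas:
    """Additive offsets applied to the second group (non-invariance)."""

    loading: dict[str, float] = field(default_factory=dict)
    threshold: dict[str, float] = field(default_factory=dict)


@dataclass
class PopulationModel:
    items: list[str]
    factors: list[str]
    loading_matrix: np.ndarray           # items x factors, simple structure
    factor_corr: np.ndarray
    thresholds: np.ndarray               # items x (categories-1)
    general_loadings: np.ndarray | None = None
    retest_stability: np.ndarray | None = None
    group_deltas: GroupDeltas | None = None
    covariates: list[CovariateSpec] = field(default_factory=list)
    reverse_items: tuple[str, ...] = ()

    # -- validation ---------------------------------------------------------

    def __post_init__(self):
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        p, k = self.loading_matrix.shape
        if p != len(self.items) or k != len(self.factors):
            raise ValueError("loading matrix shape does not match item/factor names")
        if np.any(np.abs(self.loading_matrix) > 1):
            raise ValueError("standardized loadings must lie in [-1, 1]")
        if not np.allclose(self.factor_corr, self.factor_corr.T):
            raise ValueError("factor correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.factor_corr), 1.0):
            raise ValueError("factor correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.factor_corr).min() <= 1e-10:
            raise ValueError("factor correlation matrix must be positive definite")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if self.general_loadings is not None:
            self.general_loadings = np.asarray(self.general_loadings, dtype=float)
        if self.retest_stability is None:
            self.retest_stability = np.full(k, 0.85)
        self.retest_stability = np.asarray(self.retest_stability, dtype=float)
        if np.any((self.retest_stability < 0) | (self.retest_stability > 1)):
            raise ValueError("retest stability must lie in [0, 1]")
        if np.any(self.communalities() > 1 + 1e-10):
            raise ValueError("item communality exceeds 1; reduce loadings")
        evals = np.linalg.eigvalsh(self.implied_latent_corr())
        if evals.min() < -1e-8:
            raise ValueError("implied latent correlation matrix is not PSD")

    # -- implied moments ----------------------------------------------------

    def communalities(self) -> np.ndarray:
        h = np.einsum("ip,pq,iq->i", self.loading_matrix, self.factor_corr,
                      self.loading_matrix)
        if self.general_loadings is not None:
            h = h + self.general_loadings**2
        return h

    def implied_latent_corr(self) -> np.ndarray:
        """Correlation matrix of the latent item responses y*."""
        r = self.loading_matrix @ self.factor_corr @ self.loading_matrix.T
        if self.general_loadings is not None:
            r = r + np.outer(self.general_loadings, self.general_loadings)
        np.fill_diagonal(r, 1.0)
        return r

    def implied_ordinal_cov(self) -> np.ndarray:
        """Covariance matrix of the discretized 0..C codes (closed form)."""
        r = self.implied_latent_corr()
        p = len(self.items)
        cov = np.zeros((p, p))
        for i in range(p):
            cov[i, i] = ordinal_var(self.thresholds[i])
            for j in range(i + 1, p):
                cov[i, j] = cov[j, i] = ordinal_cov(
                    self.thresholds[i], self.thresholds[j], r[i, j])
        return cov

    def _score_signs(self, items: list[str] | None = None) -> np.ndarray:
        items = items or self.items
        return np.array([-1.0 if it in self.reverse_items else 1.0 for it in items])

    def implied_sum_score_corr(self, items_a: list[str], items_b: list[str],
                               signed: bool = False) -> float:
        """Model-implied correlation of two (optionally reverse-keyed) sums."""
        cov = self.implied_ordinal_cov()
        ia = [self.items.index(i) for i in items_a]
        ib = [self.items.index(i) for i in items_b]
        sa = self._score_signs(items_a) if signed else np.ones(len(ia))
        sb = self._score_signs(items_b) if signed else np.ones(len(ib))
        c = sa @ cov[np.ix_(ia, ib)] @ sb
        va = sa @ cov[np.ix_(ia, ia)] @ sa
        vb = sb @ cov[np.ix_(ib, ib)] @ sb
        return float(c / np.sqrt(va * vb))

    # -- covariate calibration ---------------------------------------------

    def calibrate_covariates(self) -> None:
        """Solve covariate factor weights for the target total-score correlations.

        The covariate is w' eta + noise with unit total variance.  Using the
        attenuation slope a_i = sum_c phi(tau_ic) (covariance of code i with
        its latent response), cov(covariate, total) = w' c with
        c_p = sum_i s_i a_i (Lambda Phi)_ip, and the closed-form ordinal
        variance of the total gives the exact implied correlation.  Weights
        point along the canonical direction Phi^-1 c.
        """
        if not self.covariates:
            return
        signs = self._score_signs()
        slopes = np.array([ordinal_latent_slope(t) for t in self.thresholds])
        lam_phi = self.loading_matrix @ self.factor_corr
        c = (signs * slopes) @ lam_phi
        cov = self.implied_ordinal_cov()
        var_total = signs @ cov @ signs
        q = float(c @ np.linalg.solve(self.factor_corr, c))
        for spec in self.covariates:
            k = spec.target_r * np.sqrt(var_total) / q
            if k * k * q >= 1.0:
                raise ValueError(
                    f"target correlation {spec.target_r} for {spec.name!r} "
                    "exceeds the attainable bound")
            spec.weights = k * np.linalg.solve(self.factor_corr, c)
            spec.noise_sd = float(np.sqrt(1.0 - k * k * q))

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "factors": list(self.factors),
            "loading_matrix": self.loading_matrix.tolist(),
            "factor_corr": self.factor_corr.tolist(),
            "thresholds": self.thresholds.tolist(),
            "general_loadings": None if self.general_loadings is None
            else self.general_loadings.tolist(),
            "retest_stability": self.retest_stability.tolist(),
            "reverse_items": list(self.reverse_items),
            "covariates": [{"name": c.name, "target_r": c.target_r,
                            "score": c.score} for c in self.covariates],
        }


@dataclass
class SimConfig:
    n: int = 1437
    seed: int = 0
    waves: int = 2
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {"women": 0.53, "men": 0.47})
    missing_rate: float = 0.001
    mechanism: str = "mcar"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.waves not in (1, 2):
            raise ValueError("waves must be 1 or 2")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing rate must lie in [0, 1)")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-8:
            raise ValueError("group proportions must sum to 1")
        if self.mechanism != "mcar":
            raise ValueError("only MCAR missingness is supported")


def build_population_model(spec: dict) -> PopulationModel:
    """Build and validate a :class:`PopulationModel` from a parameter set.

    ``spec`` maps factor names to ``{item: loading}`` under ``"factors"``;
    optional keys: ``factor_corr``, ``thresholds`` (per-item rows or a single
    shift rule), ``general`` ({item: loading}), ``retest_stability``,
    ``group_deltas``, ``covariates`` ({name: target_r}), ``reverse_items``.
    """
    factor_map: dict[str, dict[str, float]] = spec["factors"]
    factors = list(factor_map)
    items: list[str] = []
    for f in factors:
        items.extend(factor_map[f])
    if len(set(items)) != len(items):
        raise ValueError("simple structure requires disjoint item sets per factor")
    p, k = len(items), len(factors)
    lam = np.zeros((p, k))
    for j, f in enumerate(factors):
        for it, lo in factor_map[f].items():
            lam[items.index(it), j] = lo
    fc = np.asarray(spec.get("factor_corr", np.eye(k)), dtype=float)
    if np.isscalar(spec.get("factor_corr")) and k == 2:
        fc = np.array([[1.0, spec["factor_corr"]], [spec["factor_corr"], 1.0]])
    thr = spec.get("thresholds")
    if thr is None:
        shifts = np.asarray(spec.get("threshold_shifts", np.zeros(p)), dtype=float)
        thr = DEFAULT_THRESHOLDS[None, :] + shifts[:, None]
    thr = np.asarray(thr, dtype=float)
    if thr.ndim == 1:
        thr = np.tile(thr, (p, 1))
    gen = None
    if "general" in spec:
        gen = np.array([spec["general"].get(it, 0.0) for it in items])
    covs = [CovariateSpec(name=n, target_r=r)
            for n, r in spec.get("covariates", {}).items()]
    model = PopulationModel(
        items=items, factors=factors, loading_matrix=lam, factor_corr=fc,
        thresholds=thr, general_loadings=gen,
        retest_stability=spec.get("retest_stability"),
        group_deltas=spec.get("group_deltas"),
        covariates=covs, reverse_items=tuple(spec.get("reverse_items", ())))
    model.calibrate_covariates()
    return model


# ---------------------------------------------------------------------------
# generation


def _discretize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    # raising a latent value can never lower the code: counts of exceeded cuts
    return (latent[:, :, None] > thresholds[None, :, :]).sum(axis=2)


def generate(model: PopulationModel, config: SimConfig) -> pd.DataFrame:
    """Draw an item-response table: persons x (items, wave, group, covariates).

    Wave-2 factor scores follow a latent first-order autoregression with the
    model's per-factor stability; unique noise is redrawn at wave 2.
    Covariates are person-level (measured once, repeated on both wave rows).
    """
    n, k, p = config.n, len(model.factors), len(model.items)
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(5)]
    rng_eta, rng_eps, rng_cov, rng_miss, _ = streams

    chol = np.linalg.cholesky(model.factor_corr)
    eta1 = rng_eta.standard_normal((n, k)) @ chol.T
    g1 = rng_eta.standard_normal(n) if model.general_loadings is not None else None

    groups = np.empty(n, dtype=object)
    labels = list(config.group_proportions)
    bounds = np.floor(np.cumsum([config.group_proportions[g] for g in labels]) * n).astype(int)
    start = 0
    for lbl, stop in zip(labels, bounds):
        groups[start:stop] = lbl
        start = stop
    groups[start:] = labels[-1]

    theta = 1.0 - model.communalities()
    theta = np.clip(theta, 0.0, None)

    def latent_wave(eta, g, lam_by_group, thr_by_group, rng):
        eps = rng.standard_normal((n, p)) * np.sqrt(theta)[None, :]
        codes = np.empty((n, p), dtype=int)
        for lbl in labels:
            m = groups == lbl
            y = eta[m] @ lam_by_group[lbl].T + eps[m]
            if g is not None:
                y = y + np.outer(g[m], model.general_loadings)
            codes[m] = _discretize(y, thr_by_group[lbl])
        return codes

    lam_by_group = {lbl: model.loading_matrix.copy() for lbl in labels}
    thr_by_group = {lbl: model.thresholds.copy() for lbl in labels}
    if model.group_deltas is not None and len(labels) > 1:
        tgt = labels[1]
        for it, d in model.group_deltas.loading.items():
            i = model.items.index(it)
            j = int(np.argmax(np.abs(lam_by_group[tgt][i])))
            lam_by_group[tgt][i, j] += d
        for it, d in model.group_deltas.threshold.items():
            thr_by_group[tgt][model.items.index(it)] += d

    frames = []
    codes1 = latent_wave(eta1, g1, lam_by_group, thr_by_group, rng_eps)

    covariate_cols = {}
    for spec in model.covariates:
        if spec.weights is None:
            raise ValueError(f"covariate {spec.name!r} was never calibrated")
        covariate_cols[spec.name] = eta1 @ spec.weights + spec.noise_sd * \
            rng_cov.standard_normal(n)

    def frame(codes, wave):
        df = pd.DataFrame(codes, columns=model.items)
        df.insert(0, "person", np.arange(n))
        df.insert(1, "wave", wave)
        df.insert(2, "group", groups)
        for name, vals in covariate_cols.items():
            df[name] = vals
        return df

    frames.append(frame(codes1, 1))
    if config.waves == 2:
        s = model.retest_stability
        zeta = rng_eta.standard_normal((n, k)) @ chol.T
        eta2 = eta1 * s[None, :] + zeta * np.sqrt(1 - s**2)[None, :]
        g2 = None
        if g1 is not None:
            sg = float(np.mean(s))
            g2 = g1 * sg + np.sqrt(1 - sg**2) * rng_eta.standard_normal(n)
        codes2 = latent_wave(eta2, g2, lam_by_group, thr_by_group, rng_eps)
        frames.append(frame(codes2, 2))

    table = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        table = table.astype({it: float for it in model.items})
        mask = rng_miss.random((len(table), p)) < config.missing_rate
        block = table.loc[:, model.items].to_numpy()
        block[mask] = np.nan
        table[model.items] = block
    return table


def stress_total(table: pd.DataFrame, model: PopulationModel,
                 items: list[str] | None = None) -> pd.Series:
    """Stress-keyed total: reverse-keyed items flipped (code -> max - code)."""
    items = items or model.items
    max_code = model.thresholds.shape[1]
    block = table.loc[:, items].astype(float).copy()
    for it in items:
        if it in model.reverse_items:
            block[it] = max_code - block[it]
    return block.sum(axis=1, skipna=False)


def verify_targets(table: pd.DataFrame, model: PopulationModel,
                   targets: dict[str, tuple[float, float]] | None = None,
                   score_items: list[str] | None = None) -> pd.DataFrame:
    """Check observed covariate correlations against their calibration targets.

    ``targets`` maps covariate name -> (target r, tolerance); defaults to the
    model's own calibration targets with the +-0.15 tolerance convention.
    """
    if targets is None:
        targets = {c.name: (c.target_r, 0.15) for c in model.covariates}
    wave1 = table[table["wave"] == 1]
    score = stress_total(wave1, model, score_items)
    rows = []
    for name, (target, tol) in targets.items():
        if name not in table.columns:
            raise KeyError(f"unknown covariate or score name {name!r}")
        keep = score.notna() & wave1[name].notna()
        obs = float(np.corrcoef(score[keep], wave1.loc[keep, name])[0, 1])
        dev = abs(obs - target)
        rows.append(dict(name=name, observed=obs, target=target,
                         deviation=dev, passed=dev <= tol))
    return pd.DataFrame(rows).set_index("name")


# ---------------------------------------------------------------------------
# presets


def pss14_model(**overrides) -> PopulationModel:
    """Default 14-item two-factor population: 7 helplessness + 7 self-efficacy
    items with published-magnitude loadings, inter-factor correlation -0.37,
    mildly right-shifted thresholds, retest stability 0.85, and covariates
    calibrated to (0.59, -0.53, -0.44) with the stress-keyed total."""
    helplessness = {"item01": 0.78, "item02": 0.87, "item03": 0.82,
                    "item08": 0.74, "item11": 0.69, "item12": 0.50,
                    "item14": 0.87}
    self_efficacy = {"item04": 0.65, "item05": 0.75, "item06": 0.88,
                     "item07": 0.79, "item09": 0.56, "item10": 0.90,
                     "item13": 0.54}
    spec = {
        "factors": {"helplessness": helplessness, "self_efficacy": self_efficacy},
        "factor_corr": -0.37,
        "threshold_shifts": np.linspace(0.0, 0.6, 14),
        "retest_stability": [0.85, 0.85],
        "covariates": dict(DEFAULT_COVARIATE_TARGETS),
        "reverse_items": tuple(self_efficacy),
    }
    spec.update(overrides)
    return build_population_model(spec)


def marker_model(marker_loadings=(0.92, 0.90), distractor_max=0.58,
                 **overrides) -> PopulationModel:
    """Planted-optimum bundle: per factor, two marker items with loadings
    >= 0.88 and five weaker distractors (<= ``distractor_max``), used for
    short-form selection studies with a known best 2+2 subset."""
    lo_hi = list(marker_loadings)
    distract = np.round(np.linspace(distractor_max, 0.42, 5), 2).tolist()
    helplessness = dict(zip(
        [f"item{i:02d}" for i in (1, 2, 3, 8, 11, 12, 14)],
        lo_hi + distract))
    self_efficacy = dict(zip(
        [f"item{i:02d}" for i in (4, 5, 6, 7, 9, 10, 13)],
        lo_hi + distract))
    spec = {
        "factors": {"helplessness": helplessness, "self_efficacy": self_efficacy},
        "factor_corr": -0.37,
        "threshold_shifts": np.linspace(0.0, 0.6, 14),
        "retest_stability": [0.85, 0.85],
        "covariates": dict(DEFAULT_COVARIATE_TARGETS),
        "reverse_items": tuple(self_efficacy),
    }
    spec.update(overrides)
    return build_population_model(spec)
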