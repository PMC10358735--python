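"""Confirmatory factor analysis for ordinal scales.

Two estimation paths:

* ``dwls`` -- diagonally weighted least squares on a polychoric correlation
  matrix: F = sum_{i<j} (s_ij - sigma_ij(theta))^2 / avar_ij with the
  asymptotic variances of the polychoric estimates as (diagonal) weights.
  The *unadjusted* statistic T = F is reported; no mean-and-variance
  correction is applied, and the estimator tag records this.
* ``ml`` -- normal-theory maximum likelihood on the Pearson correlation
  matrix, T = (n-1) * F_ML.

Supported structures: one-factor, multi-factor simple structure with
correlated factors (optionally with explicit cross-loadings), and bifactor
(one general factor on all items, specific factors orthogonal to it and to
each other).  Identification fixes all factor variances to 1; unique
variances are implicit (1 - communality) under DWLS and free under ML.
Heywood cases (negative implied uniqueness) are flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from .prep import CorrelationEstimate, pearson_matrix, polychoric_matrix

__all__ = ["ModelSpec", "CfaFit", "fit_cfa", "fit_indices", "chi2_diff",
           "modification_candidates"]


@dataclass(frozen=True)
class ModelSpec:
    factors: dict[str, tuple[str, ...]]
    bifactor: bool = False
    estimator: str = "dwls"
    correlated_factors: bool = True
    cross_loadings: tuple[tuple[str, str], ...] = ()   # (item, factor)

    def __post_init__(self):
        object.__setattr__(self, "factors",
                           {f: tuple(its) for f, its in self.factors.items()})
        if self.estimator not in ("dwls", "ml"):
            raise ValueError("estimator must be 'dwls' or 'ml'")
        for it, f in self.cross_loadings:
            if f not in self.factors:
                raise KeyError(f"cross-loading references unknown factor {f!r}")

    @property
    def items(self) -> list[str]:
        seen: list[str] = []
        for its in self.factors.values():
            for it in its:
                if it not in seen:
                    seen.append(it)
        return seen

    def edges(self) -> list[tuple[str, str]]:
        """Free (item, factor) loading edges, including the general factor."""
        e = [(it, f) for f, its in self.factors.items() for it in its]
        e += [(it, f) for it, f in self.cross_loadings]
        if self.bifactor:
            e += [(it, "general") for it in self.items]
        return e

    def factor_names(self) -> list[str]:
        names = list(self.factors)
        if self.bifactor:
            names.append("general")
        return names


@dataclass
class CfaFit:
    spec: ModelSpec
    items: list[str]
    loadings: pd.DataFrame
    theta: np.ndarray
    factor_corr: pd.DataFrame
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    rmsea: float
    n: int
    converged: bool
    estimator: str
    heywood: bool
    fmin: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator, "n": self.n,
            "chi2": self.chi2, "df": self.df,
            "chi2_baseline": self.chi2_baseline, "df_baseline": self.df_baseline,
            "cfi": self.cfi, "rmsea": self.rmsea,
            "converged": self.converged, "heywood": self.heywood,
            "loadings": self.loadings.round(6).to_dict(),
            "factor_corr": self.factor_corr.round(6).to_dict(),
            "theta": np.round(self.theta, 6).tolist(),
        }


# ---------------------------------------------------------------------------
# parameter packing


class _Structure:
    """Maps a packed parameter vector to implied moments for one ModelSpec."""

    def __init__(self, spec: ModelSpec, items: list[str]):
        self.spec = spec
        self.items = items
        self.factors = spec.factor_names()
        self.p = len(items)
        self.k = len(self.factors)
        self.edges = [(items.index(it), self.factors.index(f))
                      for it, f in spec.edges()]
        self.n_load = len(self.edges)
        self.corr_pairs: list[tuple[int, int]] = []
        if not spec.bifactor and spec.correlated_factors and self.k > 1:
            self.corr_pairs = [(i, j) for i in range(self.k)
                               for j in range(i + 1, self.k)]
        self.free_theta = spec.estimator == "ml"
        self.n_params = (self.n_load + len(self.corr_pairs)
                         + (self.p if self.free_theta else 0))

    def start(self) -> np.ndarray:
        x = np.concatenate([
            np.full(self.n_load, 0.6),
            np.zeros(len(self.corr_pairs)),
        ])
        if self.free_theta:
            x = np.concatenate([x, np.full(self.p, np.log(0.5))])
        return x

    def unpack(self, x: np.ndarray):
        lam = np.zeros((self.p, self.k))
        for v, (i, j) in zip(x[: self.n_load], self.edges):
            lam[i, j] = v
        phi = np.eye(self.k)
        z = x[self.n_load: self.n_load + len(self.corr_pairs)]
        for v, (i, j) in zip(np.tanh(z), self.corr_pairs):
            phi[i, j] = phi[j, i] = v
        theta = None
        if self.free_theta:
            theta = np.exp(x[self.n_load + len(self.corr_pairs):])
        return lam, phi, theta

    def implied(self, x: np.ndarray) -> np.ndarray:
        lam, phi, theta = self.unpack(x)
        sigma = lam @ phi @ lam.T
        if theta is not None:
            sigma = sigma + np.diag(theta)
        else:
            np.fill_diagonal(sigma, 1.0)
        return sigma


def _dwls_weights(est: CorrelationEstimate) -> np.ndarray:
    iu = np.triu_indices(len(est.items), 1)
    if est.avar is not None and np.all(est.avar[iu] > 0):
        return 1.0 / est.avar[iu]
    # Pearson-type fallback when no asymptotic variances are available
    s = est.matrix[iu]
    return est.n / np.maximum((1 - s**2) ** 2, 1e-8)


def fit_cfa(data, spec: ModelSpec, n: int | None = None) -> CfaFit:
    """Fit a CFA; ``data`` is an ItemResponseTable slice or a CorrelationEstimate.

    Non-convergence is returned as a flagged result, not raised.
    """
    items = spec.items
    if isinstance(data, CorrelationEstimate):
        est = data
        missing = set(items) - set(est.items)
        if missing:
            raise KeyError(f"correlation estimate lacks items {sorted(missing)}")
        idx = [est.items.index(it) for it in items]
        sub = CorrelationEstimate(
            items=items, matrix=est.matrix[np.ix_(idx, idx)], method=est.method,
            n=est.n, thresholds={i: est.thresholds[i] for i in items if i in est.thresholds},
            avar=None if est.avar is None else est.avar[np.ix_(idx, idx)])
        est = sub
    else:
        est = (polychoric_matrix(data, items) if spec.estimator == "dwls"
               else pearson_matrix(data, items))
    n = n or est.n
    if n < 2:
        raise ValueError("need n >= 2")
    if abs(np.linalg.det(est.matrix)) < 1e-14:
        raise ValueError("input correlation matrix is singular")

    struct = _Structure(spec, items)
    p = struct.p
    if struct.free_theta:
        # ML fits the full covariance including the diagonal
        n_stats = p * (p + 1) // 2
    else:
        n_stats = p * (p - 1) // 2
    df = n_stats - struct.n_params
    if df < 0:
        raise ValueError("model under-identified: negative degrees of freedom")
    for f, its in spec.factors.items():
        if len(its) < 3 and len(spec.factors) < 2 and not spec.bifactor:
            raise ValueError(f"stand-alone factor {f!r} needs >= 3 indicators")

    iu = np.triu_indices(p, 1)
    s_vec = est.matrix[iu]

    if spec.estimator == "dwls":
        w = _dwls_weights(est)

        def objective(x):
            sigma = struct.implied(x)
            return float(np.sum(w * (s_vec - sigma[iu]) ** 2))

        chi2_baseline = float(np.sum(w * s_vec**2))
        df_baseline = n_stats
        stat_of = lambda f: f
    else:
        S = est.matrix
        sign, logdet_s = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample matrix not positive definite")

        def objective(x):
            sigma = struct.implied(x)
            sgn, logdet = np.linalg.slogdet(sigma)
            if sgn <= 0:
                return 1e10
            return float(logdet + np.trace(np.linalg.solve(sigma, S))
                         - logdet_s - p)

        chi2_baseline = float((n - 1) * (-logdet_s))
        df_baseline = p * (p - 1) // 2
        stat_of = lambda f: (n - 1) * f

    res = optimize.minimize(objective, struct.start(), method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    lam, phi, theta = struct.unpack(res.x)
    if theta is None:
        theta = 1.0 - np.einsum("ip,pq,iq->i", lam, phi, lam)
    heywood = bool(np.any(theta < -1e-6))
    fmin = max(float(res.fun), 0.0)
    chi2 = stat_of(fmin)
    chi2 = max(chi2, 0.0)
    if df == 0 and chi2 < 1e-6:
        chi2 = 0.0
    cfi, rmsea, note = fit_indices(chi2, df, chi2_baseline, df_baseline, n)

    return CfaFit(
        spec=spec, items=items,
        loadings=pd.DataFrame(lam, index=items, columns=struct.factors),
        theta=theta,
        factor_corr=pd.DataFrame(phi, index=struct.factors, columns=struct.factors),
        chi2=chi2, df=df, chi2_baseline=chi2_baseline, df_baseline=df_baseline,
        cfi=cfi, rmsea=rmsea, n=n, converged=bool(res.success),
        estimator=spec.estimator, heywood=heywood, fmin=fmin, note=note)


def fit_indices(chi2_m: float, df_m: int, chi2_b: float, df_b: int, n: int):
    """CFI and RMSEA from model and baseline chi-square statistics.

    CFI = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    RMSEA = sqrt(max(chi2_m - df_m, 0) / (df_m (n - 1))).
    Returns (cfi, rmsea, note); df_m = 0 yields RMSEA 0 with a note.
    """
    if min(chi2_m, chi2_b) < 0 or min(df_m, df_b) < 0:
        raise ValueError("chi-square statistics and df must be non-negative")
    if n < 2:
        raise ValueError("need n >= 2")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    note = ""
    if df_m == 0:
        rmsea = 0.0
        note = "saturated model: RMSEA reported as 0"
    else:
        rmsea = float(np.sqrt(num / (df_m * (n - 1))))
    return float(cfi), rmsea, note


def chi2_diff(fit_restricted, fit_free):
    """Chi-square difference test of nested fits.

    Accepts CfaFit-like objects (``.chi2``, ``.df``) or (chi2, df) tuples.
    Returns (delta chi2, delta df, p).  The DWLS path uses the naive
    unadjusted difference -- a documented approximation.
    """
    def stats(f):
        if hasattr(f, "chi2"):
            return f.chi2, f.df
        return f

    c_r, df_r = stats(fit_restricted)
    c_f, df_f = stats(fit_free)
    ddf = df_r - df_f
    if ddf <= 0:
        raise ValueError("restricted model must have more degrees of freedom")
    dchi = max(c_r - c_f, 0.0)
    p = float(chi2_dist.sf(dchi, ddf))
    return dchi, ddf, p


def modification_candidates(fit: CfaFit, data, pool: list[tuple[str, str]]):
    """Rank candidate cross-loadings by the chi-square drop when freed.

    Each (item, factor) pair in ``pool`` is freed one at a time and the model
    refit; the result is a list of (parameter, drop) sorted descending.  A
    refit that fails to converge reports NaN for that candidate.
    """
    if not fit.converged:
        raise ValueError("base fit did not converge")
    if not pool:
        raise ValueError("candidate pool is empty")
    out = []
    for item, factor in pool:
        spec2 = ModelSpec(factors=fit.spec.factors, bifactor=fit.spec.bifactor,
                          estimator=fit.spec.estimator,
                          correlated_factors=fit.spec.correlated_factors,
                          cross_loadings=fit.spec.cross_loadings + ((item, factor),))
        refit = fit_cfa(data, spec2, n=fit.n)
        drop = fit.chi2 - refit.chi2 if refit.converged else np.nan
        out.append(((item, factor), drop))
    return sorted(out, key=lambda t: (np.isnan(t[1]), -t[1] if np.isfinite(t[1]) else 0))
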