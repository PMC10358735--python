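"""Internal consistency and test-retest reliability.

Cronbach's alpha, McDonald's omega from a one-factor solution, and the
intraclass correlation for two-wave retest designs.  The default ICC is the
two-way random-effects, absolute-agreement, single-measurement coefficient
ICC(2,1); a consistency variant ICC(3,1) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReliabilityReport", "cronbach_alpha", "mcdonald_omega",
           "icc_retest", "omega_from_items"]


@dataclass
class ReliabilityReport:
    alpha: float
    omega: float
    icc: float
    icc_variant: str
    n_alpha: int
    n_icc: int

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "omega": self.omega, "icc": self.icc,
                "icc_variant": self.icc_variant,
                "n_alpha": self.n_alpha, "n_icc": self.n_icc}


def cronbach_alpha(scores: pd.DataFrame | np.ndarray) -> float:
    """alpha = k/(k-1) (1 - sum of item variances / variance of the sum).

    Listwise-complete rows; requires >= 2 items and >= 2 complete rows.
    """
    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 2:
        raise ValueError("alpha needs at least 2 complete rows")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def mcdonald_omega(loadings: np.ndarray, theta: np.ndarray) -> float:
    """omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta)."""
    lam = np.asarray(loadings, dtype=float)
    th = np.asarray(theta, dtype=float)
    if lam.shape != th.shape:
        raise ValueError("loadings and unique variances must have equal length")
    if np.any(th < 0):
        raise ValueError("unique variances must be non-negative")
    num = lam.sum() ** 2
    den = num + th.sum()
    if den == 0:
        raise ValueError("omega undefined: zero loadings and zero uniqueness")
    return float(num / den)


def omega_from_items(table: pd.DataFrame, items: list[str],
                     method: str = "polychoric") -> float:
    """Omega of an item set from its own one-factor solution.

    For >= 3 items a one-factor CFA is fit (DWLS on polychorics by default).
    A two-item set is under-identified, so the tau-equivalent solution
    lambda_i = sqrt(r) of the inter-item correlation is used; with r <= 0
    omega is reported as 0.
    """
    from . import cfa
    from .prep import pearson_matrix, polychoric_matrix

    if len(items) < 2:
        raise ValueError("omega needs at least 2 items")
    if len(items) == 2:
        est = (polychoric_matrix(table, items) if method == "polychoric"
               else pearson_matrix(table, items))
        r = est.matrix[0, 1]
        if r <= 0:
            return 0.0
        lam = np.sqrt(r)
        return mcdonald_omega(np.array([lam, lam]), np.array([1 - r, 1 - r]))
    spec = cfa.ModelSpec(factors={"f": tuple(items)},
                         estimator="dwls" if method == "polychoric" else "ml")
    fit = cfa.fit_cfa(table, spec)
    lam = fit.loadings["f"].to_numpy()
    if lam.sum() < 0:
        lam = -lam
    theta = np.clip(fit.theta, 0.0, None)
    return mcdonald_omega(lam, theta)


def icc_retest(wave1: np.ndarray | pd.Series, wave2: np.ndarray | pd.Series,
               variant: str = "agreement") -> float:
    """Test-retest ICC from the two-way ANOVA decomposition with k = 2 raters.

    ``agreement`` is ICC(2,1): (MS_R - MS_E) / (MS_R + (k-1) MS_E +
    (k/n)(MS_C - MS_E)); ``consistency`` is ICC(3,1):
    (MS_R - MS_E) / (MS_R + (k-1) MS_E).
    """
    x = np.asarray(wave1, dtype=float)
    y = np.asarray(wave2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("waves must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise ValueError("ICC needs at least 2 paired persons")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if variant == "agreement":
        den = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    elif variant == "consistency":
        den = ms_r + (k - 1) * ms_e
    else:
        raise ValueError("variant must be 'agreement' or 'consistency'")
    if den <= 0:
        return 0.0
    return float((ms_r - ms_e) / den)
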