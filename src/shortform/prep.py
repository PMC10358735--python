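"""Scale preparation: missing data, scoring, descriptives, correlations.

Implements the pre-modeling layer of the pipeline: person-mean imputation
for single missing items, reverse-keyed sum scoring, item-level normality
screening (skewness / excess kurtosis / Shapiro-Wilk), and Pearson and
polychoric correlation estimation with per-item thresholds and asymptotic
variances for downstream diagonally weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from ._bvnorm import RHO_CLIP, bvn_cell_probs

__all__ = [
    "ScaleDefinition",
    "CorrelationEstimate",
    "impute_missing",
    "reverse_and_score",
    "describe_items",
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
    "pearson_matrix",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A named item set with an optional reverse-keyed subset.

    ``max_code`` is the largest ordinal code; reversal maps x -> max_code - x.
    """

    name: str
    items: tuple[str, ...]
    reverse: tuple[str, ...] = ()
    max_code: int = 4

    def __post_init__(self):
        if self.max_code < 1:
            raise ValueError("max_code must be >= 1")
        extra = set(self.reverse) - set(self.items)
        if extra:
            raise ValueError(f"reverse-keyed items not in scale: {sorted(extra)}")


@dataclass
class CorrelationEstimate:
    """A correlation matrix plus the metadata DWLS fitting needs."""

    items: list[str]
    matrix: np.ndarray
    method: str  # "pearson" | "polychoric"
    n: int
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    avar: np.ndarray | None = None          # asymptotic variance per entry
    threshold_avar: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(m) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV with item-name headers."""
        pd.DataFrame(self.matrix, index=self.items,
                     columns=self.items).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# missing data and scoring


def impute_missing(table: pd.DataFrame, scales: list[ScaleDefinition]):
    """Person-mean imputation of single missing items per scale.

    Exactly one missing item on a scale is replaced by that person's mean of
    the remaining items of the same scale; two or more missing items flag the
    person's score on that scale as unusable (the items stay missing).
    Returns the imputed table and a log with counts of both events.
    """
    out = table.copy()
    log = {}
    for scale in scales:
        missing_cols = [c for c in scale.items if c not in table.columns]
        if missing_cols:
            raise KeyError(f"scale {scale.name!r} references absent columns {missing_cols}")
        block = out.loc[:, list(scale.items)]
        n_miss = block.isna().sum(axis=1)
        one = n_miss == 1
        many = n_miss > 1
        if one.any():
            means = block.loc[one].mean(axis=1, skipna=True)
            sub = block.loc[one].apply(lambda col: col.fillna(means))
            out.loc[one, list(scale.items)] = sub
        log[scale.name] = {
            "imputed_single": int(one.sum()),
            "flagged_unusable": int(many.sum()),
        }
    return out, log


def reverse_and_score(table: pd.DataFrame, scale: ScaleDefinition) -> pd.Series:
    """Reverse-keyed sum score; missing items propagate to a missing score."""
    block = table.loc[:, list(scale.items)].astype(float)
    vals = block.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > scale.max_code):
        raise ValueError(
            f"codes outside 0..{scale.max_code} in scale {scale.name!r}"
        )
    for item in scale.reverse:
        block[item] = scale.max_code - block[item]
    return block.sum(axis=1, skipna=False).rename(scale.name)


def describe_items(table: pd.DataFrame, items: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Per-item skewness, excess kurtosis, Shapiro-Wilk p, and normality flag.

    An item is flagged when Shapiro-Wilk rejects at ``alpha`` *and* a moment
    leaves the -1.5..1.5 band (|skewness| > 1.5 or |excess kurtosis| > 1.5).
    In large samples Shapiro-Wilk rejects for negligible deviations, so the
    moment bounds carry the decision; components are reported separately.
    Kurtosis is the excess (Fisher) convention.
    """
    rows = []
    for item in items:
        x = table[item].dropna().to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"item {item!r} has fewer than 3 observations")
        if np.ptp(x) == 0.0:
            rows.append(dict(item=item, skewness=np.nan, kurtosis=np.nan,
                             shapiro_p=np.nan, flagged=True, reason="constant"))
            continue
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        # scipy warns above n=5000; the p-value is still monotone and only
        # its rejection at alpha is consumed
        sub = x if x.size <= 5000 else np.random.default_rng(0).choice(x, 5000, replace=False)
        sw_p = float(stats.shapiro(sub).pvalue)
        moments_out = abs(skew) > 1.5 or abs(kurt) > 1.5
        flagged = moments_out and sw_p < alpha
        reason = ""
        if flagged:
            parts = [p for p, bad in (("skewness", abs(skew) > 1.5),
                                      ("kurtosis", abs(kurt) > 1.5)) if bad]
            reason = "+".join(parts + ["shapiro"])
        rows.append(dict(item=item, skewness=skew, kurtosis=kurt,
                         shapiro_p=sw_p, flagged=bool(flagged), reason=reason))
    return pd.DataFrame(rows).set_index("item")


# ---------------------------------------------------------------------------
# polychoric correlations


def estimate_thresholds(codes: np.ndarray, n_categories: int):
    """Inverse-normal thresholds from cumulative category proportions.

    Returns (thresholds, asymptotic variances); ``n_categories - 1``
    thresholds for codes 0 .. n_categories-1.
    """
    codes = np.asarray(codes)
    codes = codes[np.isfinite(codes)].astype(int)
    n = codes.size
    counts = np.bincount(codes, minlength=n_categories)
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1e-8, 1 - 1e-8)
    tau = stats.norm.ppf(cum)
    avar = cum * (1 - cum) / (n * stats.norm.pdf(tau) ** 2)
    return tau, avar


def _neg_loglik(rho: float, counts: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray) -> float:
    probs = bvn_cell_probs(tau_x, tau_y, rho)
    probs = np.clip(probs, 1e-12, 1.0)
    return -float(np.sum(counts * np.log(probs)))


def polychoric_pair(x: np.ndarray, y: np.ndarray, n_categories: int | None = None):
    """Two-step polychoric correlation of two ordinal code vectors.

    Thresholds are fixed from the margins, then the latent correlation is
    found by a coarse grid scan refined with bounded Brent minimization of
    the bivariate-normal two-way-table likelihood.  Estimates are clipped to
    [-0.999, 0.999].  Returns (rho, asymptotic variance of rho).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep].astype(int), y[keep].astype(int)
    if n_categories is None:
        n_categories = int(max(x.max(), y.max())) + 1
    for name, v in (("x", x), ("y", y)):
        if np.unique(v).size < 2:
            raise ValueError(f"item {name!r} has a single observed category")
    counts = np.zeros((n_categories, n_categories))
    np.add.at(counts, (x, y), 1.0)
    # collapse empty marginal categories so thresholds stay strictly ordered
    rx = counts.sum(axis=1) > 0
    ry = counts.sum(axis=0) > 0
    counts = counts[np.ix_(rx, ry)]
    tau_x, _ = estimate_thresholds(_rank_codes(x), int(rx.sum()))
    tau_y, _ = estimate_thresholds(_rank_codes(y), int(ry.sum()))

    grid = np.linspace(-0.95, 0.95, 13)
    vals = [_neg_loglik(r, counts, tau_x, tau_y) for r in grid]
    r0 = grid[int(np.argmin(vals))]
    lo, hi = max(r0 - 0.17, -RHO_CLIP), min(r0 + 0.17, RHO_CLIP)
    res = minimize_scalar(_neg_loglik, bounds=(lo, hi), args=(counts, tau_x, tau_y),
                          method="bounded", options={"xatol": 1e-6})
    rho = float(np.clip(res.x, -RHO_CLIP, RHO_CLIP))
    # boundary handling: if the optimum sits on the clip, report the clip
    if _neg_loglik(RHO_CLIP, counts, tau_x, tau_y) < res.fun:
        rho = RHO_CLIP
    if _neg_loglik(-RHO_CLIP, counts, tau_x, tau_y) < min(res.fun, _neg_loglik(RHO_CLIP, counts, tau_x, tau_y)):
        rho = -RHO_CLIP

    h = 1e-4
    r_in = float(np.clip(rho, -RHO_CLIP + 2 * h, RHO_CLIP - 2 * h))
    d2 = (_neg_loglik(r_in + h, counts, tau_x, tau_y)
          - 2 * _neg_loglik(r_in, counts, tau_x, tau_y)
          + _neg_loglik(r_in - h, counts, tau_x, tau_y)) / h**2
    avar = 1.0 / d2 if d2 > 0 else 1.0 / max(x.size, 1)
    return rho, float(avar)


def _rank_codes(v: np.ndarray) -> np.ndarray:
    """Re-code to consecutive 0..k-1 over observed categories."""
    _, inv = np.unique(v, return_inverse=True)
    return inv


def polychoric_matrix(table: pd.DataFrame, items: list[str],
                      n_categories: int | None = None) -> CorrelationEstimate:
    """Pairwise polychoric correlation matrix with thresholds and avars."""
    p = len(items)
    mat = np.eye(p)
    avar = np.zeros((p, p))
    thresholds, th_avar = {}, {}
    data = {it: table[it].to_numpy(dtype=float) for it in items}
    ncat = n_categories
    if ncat is None:
        ncat = int(np.nanmax(np.concatenate([data[it] for it in items]))) + 1
    n_obs = len(table)
    for it in items:
        codes = data[it][np.isfinite(data[it])]
        if np.unique(codes).size < 2:
            raise ValueError(f"item {it!r} has a single observed category")
        thresholds[it], th_avar[it] = estimate_thresholds(codes, ncat)
    for i in range(p):
        for j in range(i + 1, p):
            r, v = polychoric_pair(data[items[i]], data[items[j]], ncat)
            mat[i, j] = mat[j, i] = r
            avar[i, j] = avar[j, i] = v
    return CorrelationEstimate(items=list(items), matrix=mat, method="polychoric",
                               n=n_obs, thresholds=thresholds, avar=avar,
                               threshold_avar=th_avar)


def pearson_matrix(table: pd.DataFrame, items: list[str]) -> CorrelationEstimate:
    block = table.loc[:, items].dropna()
    mat = np.corrcoef(block.to_numpy(dtype=float), rowvar=False)
    return CorrelationEstimate(items=list(items), matrix=mat, method="pearson",
                               n=len(block))
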