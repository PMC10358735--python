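"""Multiple-group CFA and the measurement-invariance ladder.

Levels, from least to most constrained:

* ``configural`` -- same factor structure per group, all parameters free;
* ``metric``     -- factor loadings equal across groups (group 2+ factor
                    variances/covariances freed);
* ``scalar``     -- item thresholds (ordinal path) or intercepts (ML path)
                    additionally equal (group 2+ latent means freed; ordinal
                    path also frees group 2+ latent-response scales);
* ``strict``     -- residual variances additionally equal.

Adjacent levels are compared with chi-square difference tests; a greedy
partial-invariance search frees the constrained parameter with the largest
chi-square drop until the difference test passes or a release budget is
exhausted.

Identification follows a delta-parameterization analogue: the first group
sets the scale (unit latent-response variances, zero latent means, unit
factor variances); higher groups earn free factor (co)variances at metric,
and free latent means plus free scales at scalar.  Thresholds (and ML
intercepts/means at saturated levels) are profiled out analytically, which
keeps the optimization dimension small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import optimize

from .cfa import ModelSpec, chi2_diff, fit_indices
from .prep import polychoric_matrix

__all__ = ["GroupStats", "MgFit", "InvarianceLadder", "compute_group_stats",
           "fit_multigroup", "invariance_ladder", "partial_release", "LEVELS"]

LEVELS = ("configural", "metric", "scalar", "strict")


@dataclass
class GroupStats:
    label: str
    n: int
    items: list[str]
    estimator: str
    tau: np.ndarray | None = None        # p x (C-1)
    tau_w: np.ndarray | None = None      # 1 / avar
    corr: np.ndarray | None = None
    corr_w: np.ndarray | None = None
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None


def compute_group_stats(table: pd.DataFrame, items: list[str], label: str,
                        estimator: str, n_categories: int | None = None) -> GroupStats:
    n = len(table)
    if estimator == "dwls":
        est = polychoric_matrix(table, items, n_categories=n_categories)
        ncat = len(next(iter(est.thresholds.values()))) + 1
        tau = np.array([est.thresholds[i] for i in items])
        tau_w = 1.0 / np.array([est.threshold_avar[i] for i in items])
        iu = np.triu_indices(len(items), 1)
        corr_w = np.zeros_like(est.avar)
        corr_w[iu] = 1.0 / est.avar[iu]
        corr_w = corr_w + corr_w.T
        return GroupStats(label=label, n=n, items=list(items), estimator="dwls",
                          tau=tau, tau_w=tau_w, corr=est.matrix, corr_w=corr_w)
    block = table.loc[:, items].dropna().to_numpy(dtype=float)
    return GroupStats(label=label, n=len(block), items=list(items), estimator="ml",
                      mean=block.mean(axis=0), cov=np.cov(block, rowvar=False))


@dataclass
class MgFit:
    level: str
    estimator: str
    chi2: float
    df: int
    cfi: float
    rmsea: float
    n: int
    converged: bool
    freed: dict[str, tuple] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    note: str = ""


# ---------------------------------------------------------------------------
# parameter bookkeeping


class _MgModel:
    def __init__(self, stats: list[GroupStats], spec: ModelSpec, level: str,
                 freed_loadings=(), freed_locations=(), freed_residuals=()):
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        self.stats = stats
        self.spec = spec
        self.level = level
        self.rank = LEVELS.index(level)
        self.estimator = stats[0].estimator
        self.items = stats[0].items
        self.factors = spec.factor_names()
        self.p = len(self.items)
        self.k = len(self.factors)
        self.G = len(stats)
        self.edges = [(self.items.index(it), self.factors.index(f))
                      for it, f in spec.edges()]
        self.freed_loadings = {(it, f) for it, f in freed_loadings}
        self.freed_locations = set(freed_locations)   # items (thresholds/intercepts)
        self.freed_residuals = set(freed_residuals)
        self.correlated = (not spec.bifactor) and spec.correlated_factors and self.k > 1
        self.n_corr = self.k * (self.k - 1) // 2 if self.correlated else 0
        self._build_slots()

    def _build_slots(self):
        slots: list[tuple[str, int]] = []
        E = len(self.edges)
        if self.rank >= 1:          # metric+: shared loadings, freed ones per group
            slots.append(("lam_shared", E))
            n_freed = len([e for e in self.spec.edges() if e in self.freed_loadings])
            for g in range(1, self.G):
                if n_freed:
                    slots.append((f"lam_freed_{g}", n_freed))
        else:
            for g in range(self.G):
                slots.append((f"lam_{g}", E))
        slots.append(("phi_corr_0", self.n_corr))
        for g in range(1, self.G):
            if self.rank >= 1:
                slots.append((f"phi_logvar_{g}", self.k))
                slots.append((f"phi_corr_{g}", self.n_corr))
            else:
                slots.append((f"phi_corr_{g}", self.n_corr))
        if self.rank >= 2:
            for g in range(1, self.G):
                slots.append((f"alpha_{g}", self.k))
        if self.estimator == "dwls":
            # group 2+ latent-response scales: free at scalar, tied at strict
            if self.rank == 2:
                for g in range(1, self.G):
                    slots.append((f"logtheta_{g}", self.p))
            elif self.rank == 3 and self.freed_residuals:
                for g in range(1, self.G):
                    slots.append((f"logtheta_freed_{g}", len(self.freed_residuals)))
        else:
            if self.rank >= 3:
                slots.append(("logtheta_shared", self.p))
                for g in range(1, self.G):
                    if self.freed_residuals:
                        slots.append((f"logtheta_freed_{g}", len(self.freed_residuals)))
            else:
                for g in range(self.G):
                    slots.append((f"logtheta_{g}", self.p))
        self.slots = [(k, sz) for k, sz in slots if sz > 0]
        self.index = {}
        pos = 0
        for key, sz in self.slots:
            self.index[key] = slice(pos, pos + sz)
            pos += sz
        self.n_opt = pos

    # -- free-parameter count (including profiled location parameters) ------

    def n_free(self) -> int:
        n = self.n_opt
        C = self.stats[0].tau.shape[1] if self.estimator == "dwls" else 1
        if self.estimator == "dwls":
            if self.rank < 2:
                n += self.G * self.p * C
            else:
                n += self.p * C
                n += (self.G - 1) * len(self.freed_locations) * C
        else:
            if self.rank < 2:
                n += self.G * self.p
            else:
                n += self.p
                n += (self.G - 1) * len(self.freed_locations)
        return n

    def n_stats(self) -> int:
        if self.estimator == "dwls":
            C = self.stats[0].tau.shape[1]
            return self.G * (self.p * C + self.p * (self.p - 1) // 2)
        return self.G * (self.p + self.p * (self.p + 1) // 2)

    def start(self) -> np.ndarray:
        x = np.zeros(self.n_opt)
        for key, sl in self.index.items():
            if key.startswith("lam"):
                x[sl] = 0.6
            elif key.startswith("logtheta"):
                x[sl] = np.log(0.5)
        return x

    # -- unpack -------------------------------------------------------------

    def _phi(self, x, g) -> np.ndarray:
        phi = np.eye(self.k)
        corr_key = f"phi_corr_{g}"
        if self.n_corr and corr_key in self.index:
            z = np.tanh(x[self.index[corr_key]])
            idx = 0
            for i in range(self.k):
                for j in range(i + 1, self.k):
                    phi[i, j] = phi[j, i] = z[idx]
                    idx += 1
        if g > 0 and self.rank >= 1 and f"phi_logvar_{g}" in self.index:
            v = np.exp(x[self.index[f"phi_logvar_{g}"]])
            d = np.sqrt(v)
            phi = phi * np.outer(d, d)
        return phi

    def _lambda(self, x, g) -> np.ndarray:
        lam = np.zeros((self.p, self.k))
        if self.rank >= 1:
            vals = x[self.index["lam_shared"]]
            freed_vals = None
            freed_edges = [e for e in self.spec.edges() if e in self.freed_loadings]
            if g > 0 and freed_edges and f"lam_freed_{g}" in self.index:
                freed_vals = dict(zip(freed_edges, x[self.index[f"lam_freed_{g}"]]))
            for v, (edge, (i, j)) in zip(vals, zip(self.spec.edges(), self.edges)):
                if freed_vals is not None and edge in freed_vals:
                    lam[i, j] = freed_vals[edge]
                else:
                    lam[i, j] = v
        else:
            vals = x[self.index[f"lam_{g}"]]
            for v, (i, j) in zip(vals, self.edges):
                lam[i, j] = v
        return lam

    def unpack(self, x):
        groups = []
        for g in range(self.G):
            lam = self._lambda(x, g)
            phi = self._phi(x, g)
            cov = lam @ phi @ lam.T
            h = np.diag(cov).copy()
            alpha = np.zeros(self.k)
            if g > 0 and self.rank >= 2 and f"alpha_{g}" in self.index:
                alpha = x[self.index[f"alpha_{g}"]]
            mu = lam @ alpha
            groups.append(dict(lam=lam, phi=phi, cov=cov, h=h, mu=mu, g=g))
        return groups

    # -- objective ----------------------------------------------------------

    def _dwls_objective(self, x) -> float:
        groups = self.unpack(x)
        f = 0.0
        p = self.p
        iu = np.triu_indices(p, 1)
        scales = []
        for gd in groups:
            g = gd["g"]
            if g == 0 or self.rank < 2:
                v = np.ones(p)
            elif self.rank == 2:
                theta = np.exp(x[self.index[f"logtheta_{g}"]])
                v = gd["h"] + theta
            else:  # strict: theta tied to the group-0 uniqueness
                theta0 = 1.0 - groups[0]["h"]
                theta = theta0.copy()
                if self.freed_residuals and f"logtheta_freed_{g}" in self.index:
                    fr = sorted(self.freed_residuals, key=self.items.index)
                    for it, val in zip(fr, np.exp(x[self.index[f"logtheta_freed_{g}"]])):
                        theta[self.items.index(it)] = val
                v = gd["h"] + np.clip(theta, 1e-6, None)
            if np.any(v <= 1e-8):
                return 1e12
            gd["v"] = v
            scales.append(np.sqrt(v))
        for gd, st, s in zip(groups, self.stats, scales):
            model_corr = gd["cov"] / np.outer(s, s)
            resid = st.corr[iu] - model_corr[iu]
            f += float(np.sum(st.corr_w[iu] * resid**2))
        # thresholds: free (saturated) below scalar, shared and profiled above
        if self.rank >= 2:
            A = np.array([1.0 / s for s in scales])              # G x p
            Cvec = np.array([-gd["mu"] / s for gd, s in zip(groups, scales)])
            for i in range(p):
                shared = self.items[i] not in self.freed_locations
                bw = np.array([st.tau_w[i] for st in self.stats])  # G x C
                b = np.array([st.tau[i] for st in self.stats])
                if shared:
                    a = A[:, i][:, None]
                    c = Cvec[:, i][:, None]
                    num = np.sum(bw * a * (b - c), axis=0)
                    den = np.sum(bw * a * a, axis=0)
                    tau_star = num / den
                    model = a * tau_star[None, :] + c
                    f += float(np.sum(bw * (b - model) ** 2))
                # freed: per-group saturated, contributes 0
        return f

    def _ml_objective(self, x) -> float:
        groups = self.unpack(x)
        p = self.p
        f = 0.0
        sigmas = []
        for gd in groups:
            g = gd["g"]
            if self.rank >= 3:
                theta = np.exp(x[self.index["logtheta_shared"]])
                if g > 0 and self.freed_residuals and f"logtheta_freed_{g}" in self.index:
                    theta = theta.copy()
                    fr = sorted(self.freed_residuals, key=self.items.index)
                    for it, val in zip(fr, np.exp(x[self.index[f"logtheta_freed_{g}"]])):
                        theta[self.items.index(it)] = val
            else:
                theta = np.exp(x[self.index[f"logtheta_{g}"]])
            sigma = gd["cov"] + np.diag(theta)
            sigmas.append(sigma)
        mean_term = np.zeros(self.G)
        if self.rank >= 2:
            # profile the shared intercepts given latent means
            lhs = np.zeros((p, p))
            rhs = np.zeros(p)
            sinv = []
            for st, gd, sigma in zip(self.stats, groups, sigmas):
                try:
                    si = np.linalg.inv(sigma)
                except np.linalg.LinAlgError:
                    return 1e12
                sinv.append(si)
                lhs += st.n * si
                rhs += st.n * si @ (st.mean - gd["mu"])
            nu = np.linalg.solve(lhs, rhs)
            free_idx = [self.items.index(it) for it in self.freed_locations]
            for g, (st, gd, si) in enumerate(zip(self.stats, groups, sinv)):
                mu_g = nu + gd["mu"]
                d = st.mean - mu_g
                if free_idx:
                    d = d.copy()
                    d[free_idx] = 0.0   # freed intercepts are saturated per group
                mean_term[g] = float(d @ si @ d)
        for g, (st, sigma) in enumerate(zip(self.stats, sigmas)):
            sgn, logdet = np.linalg.slogdet(sigma)
            if sgn <= 0:
                return 1e12
            sgn_s, logdet_s = np.linalg.slogdet(st.cov)
            val = (logdet + np.trace(np.linalg.solve(sigma, st.cov))
                   - logdet_s - p + mean_term[g])
            f += st.n * val
        return f

    def objective(self, x) -> float:
        return (self._dwls_objective(x) if self.estimator == "dwls"
                else self._ml_objective(x))

    def baseline_chi2(self):
        if self.estimator == "dwls":
            iu = np.triu_indices(self.p, 1)
            chi2 = sum(float(np.sum(st.corr_w[iu] * st.corr[iu] ** 2))
                       for st in self.stats)
        else:
            chi2 = 0.0
            for st in self.stats:
                corr = st.cov / np.sqrt(np.outer(np.diag(st.cov), np.diag(st.cov)))
                sgn, logdet = np.linalg.slogdet(corr)
                chi2 += st.n * (-logdet)
        df = self.G * self.p * (self.p - 1) // 2
        return chi2, df


def fit_multigroup(stats: list[GroupStats], spec: ModelSpec, level: str,
                   freed_loadings=(), freed_locations=(), freed_residuals=()) -> MgFit:
    model = _MgModel(stats, spec, level, freed_loadings, freed_locations,
                     freed_residuals)
    res = optimize.minimize(model.objective, model.start(), method="L-BFGS-B",
                            options={"maxiter": 800, "ftol": 1e-12, "gtol": 1e-8})
    chi2 = max(float(res.fun), 0.0)
    df = model.n_stats() - model.n_free()
    n = sum(st.n for st in stats)
    chi2_b, df_b = model.baseline_chi2()
    cfi, rmsea, note = fit_indices(chi2, df, chi2_b, df_b, n)
    return MgFit(level=level, estimator=model.estimator, chi2=chi2, df=df,
                 cfi=cfi, rmsea=rmsea, n=n, converged=bool(res.success),
                 freed={"loadings": tuple(freed_loadings),
                        "locations": tuple(freed_locations),
                        "residuals": tuple(freed_residuals)},
                 params={"x": res.x, "slots": model.slots}, note=note)


@dataclass
class InvarianceLadder:
    fits: dict[str, MgFit]
    comparisons: pd.DataFrame
    decisions: dict[str, str]
    stats: list[GroupStats]
    spec: ModelSpec
    alpha: float


def invariance_ladder(table: pd.DataFrame, group_col: str, spec: ModelSpec,
                      levels=LEVELS, alpha: float = 0.05,
                      min_group_n: int = 100,
                      n_categories: int | None = None) -> InvarianceLadder:
    """Fit the invariance ladder across the groups of ``group_col``.

    Adjacent levels are compared by chi-square difference at ``alpha``; a
    non-convergent level truncates the ladder with a flag.
    """
    labels = [g for g in table[group_col].dropna().unique()]
    if len(labels) < 2:
        raise ValueError("invariance testing needs at least 2 groups")
    items = spec.items
    stats = []
    for lbl in labels:
        sub = table[table[group_col] == lbl]
        if len(sub) < min_group_n:
            raise ValueError(f"group {lbl!r} has n={len(sub)} < floor {min_group_n}")
        stats.append(compute_group_stats(sub, items, str(lbl), spec.estimator,
                                         n_categories=n_categories))
    fits: dict[str, MgFit] = {}
    decisions: dict[str, str] = {}
    rows = []
    prev = None
    for level in levels:
        fit = fit_multigroup(stats, spec, level)
        fits[level] = fit
        row = dict(model=level, chi2=fit.chi2, df=fit.df, cfi=fit.cfi,
                   rmsea=fit.rmsea, comparison="", dchi2=np.nan, ddf=np.nan,
                   p=np.nan)
        if not fit.converged:
            decisions[level] = "non-convergent (ladder truncated)"
            rows.append(row)
            break
        if prev is not None:
            dchi, ddf, p = chi2_diff(fit, fits[prev])
            row.update(comparison=f"{prev} vs {level}", dchi2=dchi, ddf=ddf, p=p)
            decisions[level] = "hold" if p >= alpha else "reject"
        else:
            decisions[level] = "hold"
        rows.append(row)
        prev = level
    comparisons = pd.DataFrame(rows).set_index("model")
    return InvarianceLadder(fits=fits, comparisons=comparisons,
                            decisions=decisions, stats=stats, spec=spec,
                            alpha=alpha)


def _level_pool(ladder: InvarianceLadder, level: str):
    spec = ladder.spec
    if level == "metric":
        return [("loading", e) for e in spec.edges()]
    if level == "scalar":
        return [("location", it) for it in spec.items]
    if level == "strict":
        return [("residual", it) for it in spec.items]
    raise ValueError(f"no constrained pool at level {level!r}")


def partial_release(ladder: InvarianceLadder, failing_level: str,
                    pool=None, max_freed: int = 4):
    """Greedy partial-invariance search at ``failing_level``.

    Repeatedly frees the constrained parameter whose release drops chi-square
    the most, re-testing against the previous level after each release.
    Returns (freed parameter list, final MgFit, decision string).
    """
    levels = list(ladder.fits)
    if failing_level not in levels or failing_level == "configural":
        raise ValueError(f"level {failing_level!r} not in the fitted ladder")
    prev_level = LEVELS[LEVELS.index(failing_level) - 1]
    prev_fit = ladder.fits[prev_level]
    pool = list(pool if pool is not None else _level_pool(ladder, failing_level))
    freed: list[tuple] = []
    current = ladder.fits[failing_level]

    def refit(extra):
        kinds = {"loading": [], "location": [], "residual": []}
        for kind, param in freed + ([extra] if extra else []):
            kinds[kind].append(param)
        return fit_multigroup(ladder.stats, ladder.spec, failing_level,
                              freed_loadings=kinds["loading"],
                              freed_locations=kinds["location"],
                              freed_residuals=kinds["residual"])

    if max_freed == 0:
        return freed, current, "partial invariance not established"
    while len(freed) < max_freed:
        if current.df <= prev_fit.df + 1:
            break
        _, _, p = chi2_diff(current, prev_fit)
        if p >= ladder.alpha:
            return freed, current, "partial invariance established"
        drops = []
        for cand in pool:
            if cand in freed:
                continue
            trial = refit(cand)
            drop = current.chi2 - trial.chi2 if trial.converged else -np.inf
            drops.append((drop, cand, trial))
        if not drops:
            break
        drops.sort(key=lambda t: -t[0])
        best_drop, best_cand, best_fit = drops[0]
        freed.append(best_cand)
        current = best_fit
    _, _, p = chi2_diff(current, prev_fit)
    if p >= ladder.alpha:
        return freed, current, "partial invariance established"
    return freed, current, "partial invariance not established"
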