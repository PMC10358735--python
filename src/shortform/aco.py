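"""Ant-colony-optimized item selection for short scales.

Candidate item subsets (k items per factor) are scored on five psychometric
criteria -- CFI and RMSEA of the subset's two-factor ordinal CFA, McDonald's
omega per factor, test-retest ICC per factor, and the mean absolute
deviation of covariate correlations from their validity targets.  Each raw
criterion value x is mapped to a pheromone contribution through a logistic
centered at the criterion's cut-off,

    phi_c = 1 / (1 + exp(-(x - threshold) / scale))     (sign flipped for
                                                         lower-is-better),

so phi_c = 0.5 exactly at the cut-off, and the overall pheromone is the
weighted sum Phi = sum_c w_c phi_c.  Ants sample item sets with probability
proportional to per-item pheromone, the global-best solution deposits its
Phi after each iteration (elitist scheme), and pheromone decays by the
retention multiplier (the evaporation rate).  An exhaustive enumerator over
all per-factor k-subsets serves as the optimality oracle when the candidate
space is small.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cfa
from .prep import polychoric_matrix
from .reliability import icc_retest, mcdonald_omega

__all__ = ["Criterion", "AcoConfig", "Solution", "AcoState", "SelectionBundle",
           "default_criteria", "evaluate_solution", "sample_itemset",
           "run_aco", "repeat_runs", "brute_force_optimum"]


@dataclass(frozen=True)
class Criterion:
    name: str
    extractor: str            # cfi | rmsea | omega_min | icc_min | covariate_dev
    direction: str            # "higher" | "lower"
    threshold: float
    scale: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.direction not in ("higher", "lower"):
            raise ValueError("direction must be 'higher' or 'lower'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    @property
    def effective_scale(self) -> float:
        if self.scale is not None:
            return self.scale
        return 0.10 * abs(self.threshold) / 2.0

    def pheromone(self, x: float) -> float:
        z = (x - self.threshold) / self.effective_scale
        if self.direction == "lower":
            z = -z
        return float(1.0 / (1.0 + np.exp(-z)))


def default_criteria() -> list[Criterion]:
    """The five standard criteria: CFI >= 0.96, RMSEA <= 0.05, omega >= 0.85,
    ICC >= 0.70, mean covariate deviation <= 0.15 (tolerance-derived scale)."""
    return [
        Criterion("cfi", "cfi", "higher", 0.96),
        Criterion("rmsea", "rmsea", "lower", 0.05),
        Criterion("omega", "omega_min", "higher", 0.85),
        Criterion("icc", "icc_min", "higher", 0.70),
        Criterion("covariate_dev", "covariate_dev", "lower", 0.15, scale=0.075),
    ]


@dataclass
class AcoConfig:
    k_per_factor: int = 2
    n_ants: int = 40
    n_iterations: int = 30
    evaporation: float = 0.70       # retention multiplier: tau <- 0.70 tau + deposit
    n_runs: int = 5
    patience: int = 10
    pheromone_floor: float = 0.01
    seed: int = 0
    deposit_on: str = "global_best"  # or "iteration_best"
    brute_force_cap: int = 10_000

    def __post_init__(self):
        if self.k_per_factor < 1:
            raise ValueError("need k >= 1 items per factor")
        if not (0 < self.evaporation <= 1):
            raise ValueError("evaporation must lie in (0, 1]")
        if min(self.n_ants, self.n_iterations, self.n_runs) < 1:
            raise ValueError("n_ants, n_iterations, n_runs must be >= 1")
        if self.deposit_on not in ("global_best", "iteration_best"):
            raise ValueError("deposit_on must be 'global_best' or 'iteration_best'")


@dataclass
class Solution:
    items: dict[str, tuple[str, ...]]
    raw: dict[str, float]
    phi: dict[str, float]
    total_phi: float
    converged: bool = True

    @property
    def key(self) -> tuple:
        return tuple((f, tuple(sorted(its))) for f, its in sorted(self.items.items()))

    def to_dict(self) -> dict:
        return {"items": {f: list(v) for f, v in self.items.items()},
                "raw": self.raw, "phi": self.phi,
                "total_phi": self.total_phi, "converged": self.converged}


@dataclass
class AcoState:
    tau: dict[str, float]
    iteration: int = 0
    best: Solution | None = None
    trace: list[dict] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        """Iteration trace (iteration, best Phi, best item set) for CSV export."""
        rows = [{"iteration": t["iteration"], "best_phi": t.get("best_phi"),
                 "best_items": str(t.get("best_items", ""))}
                for t in self.trace]
        return pd.DataFrame(rows)


@dataclass
class SelectionBundle:
    """Everything a solution evaluation needs: aligned waves, pools, targets."""

    wave1: pd.DataFrame
    wave2: pd.DataFrame | None
    pools: dict[str, tuple[str, ...]]
    covariate_targets: dict[str, float]
    reverse_items: tuple[str, ...] = ()
    max_code: int = 4
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame, pools: dict[str, tuple[str, ...]],
                   covariate_targets: dict[str, float],
                   reverse_items: tuple[str, ...] = (), max_code: int = 4):
        w1 = table[table["wave"] == 1].set_index("person").sort_index()
        w2 = None
        if (table["wave"] == 2).any():
            w2 = table[table["wave"] == 2].set_index("person").sort_index()
            common = w1.index.intersection(w2.index)
            w1, w2 = w1.loc[common], w2.loc[common]
        return cls(wave1=w1, wave2=w2, pools={f: tuple(p) for f, p in pools.items()},
                   covariate_targets=dict(covariate_targets),
                   reverse_items=tuple(reverse_items), max_code=max_code)

    def keyed_total(self, frame: pd.DataFrame, items: list[str]) -> pd.Series:
        block = frame.loc[:, items].astype(float).copy()
        for it in items:
            if it in self.reverse_items:
                block[it] = self.max_code - block[it]
        return block.sum(axis=1, skipna=False)


def _two_item_omega(r: float) -> float:
    if r <= 0:
        return 0.0
    return mcdonald_omega(np.array([np.sqrt(r)] * 2), np.array([1 - r] * 2))


def evaluate_solution(items_per_factor: dict[str, tuple[str, ...]],
                      bundle: SelectionBundle,
                      criteria: list[Criterion]) -> Solution:
    """Score one candidate subset on all criteria.

    Fits the subset's CFA (two-factor when two pools are given, one-factor
    otherwise) on wave-1 polychorics, computes per-factor omega (worst
    factor), per-factor retest ICC on sum scores (worst factor), and the
    mean absolute deviation of the stress-keyed total's covariate
    correlations from their targets.  CFA non-convergence yields Phi = 0.
    """
    items_per_factor = {f: tuple(its) for f, its in items_per_factor.items()}
    key = tuple((f, tuple(sorted(its))) for f, its in sorted(items_per_factor.items()))
    if key in bundle._cache:
        return bundle._cache[key]

    all_items = [it for its in items_per_factor.values() for it in its]
    if len(set(all_items)) != len(all_items):
        raise ValueError("item sets must be disjoint across factors")

    est = polychoric_matrix(bundle.wave1, all_items,
                            n_categories=bundle.max_code + 1)
    spec = cfa.ModelSpec(factors=items_per_factor, estimator="dwls")
    fit = cfa.fit_cfa(est, spec)

    raw: dict[str, float] = {}
    if not fit.converged:
        sol = Solution(items=items_per_factor, raw={}, phi={}, total_phi=0.0,
                       converged=False)
        bundle._cache[key] = sol
        return sol
    raw["cfi"], raw["rmsea"] = fit.cfi, fit.rmsea

    omegas, iccs = [], []
    for f, its in items_per_factor.items():
        idx = [all_items.index(i) for i in its]
        if len(its) == 2:
            omegas.append(_two_item_omega(float(est.matrix[idx[0], idx[1]])))
        else:
            sub = cfa.fit_cfa(est, cfa.ModelSpec(factors={f: its}, estimator="dwls"))
            lam = sub.loadings[f].to_numpy()
            lam = np.abs(lam) if lam.sum() < 0 else lam
            omegas.append(mcdonald_omega(lam, np.clip(sub.theta, 0, None)))
        if bundle.wave2 is not None:
            s1 = bundle.wave1.loc[:, list(its)].sum(axis=1)
            s2 = bundle.wave2.loc[:, list(its)].sum(axis=1)
            iccs.append(icc_retest(s1, s2))
    raw["omega_min"] = float(min(omegas))
    raw["icc_min"] = float(min(iccs)) if iccs else np.nan

    if bundle.covariate_targets:
        total = bundle.keyed_total(bundle.wave1, all_items)
        devs = []
        for name, target in bundle.covariate_targets.items():
            obs = float(np.corrcoef(total, bundle.wave1[name])[0, 1])
            devs.append(abs(obs - target))
        raw["covariate_dev"] = float(np.mean(devs))

    phi = {c.name: c.pheromone(raw[c.extractor]) for c in criteria
           if c.extractor in raw and np.isfinite(raw[c.extractor])}
    total_phi = float(sum(c.weight * phi[c.name] for c in criteria
                          if c.name in phi))
    sol = Solution(items=items_per_factor, raw=raw, phi=phi, total_phi=total_phi)
    bundle._cache[key] = sol
    return sol


def sample_itemset(state: AcoState, pools: dict[str, tuple[str, ...]],
                   k: int, rng: np.random.Generator) -> dict[str, tuple[str, ...]]:
    """Draw k distinct items per factor, sequentially, proportional to tau."""
    out = {}
    for f, pool in pools.items():
        if len(pool) < k:
            raise ValueError(f"pool for factor {f!r} smaller than k={k}")
        avail = list(pool)
        chosen = []
        for _ in range(k):
            w = np.array([state.tau[i] for i in avail])
            probs = w / w.sum()
            pick = rng.choice(len(avail), p=probs)
            chosen.append(avail.pop(pick))
        out[f] = tuple(chosen)
    return out


def run_aco(config: AcoConfig, bundle: SelectionBundle,
            criteria: list[Criterion], seed: int | None = None):
    """One ACO run; returns (best Solution, AcoState with iteration trace)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    all_pool = [it for pool in bundle.pools.values() for it in pool]
    state = AcoState(tau={it: 1.0 for it in all_pool})
    unchanged = 0
    for it_num in range(config.n_iterations):
        state.iteration = it_num + 1
        iter_best: Solution | None = None
        any_converged = False
        for _ in range(config.n_ants):
            cand = sample_itemset(state, bundle.pools, config.k_per_factor, rng)
            sol = evaluate_solution(cand, bundle, criteria)
            if not sol.converged:
                continue
            any_converged = True
            if iter_best is None or sol.total_phi > iter_best.total_phi:
                iter_best = sol
        if not any_converged:
            state.trace.append({"iteration": state.iteration, "best_phi": None,
                                "note": "all ants non-convergent"})
            continue
        improved = state.best is None or iter_best.total_phi > state.best.total_phi
        if improved:
            state.best = iter_best
            unchanged = 0
        else:
            unchanged += 1
        # evaporation as retention multiplier, then elitist deposit
        depositor = state.best if config.deposit_on == "global_best" else iter_best
        for item in state.tau:
            state.tau[item] *= config.evaporation
        for its in depositor.items.values():
            for item in its:
                state.tau[item] += depositor.total_phi
        for item in state.tau:
            state.tau[item] = max(state.tau[item], config.pheromone_floor)
        state.trace.append({"iteration": state.iteration,
                            "best_phi": state.best.total_phi,
                            "best_items": state.best.key})
        if unchanged >= config.patience:
            break
    return state.best, state


def repeat_runs(config: AcoConfig, bundle: SelectionBundle,
                criteria: list[Criterion]):
    """Independently seeded runs; returns (modal Solution, per-run bests,
    consistency count = multiplicity of the modal item set)."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    bests = []
    for s in seeds:
        child = int(np.random.default_rng(s).integers(0, 2**31 - 1))
        best, _ = run_aco(config, bundle, criteria, seed=child)
        bests.append(best)
    keys = [b.key for b in bests]
    counts: dict = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    modal_keys = [k for k, c in counts.items() if c == top]
    candidates = [b for b in bests if b.key in modal_keys]
    modal = max(candidates, key=lambda b: b.total_phi)
    return modal, bests, counts[modal.key]


def brute_force_optimum(bundle: SelectionBundle, criteria: list[Criterion],
                        k: int, cap: int = 10_000) -> Solution:
    """Exhaustive enumeration of all per-factor k-subsets; deterministic argmax.

    Ties in Phi break lexicographically on the item names, so the result is
    reproducible regardless of enumeration order.
    """
    pools = bundle.pools
    combos = [list(itertools.combinations(pool, k)) for pool in pools.values()]
    total = int(np.prod([len(c) for c in combos]))
    if total > cap:
        raise ValueError(f"{total} candidates exceed cap {cap}; use run_aco")
    best: Solution | None = None
    for picks in itertools.product(*combos):
        cand = dict(zip(pools.keys(), picks))
        sol = evaluate_solution(cand, bundle, criteria)
        if not sol.converged:
            continue
        if (best is None or sol.total_phi > best.total_phi
                or (sol.total_phi == best.total_phi and sol.key < best.key)):
            best = sol
    return best
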