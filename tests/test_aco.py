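"""Ant-colony selection: sampling law, pheromone mapping, oracle equivalence."""

import itertools

import numpy as np
import pytest
from scipy import stats

from shortform import aco
from tests.conftest import make_bundle


class TestCriterion:
    def test_pheromone_is_half_at_threshold(self, criteria):
        at_threshold = {"cfi": 0.96, "rmsea": 0.05, "omega_min": 0.85,
                        "icc_min": 0.70, "covariate_dev": 0.15}
        total = sum(c.pheromone(at_threshold[c.extractor]) for c in criteria)
        assert total == pytest.approx(2.5)

    def test_direction_handling(self):
        higher = aco.Criterion("c", "cfi", "higher", 0.96)
        lower = aco.Criterion("r", "rmsea", "lower", 0.05)
        assert higher.pheromone(0.99) > 0.5 > higher.pheromone(0.90)
        assert lower.pheromone(0.01) > 0.5 > lower.pheromone(0.10)

    def test_exact_covariate_match_has_zero_deviation(self, marker_bundle,
                                                      criteria, marker_brute):
        # the deviation extractor is a mean of absolute differences, so a
        # solution matching all three targets exactly would score 0; the
        # planted bundle comes close
        assert marker_brute.raw["covariate_dev"] < 0.05
        dev_crit = [c for c in criteria if c.extractor == "covariate_dev"][0]
        assert dev_crit.pheromone(0.0) > 0.85

    def test_invalid_criterion_rejected(self):
        with pytest.raises(ValueError):
            aco.Criterion("c", "cfi", "sideways", 0.9)
        with pytest.raises(ValueError):
            aco.Criterion("c", "cfi", "higher", 0.9, scale=-1.0)

    def test_phi_monotone_in_each_criterion(self, criteria):
        base = {"cfi": 0.97, "rmsea": 0.04, "omega_min": 0.86,
                "icc_min": 0.72, "covariate_dev": 0.10}
        better = {"cfi": 0.99, "rmsea": 0.02, "omega_min": 0.90,
                  "icc_min": 0.80, "covariate_dev": 0.02}
        for c in criteria:
            improved = dict(base)
            improved[c.extractor] = better[c.extractor]
            phi0 = sum(k.pheromone(base[k.extractor]) for k in criteria)
            phi1 = sum(k.pheromone(improved[k.extractor]) for k in criteria)
            assert phi1 >= phi0


class TestSampling:
    def test_uniform_tau_gives_uniform_pairs(self):
        state = aco.AcoState(tau={f"i{k}": 1.0 for k in range(7)})
        pools = {"f": tuple(f"i{k}" for k in range(7))}
        rng = np.random.default_rng(0)
        counts = {}
        n_draws = 40_000
        for _ in range(n_draws):
            picked = aco.sample_itemset(state, pools, 2, rng)["f"]
            key = tuple(sorted(picked))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 21
        observed = np.array([counts[k] for k in sorted(counts)])
        chi2, p = stats.chisquare(observed)
        assert p > 0.01

    def test_concentrated_tau_dominates(self):
        tau = {f"i{k}": 0.01 for k in range(7)}
        tau["i0"] = 1e4
        state = aco.AcoState(tau=tau)
        pools = {"f": tuple(f"i{k}" for k in range(7))}
        rng = np.random.default_rng(1)
        hits = sum("i0" in aco.sample_itemset(state, pools, 2, rng)["f"]
                   for _ in range(2000))
        assert hits / 2000 > 0.999

    def test_sequential_sampling_distribution_sums_to_one(self):
        # exhaustive enumeration of the sequential no-replacement law
        tau = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5}
        names = list(tau)
        prob = {}
        for first, second in itertools.permutations(names, 2):
            p1 = tau[first] / sum(tau.values())
            rest = sum(v for k, v in tau.items() if k != first)
            p2 = tau[second] / rest
            key = tuple(sorted((first, second)))
            prob[key] = prob.get(key, 0.0) + p1 * p2
        assert sum(prob.values()) == pytest.approx(1.0)

    def test_pool_smaller_than_k_rejected(self):
        state = aco.AcoState(tau={"a": 1.0})
        with pytest.raises(ValueError, match="smaller than k"):
            aco.sample_itemset(state, {"f": ("a",)}, 2,
                               np.random.default_rng(0))


class TestEvaluate:
    def test_planted_markers_score_near_brute_force_max(self, marker_bundle,
                                                        criteria, marker_brute):
        planted = {"helplessness": ("item01", "item02"),
                   "self_efficacy": ("item04", "item05")}
        sol = aco.evaluate_solution(planted, marker_bundle, criteria)
        assert sol.total_phi >= marker_brute.total_phi - 0.05

    def test_duplicate_items_across_factors_rejected(self, marker_bundle, criteria):
        with pytest.raises(ValueError, match="disjoint"):
            aco.evaluate_solution({"helplessness": ("item01", "item02"),
                                   "self_efficacy": ("item01", "item04")},
                                  marker_bundle, criteria)

    def test_evaluation_is_cached(self, marker_bundle, criteria):
        sel = {"helplessness": ("item03", "item08"),
               "self_efficacy": ("item06", "item07")}
        s1 = aco.evaluate_solution(sel, marker_bundle, criteria)
        s2 = aco.evaluate_solution(sel, marker_bundle, criteria)
        assert s1 is s2


class TestRunAco:
    def test_fixed_seed_reproduces_trace(self, marker_bundle, criteria):
        cfg = aco.AcoConfig(n_ants=8, n_iterations=4, seed=2)
        b1, s1 = aco.run_aco(cfg, marker_bundle, criteria)
        b2, s2 = aco.run_aco(cfg, marker_bundle, criteria)
        assert b1.key == b2.key
        assert [t.get("best_phi") for t in s1.trace] == \
            [t.get("best_phi") for t in s2.trace]

    def test_single_candidate_pool_returns_it_immediately(self, marker_model,
                                                          criteria):
        bundle = make_bundle(marker_model, seed=4, n=400)
        bundle.pools = {"helplessness": ("item01", "item02"),
                        "self_efficacy": ("item04", "item05")}
        cfg = aco.AcoConfig(n_ants=3, n_iterations=1, seed=0)
        best, state = aco.run_aco(cfg, bundle, criteria)
        assert best.items == {"helplessness": ("item01", "item02"),
                              "self_efficacy": ("item04", "item05")} or \
            best.key == (("helplessness", ("item01", "item02")),
                         ("self_efficacy", ("item04", "item05")))
        assert state.iteration == 1

    def test_global_best_phi_nondecreasing(self, marker_bundle, criteria):
        cfg = aco.AcoConfig(n_ants=10, n_iterations=8, seed=3)
        _, state = aco.run_aco(cfg, marker_bundle, criteria)
        phis = [t["best_phi"] for t in state.trace if t.get("best_phi")]
        assert all(b >= a for a, b in zip(phis, phis[1:]))

    def test_pheromone_floor_respected(self, marker_bundle, criteria):
        cfg = aco.AcoConfig(n_ants=10, n_iterations=10, seed=5,
                            pheromone_floor=0.01)
        _, state = aco.run_aco(cfg, marker_bundle, criteria)
        assert min(state.tau.values()) >= 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            aco.AcoConfig(evaporation=0.0)
        with pytest.raises(ValueError):
            aco.AcoConfig(n_ants=0)


class TestRepeatRuns:
    def test_single_run_consistency_is_one(self, marker_bundle, criteria):
        cfg = aco.AcoConfig(n_ants=6, n_iterations=3, n_runs=1, seed=9)
        _, bests, consistency = aco.repeat_runs(cfg, marker_bundle, criteria)
        assert len(bests) == 1 and consistency == 1

    def test_same_master_seed_reproduces_runs(self, marker_bundle, criteria):
        cfg = aco.AcoConfig(n_ants=6, n_iterations=3, n_runs=2, seed=9)
        m1, b1, c1 = aco.repeat_runs(cfg, marker_bundle, criteria)
        m2, b2, c2 = aco.repeat_runs(cfg, marker_bundle, criteria)
        assert m1.key == m2.key and c1 == c2
        assert [b.key for b in b1] == [b.key for b in b2]


class TestBruteForce:
    def test_enumerates_all_441_candidates(self, marker_bundle, criteria,
                                           marker_brute):
        # C(7,2)^2 = 441 distinct subsets end up in the evaluation cache
        keys = {k for k in marker_bundle._cache}
        assert len(keys) >= 441
        assert marker_brute.total_phi > 0

    def test_optimum_beats_random_subsets(self, marker_bundle, criteria,
                                          marker_brute):
        rng = np.random.default_rng(0)
        pools = marker_bundle.pools
        for _ in range(200):
            cand = {f: tuple(rng.choice(pool, 2, replace=False))
                    for f, pool in pools.items()}
            sol = aco.evaluate_solution(cand, marker_bundle, criteria)
            assert marker_brute.total_phi >= sol.total_phi - 1e-9

    def test_candidate_space_above_cap_rejected(self, marker_bundle, criteria):
        with pytest.raises(ValueError, match="cap"):
            aco.brute_force_optimum(marker_bundle, criteria, k=2, cap=100)

    def test_unconstrained_selection_prefers_dominant_factor(self, criteria):
        # without the per-factor restriction, a one-factor evaluation on a
        # pool with one dominant factor picks only items of that factor
        from shortform import simulate as sim
        help_items = [f"h{i}" for i in range(7)]
        weak_items = [f"s{i}" for i in range(7)]
        m = sim.build_population_model({
            "factors": {
                "helplessness": dict(zip(help_items,
                                         [0.92, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65])),
                "self_efficacy": dict(zip(weak_items, [0.45] * 7)),
            },
            "factor_corr": -0.37,
            "retest_stability": [0.85, 0.85],
        })
        bundle = make_bundle(m, seed=6, n=800)
        bundle.pools = {"stress": tuple(help_items + weak_items)}
        bundle.covariate_targets = {}
        best = aco.brute_force_optimum(bundle, criteria, k=4, cap=1001)
        assert set(best.items["stress"]) <= set(help_items)
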