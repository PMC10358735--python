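"""CFA engine: recovery oracles, fit-index identities, difference tests."""

import numpy as np
import pytest

from shortform import cfa, simulate as sim
from shortform.prep import CorrelationEstimate


def two_factor_spec(model, estimator="dwls"):
    factors = {f: tuple(model.items[i] for i in range(len(model.items))
                        if model.loading_matrix[i, j] != 0)
               for j, f in enumerate(model.factors)}
    return cfa.ModelSpec(factors=factors, estimator=estimator)


def exact_estimate(model, n=1437):
    return CorrelationEstimate(items=model.items,
                               matrix=model.implied_latent_corr(),
                               method="polychoric", n=n)


class TestFitCfa:
    def test_just_identified_one_factor_is_saturated(self):
        m = sim.build_population_model(
            {"factors": {"f": {"a": 0.8, "b": 0.7, "c": 0.6}}})
        fit = cfa.fit_cfa(exact_estimate(m), cfa.ModelSpec(factors={"f": ("a", "b", "c")}))
        assert fit.df == 0
        assert fit.chi2 == 0.0
        assert fit.rmsea == 0.0 and "saturated" in fit.note

    def test_recovers_population_loadings_from_exact_matrix(self, pss_model):
        fit = cfa.fit_cfa(exact_estimate(pss_model), two_factor_spec(pss_model))
        assert fit.converged and fit.chi2 < 1e-6
        for j, f in enumerate(pss_model.factors):
            for i, item in enumerate(pss_model.items):
                true = pss_model.loading_matrix[i, j]
                if true != 0:
                    est = abs(fit.loadings.loc[item, f])
                    assert est == pytest.approx(abs(true), abs=1e-4)
        got = fit.factor_corr.iloc[0, 1]
        assert abs(got) == pytest.approx(0.37, abs=1e-4)

    def test_two_items_per_factor_identified_via_factor_correlation(self, pss_table):
        spec = cfa.ModelSpec(factors={"h": ("item01", "item02"),
                                      "s": ("item06", "item07")})
        fit = cfa.fit_cfa(pss_table[pss_table.wave == 1], spec)
        assert fit.converged
        assert fit.df == 1

    def test_single_standalone_factor_with_two_items_rejected(self):
        m = sim.build_population_model({"factors": {"f": {"a": 0.8, "b": 0.7}}})
        with pytest.raises(ValueError, match="indicators|under-identified"):
            cfa.fit_cfa(exact_estimate(m), cfa.ModelSpec(factors={"f": ("a", "b")}))

    def test_singular_matrix_rejected(self):
        mat = np.ones((3, 3))
        est = CorrelationEstimate(items=["a", "b", "c"], matrix=mat,
                                  method="pearson", n=100)
        with pytest.raises(ValueError, match="singular"):
            cfa.fit_cfa(est, cfa.ModelSpec(factors={"f": ("a", "b", "c")}))

    def test_ml_and_dwls_loadings_agree_on_symmetric_items(self, pss_model):
        tab = sim.generate(pss_model, sim.SimConfig(
            n=20_000, seed=31, waves=1, missing_rate=0.0))
        spec_d = two_factor_spec(pss_model, "dwls")
        spec_m = two_factor_spec(pss_model, "ml")
        fit_d = cfa.fit_cfa(tab, spec_d)
        fit_m = cfa.fit_cfa(tab, spec_m)
        # ML on Pearson correlations is attenuated relative to the polychoric
        # solution; rank order and rough magnitude must agree
        for f in pss_model.factors:
            ld = fit_d.loadings[f][fit_d.loadings[f] != 0].abs()
            lm = fit_m.loadings[f][fit_m.loadings[f] != 0].abs()
            assert np.corrcoef(ld, lm)[0, 1] > 0.98

    def test_fit_self_consistency_of_indices(self, pss_table):
        fit = cfa.fit_cfa(pss_table[pss_table.wave == 1],
                          cfa.ModelSpec(factors={"h": ("item01", "item02", "item03"),
                                                 "s": ("item06", "item07", "item10")}))
        cfi, rmsea, _ = cfa.fit_indices(fit.chi2, fit.df, fit.chi2_baseline,
                                        fit.df_baseline, fit.n)
        assert fit.cfi == pytest.approx(cfi)
        assert fit.rmsea == pytest.approx(rmsea)


class TestFitIndices:
    def test_perfect_fit(self):
        cfi, rmsea, _ = cfa.fit_indices(77, 77, 4000, 91, 1437)
        assert cfi == 1.0 and rmsea == 0.0

    def test_worked_example(self):
        # direct evaluation of both formulas
        cfi, rmsea, _ = cfa.fit_indices(150, 77, 4000, 91, 1437)
        assert cfi == pytest.approx(0.9813, abs=5e-5)
        assert rmsea == pytest.approx(0.0257, abs=5e-5)

    def test_cfi_floor_when_baseline_better(self):
        cfi, _, _ = cfa.fit_indices(100, 10, 50, 40, 500)
        assert cfi == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cfa.fit_indices(-1, 10, 100, 20, 100)


class TestChi2Diff:
    def test_identical_fits(self):
        d, ddf, p = cfa.chi2_diff((10.0, 5), (10.0, 3))
        assert d == 0.0 and p == 1.0

    @pytest.mark.parametrize("dchi,ddf,expected,tol", [
        (10.4, 10, 0.407, 1.5e-3),   # printed inputs rounded to 1 decimal
        (8.4, 2, 0.015, 5e-4),
    ])
    def test_published_difference_tests(self, dchi, ddf, expected, tol):
        _, _, p = cfa.chi2_diff((100.0 + dchi, 10 + ddf), (100.0, 10))
        assert p == pytest.approx(expected, abs=tol)

    def test_non_positive_ddf_rejected(self):
        with pytest.raises(ValueError):
            cfa.chi2_diff((10.0, 3), (8.0, 3))


class TestModificationCandidates:
    def test_perfect_model_has_no_meaningful_drops(self, pss_model):
        est = exact_estimate(pss_model)
        spec = two_factor_spec(pss_model)
        fit = cfa.fit_cfa(est, spec)
        pool = [("item01", "self_efficacy"), ("item06", "helplessness")]
        ranked = cfa.modification_candidates(fit, est, pool)
        assert all(drop < 0.1 for _, drop in ranked)

    def test_planted_cross_loading_ranks_first(self):
        # population with an omitted cross-loading of 0.4: "c" also loads on "g"
        lam = np.array([[0.8, 0.0], [0.75, 0.0], [0.6, 0.4],
                        [0.0, 0.8], [0.0, 0.75], [0.0, 0.7]])
        m = sim.PopulationModel(
            items=list("abcdeh"), factors=["f", "g"], loading_matrix=lam,
            factor_corr=np.array([[1.0, 0.3], [0.3, 1.0]]),
            thresholds=np.tile(sim.DEFAULT_THRESHOLDS, (6, 1)))
        tab = sim.generate(m, sim.SimConfig(n=20_000, seed=13, waves=1,
                                            missing_rate=0.0))
        spec = cfa.ModelSpec(factors={"f": ("a", "b", "c"), "g": ("d", "e", "h")})
        fit = cfa.fit_cfa(tab, spec)
        pool = [(it, f) for it, f in
                [("a", "g"), ("b", "g"), ("c", "g"),
                 ("d", "f"), ("e", "f"), ("h", "f")]]
        ranked = cfa.modification_candidates(fit, tab, pool)
        assert ranked[0][0] == ("c", "g")

    def test_empty_pool_rejected(self, pss_model):
        fit = cfa.fit_cfa(exact_estimate(pss_model), two_factor_spec(pss_model))
        with pytest.raises(ValueError, match="empty"):
            cfa.modification_candidates(fit, exact_estimate(pss_model), [])


class TestProperties:
    def test_freeing_a_parameter_never_increases_chi2(self, pss_table):
        w1 = pss_table[pss_table.wave == 1]
        base = cfa.ModelSpec(factors={"h": ("item01", "item02", "item03"),
                                      "s": ("item06", "item07", "item10")})
        freer = cfa.ModelSpec(factors=base.factors,
                              cross_loadings=(("item01", "s"),))
        f0 = cfa.fit_cfa(w1, base)
        f1 = cfa.fit_cfa(w1, freer)
        assert f1.chi2 <= f0.chi2 + 1e-6
        assert f0.fmin >= 0 and f1.fmin >= 0
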