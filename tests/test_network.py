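"""Network estimation: transform, EBIC path, centralities, stability."""

import numpy as np
import pandas as pd
import pytest

from shortform import network as net


def chain_precision(p=5, off=-0.35):
    om = np.eye(p)
    for i in range(p - 1):
        om[i, i + 1] = om[i + 1, i] = off
    return om


def sample_from_precision(om, n, seed=0):
    cov = np.linalg.inv(om)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(len(om)), cov, n)


@pytest.fixture(scope="module")
def chain_data():
    return sample_from_precision(chain_precision(), 10_000, seed=0)


class TestNpnTransform:
    def test_normal_column_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.standard_normal(10_000)})
        z = net.npn_transform(df)
        assert np.corrcoef(z["a"], df["a"])[0, 1] > 0.99

    def test_output_standardized_and_rank_preserving(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"b": rng.exponential(size=5000)})
        z = net.npn_transform(df)
        assert abs(z["b"].mean()) < 0.05
        assert z["b"].var() == pytest.approx(1.0, abs=0.05)
        order = np.argsort(df["b"].to_numpy())
        assert (np.diff(z["b"].to_numpy()[order]) >= 0).all()

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"ok": np.arange(30.0), "flat": np.ones(30)})
        with pytest.raises(ValueError, match="flat"):
            net.npn_transform(df)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 20"):
            net.npn_transform(pd.DataFrame({"a": np.arange(10.0)}))


class TestEbicGlasso:
    def test_planted_chain_support_recovered(self, chain_data):
        S = np.corrcoef(chain_data, rowvar=False)
        res = net.ebic_glasso(S, n=len(chain_data), gamma=0.25)
        iu = np.triu_indices(5, 1)
        selected = np.abs(res.weights[iu]) > 1e-6
        truth = np.abs(chain_precision()[iu]) > 0
        assert (selected == truth).all()

    def test_identity_input_gives_empty_graph(self):
        res = net.ebic_glasso(np.eye(4), n=1000, gamma=0.25)
        assert res.n_edges == 0
        assert np.abs(res.weights).max() == 0.0

    def test_lambda_max_end_of_path_is_empty(self, chain_data):
        S = np.corrcoef(chain_data, rowvar=False)
        res = net.ebic_glasso(S, n=len(chain_data), gamma=0.25)
        first = res.path.iloc[0]
        assert first["n_edges"] == 0

    def test_edge_count_monotone_along_path(self, chain_data):
        S = np.corrcoef(chain_data, rowvar=False)
        res = net.ebic_glasso(S, n=len(chain_data), gamma=0.25)
        by_lam = res.path.sort_values("lam", ascending=False)
        assert (np.diff(by_lam["n_edges"].to_numpy()) >= 0).all()

    def test_selected_network_no_denser_than_path_end(self, chain_data):
        S = np.corrcoef(chain_data, rowvar=False)
        res = net.ebic_glasso(S, n=len(chain_data), gamma=0.25)
        assert res.n_edges <= res.path.iloc[-1]["n_edges"]

    def test_ebic_equals_bic_at_gamma_zero(self, chain_data):
        S = np.corrcoef(chain_data, rowvar=False)
        res = net.ebic_glasso(S, n=len(chain_data), gamma=0.0)
        bic = -2 * res.path["loglik"] + res.path["n_edges"] * np.log(len(chain_data))
        assert np.allclose(bic, res.path["ebic"])

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            net.ebic_glasso(np.eye(3), n=100, gamma=-0.1)


class TestPartialCorr:
    def test_identity_gives_zero(self):
        assert np.abs(net.partial_corr_from_precision(np.eye(4))).max() == 0

    def test_chain_markov_property(self):
        om = chain_precision(3)
        w = net.partial_corr_from_precision(om)
        assert w[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        om = np.array([[2.0, 0.5, 0.3], [0.5, 1.5, -0.4], [0.3, -0.4, 1.8]])
        w = net.partial_corr_from_precision(om)
        x = sample_from_precision(om, 400_000, seed=3)
        ones = np.ones((len(x), 1))

        def residual_corr(a, b, c):
            za = np.column_stack([ones, x[:, [c]]])
            ra = x[:, a] - za @ np.linalg.lstsq(za, x[:, a], rcond=None)[0]
            rb = x[:, b] - za @ np.linalg.lstsq(za, x[:, b], rcond=None)[0]
            return np.corrcoef(ra, rb)[0, 1]

        assert w[0, 1] == pytest.approx(residual_corr(0, 1, 2), abs=0.01)
        assert w[0, 2] == pytest.approx(residual_corr(0, 2, 1), abs=0.01)
        assert w[1, 2] == pytest.approx(residual_corr(1, 2, 0), abs=0.01)

    def test_non_pd_rejected(self):
        om = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            net.partial_corr_from_precision(om)


class TestCentrality:
    def test_star_graph(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.5
        c = net.centrality_indices(w)
        assert c["strength"].iloc[0] == pytest.approx(2.0)
        assert np.allclose(c["strength"].iloc[1:], 0.5)
        assert c["betweenness"].iloc[0] == 6  # all leaf pairs route via hub

    def test_chain_betweenness(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.4
        c = net.centrality_indices(w)
        assert c["betweenness"].iloc[1] > 0
        assert c["betweenness"].iloc[0] == 0 == c["betweenness"].iloc[2]

    def test_disconnected_graph_all_zero(self):
        c = net.centrality_indices(np.zeros((4, 4)))
        assert (c.to_numpy() == 0).all()


class TestBootstrap:
    def test_planted_edges_separated_from_nulls(self):
        x = sample_from_precision(chain_precision(), 2500, seed=7)
        df = pd.DataFrame(x, columns=list("abcde"))
        ci = net.bootstrap_edges(df, B=120, seed=1, n_lambdas=25)
        truth = chain_precision()
        n_null_cover = 0
        n_null = 0
        for _, row in ci.iterrows():
            i, j = "abcde".index(row.node1), "abcde".index(row.node2)
            if truth[i, j] != 0:
                assert not (row.ci_lower <= 0 <= row.ci_upper)
            else:
                n_null += 1
                n_null_cover += row.ci_lower <= 0 <= row.ci_upper
        assert n_null_cover / n_null >= 0.9

    def test_low_draw_count_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((100, 3)))
        with pytest.raises(ValueError, match="100 bootstrap"):
            net.bootstrap_edges(df, B=50)


class TestCaseDrop:
    def test_strong_stable_structure_maximally_stable(self):
        # clearly ordered centralities at large n survive any tested drop
        x = sample_from_precision(chain_precision(off=-0.4), 8000, seed=5)
        df = pd.DataFrame(x, columns=list("abcde"))
        cs = net.casedrop_stability(df, "strength", drop_grid=(0.25, 0.5, 0.75),
                                    B=20, seed=2, n_lambdas=20)
        assert cs == 0.75

    def test_pure_noise_network_unstable(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((600, 5)),
                          columns=list("abcde"))
        cs = net.casedrop_stability(df, "strength", drop_grid=(0.25, 0.5),
                                    B=20, seed=3, n_lambdas=20)
        assert cs == 0.0

    def test_empty_grid_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((100, 3)))
        with pytest.raises(ValueError, match="grid"):
            net.casedrop_stability(df, "strength", drop_grid=())
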