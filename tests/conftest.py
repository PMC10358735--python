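import pytest

from shortform import aco, simulate as sim


@pytest.fixture(scope="session")
def pss_model():
    return sim.pss14_model()


@pytest.fixture(scope="session")
def marker_model():
    return sim.marker_model()


@pytest.fixture(scope="session")
def pss_table(pss_model):
    """Two-wave table at the study sample size, no missingness."""
    cfg = sim.SimConfig(n=1437, seed=7, waves=2, missing_rate=0.0)
    return sim.generate(pss_model, cfg)


@pytest.fixture(scope="session")
def big_wave1(pss_model):
    """Large single-wave table for Monte-Carlo moment checks."""
    cfg = sim.SimConfig(n=100_000, seed=19, waves=1, missing_rate=0.0)
    return sim.generate(pss_model, cfg)


def make_bundle(model, seed, n=1437):
    table = sim.generate(model, sim.SimConfig(n=n, seed=seed, waves=2,
                                              missing_rate=0.0))
    pools = {f: tuple(model.items[i] for i in range(len(model.items))
                      if model.loading_matrix[i, j] != 0)
             for j, f in enumerate(model.factors)}
    targets = {c.name: c.target_r for c in model.covariates}
    return aco.SelectionBundle.from_table(
        table, pools, targets, reverse_items=model.reverse_items,
        max_code=model.thresholds.shape[1])


@pytest.fixture(scope="session")
def marker_bundle(marker_model):
    """Planted-optimum selection bundle (markers on items 1,2 and 4,5)."""
    return make_bundle(marker_model, seed=11)


@pytest.fixture(scope="session")
def criteria():
    return aco.default_criteria()


@pytest.fixture(scope="session")
def marker_brute(marker_bundle, criteria):
    """Brute-force optimum on the planted bundle (shared across tests)."""
    return aco.brute_force_optimum(marker_bundle, criteria, k=2)
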