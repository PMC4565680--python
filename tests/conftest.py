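import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from te_evoscan.simulate import SimParams, simulate_host_tree, simulate_te_evolution


@pytest.fixture(scope="session")
def sim_family():
    """One simulated transposase family (default conditions, fixed seed)."""
    params = SimParams()
    host = simulate_host_tree(params.n_genera, params.tribe_age, seed=11,
                              min_split_frac=params.min_split_frac)
    records, truth = simulate_te_evolution(host, params, seed=12)
    return params, host, records, truth


@pytest.fixture(scope="session")
def sim_functional_rich():
    """A simulation tuned to yield many functional copies (for recovery tests)."""
    params = SimParams(n_genera=10, dup_rate=0.05, loss_rate=0.01, pseudo_rate=0.0)
    host = simulate_host_tree(params.n_genera, params.tribe_age, seed=21,
                              min_split_frac=params.min_split_frac)
    records, truth = simulate_te_evolution(host, params, seed=22)
    return params, host, records, truth
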