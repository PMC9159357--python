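import pytest

from apastab import sim
from apastab.quantify import filter_expressed, median_ratio_normalize


@pytest.fixture(scope="session")
def small_exp():
    """A small deterministic experiment shared across tests."""
    cfg = sim.SimConfig(n_genes=40, depth=30_000, seed=11)
    return sim.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_norm(small_exp):
    counts = filter_expressed(small_exp["counts"], min_reads=5)
    factors, norm, rpm = median_ratio_normalize(counts, small_exp["samples"])
    return {"counts": counts, "factors": factors, "norm": norm, "rpm": rpm}
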