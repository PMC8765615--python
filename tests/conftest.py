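import numpy as np
import pytest

from operon_voter import OperonPairSuite, SimulationConfig, default_benchmark


@pytest.fixture(scope="session")
def bench_small():
    """A reduced synthetic benchmark for fast classifier-level checks."""
    feats, labels, tr, te = default_benchmark(seed=7, config=SimulationConfig(n_genes=400))
    return feats, labels, tr, te


@pytest.fixture(scope="session")
def suite_small(bench_small):
    feats, labels, tr, _ = bench_small
    return OperonPairSuite(random_state=7).fit(feats.iloc[tr], labels[tr])


@pytest.fixture(scope="session")
def bench_full():
    """The default synthetic benchmark (4,000 genes, 2 replicates)."""
    return default_benchmark(seed=0)
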