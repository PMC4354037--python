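import warnings

import numpy as np
import pytest

from kinflow import calling, simulate


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence routine pipeline warnings (variance floor, empty reads) in tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="GMM variance floor")
        warnings.filterwarnings("ignore", message="skipped .* empty read")
        yield


@pytest.fixture(scope="session")
def small_monotemplate_run():
    """Noiseless, phasing-free 20-cluster monotemplate run (session-cached)."""
    return simulate.make_monotemplate_run(seed=11, n_clusters=20)


@pytest.fixture(scope="session")
def small_monotemplate_features(small_monotemplate_run):
    run = small_monotemplate_run
    cfg = calling.CallerConfig(flow_order="GCAT")
    feats = calling.compute_features(run.traces, run.program.bases, cfg)
    return run, cfg, feats


@pytest.fixture
def rng():
    return np.random.default_rng(42)
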