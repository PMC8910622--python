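import numpy as np
import pytest

from sleepstage import synthetic
from sleepstage.features import extract_features
from sleepstage.signal_io import STAGES


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def benchmark_features():
    """57-feature table of the default synthetic benchmark (200 epochs/stage).

    Session-scoped: generating and featurising 1000 epochs takes about a
    minute and is shared by the end-to-end tests.
    """
    er = synthetic.generate_dataset({s: 200 for s in STAGES}, seed=1234)
    return extract_features(er)


@pytest.fixture(scope="session")
def small_features(benchmark_features):
    """A 40-epochs-per-stage slice of the benchmark table for cheaper tests."""
    parts = [
        benchmark_features[benchmark_features["stage"] == s].head(40) for s in STAGES
    ]
    import pandas as pd

    return pd.concat(parts, ignore_index=True)
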