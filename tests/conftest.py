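import numpy as np
import pytest

from rutvox.detector import TrainConfig
from rutvox.pipeline import train_on_benchmark
from rutvox.synth import synth_benchmark


@pytest.fixture(scope="session")
def easy_benchmark(tmp_path_factory):
    """A small easy-tier benchmark shared across detector/pipeline tests."""
    out = tmp_path_factory.mktemp("bench") / "easy"
    synth_benchmark(out, n_train_scenes=3, n_test_scenes=2, difficulty="easy", seed=7)
    return out


@pytest.fixture(scope="session")
def trained_easy(easy_benchmark):
    """A compact CNN trained briefly on the easy benchmark."""
    config = TrainConfig(epochs=6, seed=7)
    model, history, data_hash = train_on_benchmark(easy_benchmark, config)
    return model, config, history, data_hash
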