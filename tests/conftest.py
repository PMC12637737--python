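import numpy as np
import pytest

from bmisim import TrialConfig, default_parameter_set, run_replicates


@pytest.fixture()
def default_params():
    # function-scoped: tests are free to mutate their copy
    return default_parameter_set()


@pytest.fixture(scope="session")
def endtoend_results():
    """The reference end-to-end run: 100 paired replicates at 1/10 scale."""
    config = TrialConfig(replicates=100, scale=0.1, base_seed=42)
    return run_replicates(default_parameter_set(), config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
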