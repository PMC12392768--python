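import numpy as np
import pytest

from fdiarch import postprocess, synthetic


@pytest.fixture(scope="session")
def upper_scan():
    """Default 14-tooth upper arch in the standard pose."""
    return synthetic.generate_arch(synthetic.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def lower_scan():
    return synthetic.generate_arch(
        synthetic.GeneratorConfig(arch="lower", seed=0))


@pytest.fixture(scope="session")
def training_scans():
    """Small training set for the offset prior."""
    return [synthetic.generate_arch(synthetic.GeneratorConfig(seed=s))
            for s in range(20)]


@pytest.fixture(scope="session")
def offset_model(training_scans):
    model = postprocess.collect_offsets(training_scans)
    return postprocess.fit_offset_model(model)
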