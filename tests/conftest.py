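import numpy as np
import pytest

from adnet import NetworkSpec, generate_synthetic_stream
from adnet.network import init_params


@pytest.fixture(scope="session")
def tiny_spec():
    """Small dendritic network used across unit tests."""
    return NetworkSpec(
        input_dim=16,
        hidden_dims=(24, 24),
        output_dim=10,
        context_dim=16,
        weight_sparsity=0.5,
        activation_density=0.25,
        num_segments=3,
    )


@pytest.fixture()
def tiny_params(tiny_spec):
    return init_params(tiny_spec, seed=7, dtype=np.float64)


@pytest.fixture(scope="session")
def small_stream():
    """3-task, 16-dimensional stream; cheap enough for every test that needs one."""
    return generate_synthetic_stream(
        n_classes=10, dim=16, T=3, n_train=400, n_test=200, seed=11
    )
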