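import numpy as np
import pandas as pd
import pytest

from clpnet import (
    CLPNetwork,
    FitConfig,
    SimulationConfig,
    generate_cohort,
)
from clpnet import nodes as nd


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort shared by read-only tests."""
    cfg = SimulationConfig(n_participants=600, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def random_network():
    """Factory: seeded random 24-node network with the 3/9/7/5 partition."""

    def make(seed=0, scale=0.2, density=0.3):
        rng = np.random.default_rng(seed)
        w = rng.normal(0, scale, (nd.N_NODES, nd.N_NODES))
        w *= rng.random((nd.N_NODES, nd.N_NODES)) < density
        return CLPNetwork(
            weights=w,
            node_labels=list(nd.NODE_LABELS),
            construct_labels=list(nd.CONSTRUCT_LABELS),
            lambdas=np.zeros(nd.N_NODES),
            n=0,
        )

    return make


@pytest.fixture
def fast_fit():
    """Fixed-penalty fit config for resampling-heavy tests."""
    return FitConfig(lambda_selection="fixed", fixed_lambda=0.02)


def latent_frames(truth):
    """Wave-wise DataFrames of the generator's latent node scores."""
    w1 = pd.DataFrame(truth.latent_wave1, columns=nd.NODE_LABELS)
    w2 = pd.DataFrame(truth.latent_wave2, columns=nd.NODE_LABELS)
    return w1, w2
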