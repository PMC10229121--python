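import numpy as np
import pytest

from middledown.simulate import AcquisitionConfig, MixtureSpec, default_mixture, simulate_run


@pytest.fixture(scope="session")
def noise_free_run():
    """One noise-free default-mixture acquisition plus its ground truth."""
    run, truth = simulate_run(default_mixture(), AcquisitionConfig(), seed=11)
    return run, truth


@pytest.fixture()
def single_degree_mixture():
    """Mass concentrated in the 3ac class with an asymmetric K4 profile."""
    return MixtureSpec(
        abundances={3: 10.0},
        k4={3: (0.70, 0.20, 0.08, 0.02)},
    )
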