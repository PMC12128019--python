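import numpy as np
import pytest

from spinfep.systems import (
    HarmonicPairParams,
    QuarticPairParams,
    TwoStateSystem,
)


@pytest.fixture
def harmonic_1d():
    """1D harmonic pair: stiffer singlet, offset triplet minimum, ΔE0 = 10."""
    params = HarmonicPairParams(
        k_s=[300.0], k_t=[200.0], x0_s=[0.0], x0_t=[0.15], e0_s=0.0, e0_t=10.0
    )
    return TwoStateSystem(
        n_particles=1, dim=1, masses=[12.0], frozen_mask=[False], params=params
    )


@pytest.fixture
def quartic_1d():
    params = QuarticPairParams(
        k_s=[300.0], k_t=[300.0], c4_s=[0.0], c4_t=[500.0],
        x0_s=[0.0], x0_t=[0.0], e0_s=0.0, e0_t=0.0,
    )
    return TwoStateSystem(
        n_particles=1, dim=1, masses=[12.0], frozen_mask=[False], params=params
    )


@pytest.fixture
def identical_pair():
    """Both electronic states share the same surface: ΔF = 0 and ΔH ≡ 0."""
    params = HarmonicPairParams(
        k_s=[250.0, 400.0], k_t=[250.0, 400.0],
        x0_s=[0.0, 0.3], x0_t=[0.0, 0.3], e0_s=5.0, e0_t=5.0,
    )
    return TwoStateSystem(
        n_particles=2, dim=1, masses=[12.0, 16.0],
        frozen_mask=[False, False], params=params,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
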