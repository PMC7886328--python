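import numpy as np
import pytest

from stringswarm.cv import identity_cvset
from stringswarm.engine import EngineParams
from stringswarm.ensembles import LabeledEnsemble, generate_labeled_ensembles
from stringswarm.potentials import DoubleWell1D, Harmonic, MullerBrown


@pytest.fixture
def double_well():
    return DoubleWell1D(barrier=3.0, tilt=0.0)


@pytest.fixture
def harmonic():
    return Harmonic(kappa=4.0)


@pytest.fixture
def muller_brown():
    return MullerBrown(scale=0.05)


@pytest.fixture
def cv_1d():
    return identity_cvset([[-1.6, 1.6]])


@pytest.fixture
def unit_cv_1d():
    """Identity CV on [0, 1]: scaled space equals physical space."""
    return identity_cvset([[0.0, 1.0]])


@pytest.fixture
def params():
    return EngineParams(timestep=1e-3, diffusion_coefficient=1.0, kT=1.0, seed=42)


def planted_ensemble(seed: int, n_noise: int = 50, shift: float = 5.0,
                     n_frames: int = 200, planted: int | None = None) -> LabeledEnsemble:
    """Two classes of unit Gaussians differing only in one coordinate's mean
    by ``shift`` sigma — the planted-feature construction."""
    n_feat = n_noise + 1
    if planted is None:
        planted = min(7, n_noise)
    mean_a = np.zeros(n_feat)
    mean_b = np.zeros(n_feat)
    mean_b[planted] = shift
    return generate_labeled_ensembles(
        {"a": [(mean_a, np.ones(n_feat), 1.0)], "b": [(mean_b, np.ones(n_feat), 1.0)]},
        n_frames,
        seed=seed,
    )
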