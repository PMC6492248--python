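import numpy as np
import pytest

from cmsrefine import FixtureSpec, make_decoy_ensemble, make_toy_complex


@pytest.fixture(scope="session")
def truth():
    """Default toy complex (bead-chain geometry, seed 0)."""
    return make_toy_complex(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def helix_complex():
    return make_toy_complex(FixtureSpec(geometry="helix", seed=0))


@pytest.fixture(scope="session")
def decoy_set(truth):
    """Graded decoy ensemble of the default complex plus its manifest."""
    ensemble, manifest = make_decoy_ensemble(truth, n_decoys=8, seed=1)
    return ensemble, manifest


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
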