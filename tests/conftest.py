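import numpy as np
import pytest

from morphodim import LandmarkConfiguration, default_scheme, generate_mean_face
from morphodim.landmarks import LandmarkScheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def template(scheme):
    return generate_mean_face(scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_scheme():
    """Six points: two midline, two bilateral pairs (one of them sliding)."""
    return LandmarkScheme(
        names=("top", "bottom", "eye_l", "eye_r", "jaw_l", "jaw_r"),
        roles=("fixed", "fixed", "fixed", "fixed", "semilandmark", "semilandmark"),
        bilateral_pairs=((2, 3), (4, 5)),
        midline=(0, 1),
        sliders={4: (2, 4, 1), 5: (3, 5, 1)},
    )


def make_config(coords, subject_id="toy", **kw):
    return LandmarkConfiguration(subject_id=subject_id, coords=np.asarray(coords, float), **kw)
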