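import numpy as np
import pytest

from dissectfem.constants import ADVENTITIA, MEDIA, default_cohesive_params


@pytest.fixture(scope="session")
def media():
    return MEDIA


@pytest.fixture(scope="session")
def adventitia():
    return ADVENTITIA


@pytest.fixture()
def cohesive():
    return default_cohesive_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_F(rng, scale=0.1, near_isochoric=True):
    """Random deformation gradient with positive determinant."""
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    while np.linalg.det(F) <= 0.05:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
    if near_isochoric:
        F = F * np.linalg.det(F) ** (-1.0 / 3.0)
    return F
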