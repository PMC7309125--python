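import numpy as np
import pytest

from facemark import FixtureMarkerDetector, FixtureSpec, make_face_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The full-resolution (~20k triangle) fixture mesh and its truth."""
    return make_face_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def coarse_fixture():
    """A coarse (~1.3k triangle) fixture for registration-heavy tests."""
    return make_face_fixture(FixtureSpec(subdivisions=3))


@pytest.fixture(scope="session")
def medium_fixture():
    """A ~2.5k-vertex fixture for NICP recovery tests."""
    return make_face_fixture(FixtureSpec(subdivisions=4))


@pytest.fixture(scope="session")
def detector():
    return FixtureMarkerDetector()


def rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler(axis, degrees, degrees=True).as_matrix()
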