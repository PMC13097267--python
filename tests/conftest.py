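import numpy as np
import pytest

from eomhabitat import Geometry, PhantomSpec, ScalarVolume, SegmentationMask, generate_cohort


@pytest.fixture
def geom():
    return Geometry(spacing=(1.0, 1.0, 3.0))


@pytest.fixture
def small_volume(geom):
    rng = np.random.default_rng(7)
    return ScalarVolume(rng.uniform(0, 100, size=(6, 5, 4)), geom)


@pytest.fixture
def full_mask(geom):
    return SegmentationMask(np.ones((6, 5, 4), dtype=np.uint8), geom)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A 3+3 synthetic cohort on disk, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(3, 3, out, PhantomSpec(), jitter=0.1, seed=11)
    return manifest
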