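import numpy as np
import pytest

from petctseg import phantom


@pytest.fixture(scope="session")
def small_grid():
    return phantom.VoxelGrid((32, 32, 64))


@pytest.fixture(scope="session")
def anatomy(small_grid):
    """Lesion-free stylized body on a small grid (shared, read-only)."""
    return phantom.build_anatomy(small_grid, seed=0)


@pytest.fixture(scope="session")
def lesioned(anatomy):
    """Anatomy plus a reproducible set of random lesions."""
    lesions = phantom.sample_lesions(anatomy, n_range=(8, 12), seed=5)
    return phantom.apply_lesions(anatomy, lesions)
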