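import numpy as np
import pytest

from woundquant import synth
from woundquant.stack import LabeledObjects


@pytest.fixture(scope="session")
def spheres_scene():
    return synth.spheres_scene(seed=1)


@pytest.fixture(scope="session")
def cells_cargo():
    return synth.cells_cargo_scene(seed=2)


@pytest.fixture(scope="session")
def walkers_movie():
    return synth.nuclei_movie(seed=3)


@pytest.fixture(scope="session")
def ytube_fixtures():
    return {
        "long": synth.ytube_scene(),
        "short": synth.ytube_scene(branch_lengths_um=(8.0, 35.0)),
        "clipped": synth.ytube_scene(
            branch_lengths_um=(8.0, 35.0), clip_first_branch=True
        ),
    }


@pytest.fixture
def two_merged_blobs():
    """Two overlapping Gaussian blobs binarizing into one component."""
    yy, xx = np.indices((40, 64))
    img = (
        200 * np.exp(-((yy - 20) ** 2 + (xx - 24) ** 2) / 60)
        + 200 * np.exp(-((yy - 20) ** 2 + (xx - 40) ** 2) / 60)
        + 5.0
    )
    from scipy import ndimage

    labels, n = ndimage.label(img > 30)
    assert n == 1, "fixture must binarize into a single merged component"
    objs = LabeledObjects.from_labels(labels, (1.0, 1.0, 1.0))
    return img, objs, [(20.0, 24.0), (20.0, 40.0)]
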