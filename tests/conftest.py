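import numpy as np
import pytest

from emseg.core import ImageStack, LabelVolume
from emseg.synthdata import SynthSpec, gen_mitochondria


@pytest.fixture(scope="session")
def mito_small():
    """A small ellipsoid fixture shared by several stages: 8 slices, 96², 4 ovals."""
    spec = SynthSpec(shape=(8, 96, 96), n_objects=4, seed=1)
    return gen_mitochondria(spec)


def sphere_mask(shape, center, radius):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= radius**2


@pytest.fixture
def sphere_mask_fn():
    return sphere_mask
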