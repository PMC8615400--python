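import numpy as np
import pytest

from crosspet import PhantomSpec, SuvVolume, generate_phantom_pair


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic phantom subject: (A, B, lesion mask, normal mask)."""
    return generate_phantom_pair(PhantomSpec(seed=42))


def make_suv(voxels, spacing=(1.5, 1.5, 1.5), modality="synthetic-A"):
    return SuvVolume(voxels=np.asarray(voxels, dtype=float), spacing=spacing, modality=modality)


@pytest.fixture
def block_volume():
    """9^3 zeros with a 3^3 block of 10 and one adjacent voxel of 4."""
    vox = np.zeros((9, 9, 9))
    vox[3:6, 3:6, 3:6] = 10.0
    vox[3, 3, 6] = 4.0
    return make_suv(vox)
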