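import numpy as np
import pytest

from npcseg import (GTVMask, ModelConfig, NormalizedVolume, PhantomSpec,
                    build_unet25d, generate_phantom, resample_to_spacing,
                    window_and_normalize)

TEST_SPACING = (3.0, 1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def labeled_phantom():
    """One deterministic labeled phantom at desk-test size."""
    spec = PhantomSpec(shape=(16, 64, 64), tumor_radii_mm=(10.0, 12.0, 11.0),
                       seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def prepared_case(labeled_phantom):
    """(normalized image, binary mask) after the standard preprocessing."""
    vol, mask = resample_to_spacing(labeled_phantom.volume, labeled_phantom.mask)
    norm = window_and_normalize(vol)
    return norm.voxels, mask.voxels


@pytest.fixture(scope="session")
def normalized_volume(prepared_case):
    img, _ = prepared_case
    return NormalizedVolume(img, TEST_SPACING, patient_id="fixture")


@pytest.fixture(scope="session")
def gtv_mask(prepared_case):
    _, mask = prepared_case
    return GTVMask(mask, TEST_SPACING)


@pytest.fixture
def tiny_model():
    """A 2-channel-wide network: full architecture, minimal arithmetic."""
    return build_unet25d(ModelConfig(base_width=2), seed=0)
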