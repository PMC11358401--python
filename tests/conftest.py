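import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from hemilabel import (
    ContextSetConfig,
    LabelMap,
    PhantomSpec,
    Volume,
    generate_context_set,
    make_phantom_hemisphere,
    mask_background,
    merge_labels,
    refine_with_closing,
)

SMALL_SHAPE = (48, 48, 48)
MID_SHAPE = (64, 64, 64)


def ras_affine(spacing=0.3, origin=(0.0, 0.0, 0.0)):
    a = np.diag([spacing, spacing, spacing, 1.0])
    a[:3, 3] = origin
    return a


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free left hemisphere phantom with its 5-subregion labels."""
    spec = PhantomSpec(shape=MID_SHAPE, noise_sigma=0.0, seed=11)
    return make_phantom_hemisphere(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(shape=MID_SHAPE, noise_sigma=2.0, seed=12)
    return make_phantom_hemisphere(spec)


@pytest.fixture(scope="session")
def brain_mask(clean_phantom):
    vol, _ = clean_phantom
    return mask_background(vol)


@pytest.fixture(scope="session")
def merged_map(clean_phantom, brain_mask):
    """Manual labels fused into a k=4 context map, closed."""
    vol, manual = clean_phantom
    ctx = generate_context_set(vol, brain_mask, ContextSetConfig(k_min=4, k_max=4))[0]
    return refine_with_closing(merge_labels(manual, ctx))


def small_label_map(data, spacing=0.3):
    return LabelMap(np.asarray(data, dtype=np.int32), ras_affine(spacing))


def small_volume(data, spacing=0.3):
    return Volume(np.asarray(data, dtype=float), ras_affine(spacing))
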