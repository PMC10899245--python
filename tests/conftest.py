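import numpy as np
import pytest

from renalus.phantom import (
    PhantomParams,
    generate_axial_phantom,
    generate_sagittal_phantom,
    sample_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ellipse_mask(shape, center, a, b, angle_deg=0.0):
    """Filled ellipse test mask; angle counterclockwise (screen-up)."""
    import math

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cc - center[1]
    y = -(rr - center[0]).astype(float)
    th = math.radians(angle_deg)
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@pytest.fixture
def small_sagittal_phantom():
    params = PhantomParams(
        capsule_semi_major_px=100,
        capsule_semi_minor_px=40,
        rotation_deg=0.0,
        sinus_scale=0.5,
        spacing_mm_per_px=0.3,
        speckle_sigma=0.0,
        seed=7,
    )
    return params, generate_sagittal_phantom(params)


@pytest.fixture
def small_axial_phantom():
    params = PhantomParams(
        capsule_semi_major_px=110,
        capsule_semi_minor_px=50,
        rotation_deg=0.0,
        hilum_notch_depth=0.4,
        spacing_mm_per_px=0.3,
        speckle_sigma=0.0,
        seed=7,
    )
    return params, generate_axial_phantom(params)


def random_phantom_masks(n, seed, image_shape=(160, 240)):
    """Capsule/sinus mask pairs from random sagittal phantoms."""
    gen = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = sample_params(gen, "sagittal", image_shape)
        _, cap, sin, _ = generate_sagittal_phantom(p)
        out.append((cap, sin))
    return out


def random_axial_masks(n, seed, image_shape=(160, 240)):
    gen = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = sample_params(gen, "axial", image_shape)
        _, cap, _ = generate_axial_phantom(p)
        out.append(cap)
    return out
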