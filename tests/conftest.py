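import numpy as np
import pytest

from habitatrad.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_plateau_phantom():
    """40mm-grid noiseless 3-plateau phantom (the habitat recovery fixture)."""
    spec = PhantomSpec(
        grid_shape=(26, 26, 26),
        spacing_mm=(1.0, 1.0, 1.0),
        nodule_radius_mm=9.0,
        n_plateaus=3,
        plateau_levels=(-150.0, 50.0, 250.0),
        noise_sd=0.0,
    )
    return generate_phantom(spec, seed=0)


@pytest.fixture(scope="session")
def small_random_images():
    """Random 5^3 discrete images with full masks, for feature oracles."""
    rng = np.random.default_rng(20240901)
    images = []
    for _ in range(50):
        img = rng.integers(0, rng.integers(2, 7), size=(5, 5, 5)).astype(float) * 25.0
        mask = rng.random((5, 5, 5)) < 0.85
        if mask.sum() < 8:
            mask[2, 2, 2] = True
        images.append((img, mask))
    return images
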