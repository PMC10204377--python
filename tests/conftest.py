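import numpy as np
import pytest

from adiposeg import AbdominalImage, Modality, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """A mid-sized phantom with two visceral fat depots and the spine islet."""
    return PhantomSpec(
        body_radii=(160.0, 115.0),
        sat_thickness_mm=22.0,
        muscle_thickness_mm=11.0,
        visceral_blobs=[
            ((-15.0, 40.0), (20.0, 16.0), 0.3),
            ((5.0, -55.0), (14.0, 22.0), 1.1),
        ],
        seed=42,
    )


@pytest.fixture(scope="session")
def ct_phantom(default_spec):
    return generate_phantom(default_spec, Modality.CT)


@pytest.fixture(scope="session")
def mr_phantom(default_spec):
    return generate_phantom(default_spec, Modality.MR)


@pytest.fixture()
def flat_mr_image() -> AbdominalImage:
    """Homogeneous bright body on dark background, 1 mm pixels."""
    pixels = np.full((64, 64), 2.0)
    pixels[16:48, 16:48] = 1000.0
    return AbdominalImage(pixels, Modality.MR, (1.0, 1.0), source_id="flat")
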