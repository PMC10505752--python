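import numpy as np
import pytest

from ihctasc import SyntheticImageSpec, generate_ihc_image

#: The ten published per-group TASC rows: group -> (II, III, IV, total).
TABLE_EXPECTED = {
    "human_total": (4, 3, 5, 21),
    "MPNST": (4, 0, 6, 19),
    "UPS": (4, 3, 6, 22),
    "DFSP": (4, 0, 5, 18),
    "MFS": (4, 3, 6, 22),
    "canine_total": (4, 0, 5, 18),
    "PWT": (4, 3, 5, 21),
    "STS_NOS": (0, 0, 3, 12),
    "cFS": (0, 0, 5, 14),
    "fFS": (4, 3, 6, 22),
}


@pytest.fixture
def balanced_image():
    """Noiseless 100x100 image with 10% of pixels at each level 0-4."""
    spec = SyntheticImageSpec(
        width_px=100,
        height_px=100,
        level_fractions=(0.1, 0.1, 0.1, 0.1, 0.1),
        artifact_fraction=0.0,
        noise_sd=0.0,
        seed=11,
    )
    return spec, generate_ihc_image(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
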