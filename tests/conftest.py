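import numpy as np
import pytest

import sarcoxray as sx
from sarcoxray import reflections as refl


def measure_image(img, state="rest"):
    """Fold, background-subtract and measure one synthetic pattern."""
    folded = sx.quadrant_fold(img)
    corrected, diffuse_sum = sx.subtract_background(folded)
    return refl.measure_pattern(corrected, diffuse_sum=diffuse_sum, state=state)


@pytest.fixture(scope="session")
def geom():
    return sx.default_geometry()


@pytest.fixture(scope="session")
def canonical_spec():
    return sx.PatternSpec()


@pytest.fixture(scope="session")
def canonical_rest_set(geom, canonical_spec):
    """Measured reflection set of the noiseless canonical-helix pattern."""
    img = sx.simulate_pattern(canonical_spec, geom)
    return measure_image(img, "rest")


@pytest.fixture(scope="session")
def rest_active_sets(geom, canonical_spec):
    """Rest/active pair with 0.3% M13 strain and reduced ALL2/TN3 on activation."""
    rest_img, active_img = sx.simulate_pair(
        canonical_spec, geom, strain_m13=0.003,
        intensity_scale={"ALL2": 0.7, "TN3": 0.7})
    return measure_image(rest_img, "rest"), measure_image(active_img, "active")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
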