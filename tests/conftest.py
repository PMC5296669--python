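import numpy as np
import pytest

from anisoquant.synthetic import AngularDistribution, ImageSpec, render_fibril_image

# phantom geometry used whenever a test needs a clean single-orientation
# image: long, thin fibrils keep the ambiguous end-cap area small relative
# to the ridge area, as in the micrographs where fibrils span the field
PHANTOM_KW = dict(width=512, height=512, n_fibrils=100,
                  length_range=(150.0, 300.0), thickness_range=(1.5, 2.5),
                  noise_sigma=0.0)


@pytest.fixture
def delta_phantom():
    """Factory: noise-free phantom with every fibril at one known angle."""

    def make(angle, seed=3, **overrides):
        kw = {**PHANTOM_KW, **overrides}
        spec = ImageSpec(angular_distribution=AngularDistribution("delta", angle),
                         seed=seed, **kw)
        return render_fibril_image(spec)

    return make


def angular_error(a, b):
    """Smallest axial (180-deg periodic) distance between angle arrays."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)
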