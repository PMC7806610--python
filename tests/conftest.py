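import numpy as np
import pytest

from imsiq.core import AcquisitionSpec, ElementalImage, UNIT_CPS, UNIT_UGKG
from imsiq.phantom import PhantomSpec, generate_fiber_map, render_concentration_field


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def quiet_acq():
    """Noise-free acquisition with unit response: intensity equals concentration."""
    return AcquisitionSpec(
        sensitivity_cps_per_ugkg=1.0, flicker_fraction=0.0, dark_cps=0.0, seed=3
    )


@pytest.fixture
def small_phantom():
    """A 150x150 um section with 6 fibers at the default contrast levels."""
    spec = PhantomSpec(width_um=150.0, height_um=150.0, n_fibers=6, seed=11)
    labels = generate_fiber_map(spec, 1.0)
    truth = render_concentration_field(labels, spec, 1.0)
    return spec, labels, truth


def cps_image(values, dx=1.0, dy=1.0):
    return ElementalImage(np.asarray(values, float), dx, dy, UNIT_CPS)


def conc_image(values, dx=1.0, dy=1.0):
    return ElementalImage(np.asarray(values, float), dx, dy, UNIT_UGKG)
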