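import pytest

from femurtough import CrossSection, NotchGeometry
from femurtough.simulate import gen_bend_test, gen_section_mask


@pytest.fixture
def section() -> CrossSection:
    """Typical murine mid-diaphyseal equivalent annulus."""
    return CrossSection(outer_radius=0.9, inner_radius=0.65)


@pytest.fixture
def notch() -> NotchGeometry:
    return NotchGeometry(initial_half_angle=0.6, notch_depth=0.65)


@pytest.fixture
def bend_record(section, notch):
    """Noiseless forward-modelled bend test with its ground-truth sidecar."""
    return gen_bend_test(section=section, notch=notch, seed=0)


@pytest.fixture
def circular_annulus():
    """Rasterized circular annulus (R_o=1.0, R_i=0.6 mm) with truth sidecar."""
    return gen_section_mask(1.0, 0.6, pixel_size_um=12.0, seed=0)
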