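import numpy as np
import pytest

from foldstrat import synth


@pytest.fixture(scope="session")
def small_spec():
    """A small caudal-fold geometry that keeps image tests fast."""
    return synth.SectionSpec(fold_type="CauF", age_group="young",
                             lamina_depth_um=200.0,
                             epithelium_thickness_um=30.0,
                             pixel_size_um=0.5, width_um=120.0, seed=7)


@pytest.fixture(scope="session")
def small_section(small_spec):
    """Generated small section with moderate fibre content."""
    zones = synth.calibrate_composition(
        [0.15] * 10, [0.08] * 10, "CauF", "young")
    return synth.generate_section(small_spec, zones)


@pytest.fixture(scope="session")
def old_craf_section():
    """Default-geometry aged cranial fold (reddish zones 1-3, clumps)."""
    return synth.default_section("CraF", "old", seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
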