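import pytest

from cosolve import FusionProperties, load_reference_dataset


@pytest.fixture(scope="session")
def reference_grid():
    """Bundled baricitinib / DMSO / water grid (corrected)."""
    return load_reference_dataset()


@pytest.fixture(scope="session")
def fusion_props():
    """Baricitinib fusion constants: 487.42 K, 41.11 kJ/mol, 84.34 J/mol/K."""
    return FusionProperties(t_fus=487.42, dh_fus=41110.0, dcp=84.34)
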