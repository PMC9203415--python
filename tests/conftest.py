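import numpy as np
import pytest

from octfovea import ScanGeometry, build_template, generate, layer_thickness_map, resample
from octfovea.phantom import PhantomSpec


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def default_geometry():
    return ScanGeometry.default()


@pytest.fixture(scope="session")
def clean_phantom(default_geometry):
    """Noiseless, artifact-free phantom with the pit at scan centre."""
    spec = PhantomSpec(geometry=default_geometry, fovea_mm=(3.0, 3.0))
    return generate(spec)


@pytest.fixture(scope="session")
def clean_iso_map(clean_phantom):
    vol, _ = clean_phantom
    return resample(layer_thickness_map(vol, ("GCL", "IPL")))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
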