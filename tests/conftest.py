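import numpy as np
import pytest

from bpq import geometry as geo
from bpq import synth


@pytest.fixture(scope="session")
def design():
    return geo.default_design()


@pytest.fixture(scope="session")
def raster10(design):
    return geo.rasterize_design(design, 10.0)


@pytest.fixture(scope="session")
def partition10(design, raster10):
    return geo.partition_regions(raster10, design, 0.30)


@pytest.fixture(scope="session")
def dcis_scene():
    return synth.generate_scene(
        synth.example_params("dcis", 14, seed=1, pixel_size=8.0))


@pytest.fixture(scope="session")
def timecourse():
    p3 = synth.example_params("dcis", 3, seed=2, pixel_size=8.0)
    p14 = synth.example_params("dcis", 14, seed=2, pixel_size=8.0)
    return synth.generate_timecourse(p3, p14)


@pytest.fixture(scope="session")
def viability_scene():
    """Plain scene at the default 4 µm/px with a 3% planted dead fraction."""
    return synth.generate_scene(synth.SceneParams(
        pixel_size=4.0, seed=1, dead_fraction=0.03, nuclei_density=0.002))
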