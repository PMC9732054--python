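import numpy as np
import pytest

import lulcst as L


@pytest.fixture(scope="session")
def specs():
    return L.default_class_specs()


@pytest.fixture(scope="session")
def truth_map(specs):
    return L.generate_truth_map((120, 120), specs, region_scale=12, seed=11)


@pytest.fixture(scope="session")
def scene(truth_map, specs):
    return L.generate_scene(truth_map, specs, seed=13)


@pytest.fixture()
def tm_meta():
    return L.landsat5_tm_meta()


@pytest.fixture()
def oli_meta():
    return L.landsat8_oli_meta()


def grid(values, mask=None, **kw):
    return L.BandGrid(values=np.asarray(values, dtype=float),
                      nodata_mask=mask, **kw)
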