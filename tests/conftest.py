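import warnings

import numpy as np
import pytest

from iplsim import (GeometryConfig, build_grid, locate_probes,
                    make_synthetic_spectrum, run_transport)
from iplsim.pipeline import make_fixture


@pytest.fixture(scope="session")
def tiny_config():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture("tiny_grid")


@pytest.fixture(scope="session")
def tiny_grid(tiny_config):
    return build_grid(tiny_config.geometry, tiny_config.optics)


@pytest.fixture(scope="session")
def tiny_spectrum(tiny_config):
    return tiny_config.spectrum.build(total_fluence=tiny_config.fluence)


@pytest.fixture(scope="session")
def tiny_transport(tiny_grid, tiny_spectrum, tiny_config):
    """One shared transport run on the tiny fixture (absorption, tally)."""
    return run_transport(tiny_grid, tiny_spectrum, tiny_config.n_photons,
                         tiny_config.seed)


@pytest.fixture(scope="session")
def uniform_dermis_grid():
    """Uniform dermis block (no epidermis, no follicle) for solver oracles."""
    geo = GeometryConfig(domain_width=2000e-6, domain_depth=2000e-6,
                         epidermis_thickness=0.0, follicle_diameter=0.0,
                         follicle_length=0.0, follicle_top_depth=0.0)
    return build_grid(geo)
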