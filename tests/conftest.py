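import numpy as np
import pytest

from memcoev import ContactMap, ModelParams, SimulationConfig, synthetic_contact_map


@pytest.fixture
def band_map():
    """20-site backbone band map, width 2 (no helices, no long-range)."""
    cmap, _ = synthetic_contact_map(20, helix_spans=(), long_range_pairs_per_site=0.0,
                                    backbone_width=2, seed=0)
    return cmap


@pytest.fixture
def empty_map():
    """10 sites, no contacts at all."""
    return ContactMap(np.zeros((10, 10), dtype=bool))


@pytest.fixture
def fast_params():
    """High baseline rate so tests reach low identity in few steps."""
    return ModelParams(r0=0.05, J=0.02)


@pytest.fixture
def fast_config():
    return SimulationConfig(dt=0.01, equilibration_time=1.0, max_time=500.0)
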