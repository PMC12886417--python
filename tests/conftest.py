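import numpy as np
import pytest

from odcdecode import synthetic as syn
from odcdecode.design import RunDesign


@pytest.fixture(scope="session")
def small_sheet():
    """Desk-scale cortical patch: 32 x 32 vertices at 0.4 mm spacing."""
    return syn.CorticalSheet(32, 32, 0.4)


@pytest.fixture(scope="session")
def small_pattern(small_sheet):
    return syn.generate_odc_pattern(small_sheet, seed=11)


@pytest.fixture(scope="session")
def reference_design():
    """The reference ODC run: 270 s, TR 3 s, two 15 s baselines, 8 x 30 s."""
    return RunDesign()


@pytest.fixture(scope="session")
def noisefree_model():
    """Drain-free, noise-free laminar model on 11 equidistant depths."""
    return syn.LaminarResponseModel(drain_lambda=0.0, noise_sd=0.0,
                                    base_amplitude=2.0)


@pytest.fixture(scope="session")
def noisefree_session(small_sheet, small_pattern, noisefree_model,
                      reference_design):
    return syn.simulate_session(small_sheet, small_pattern, noisefree_model,
                                reference_design, drift_amplitude=0.0, seed=5)


@pytest.fixture(scope="session")
def noisy_session(small_sheet, small_pattern, reference_design):
    """Moderate-CNR session: clearly decodable but not saturated."""
    model = syn.LaminarResponseModel(base_amplitude=2.0, noise_sd=5.0)
    return syn.simulate_session(small_sheet, small_pattern, model,
                                reference_design, seed=6)


def vertex_samples(session, depths=None):
    """Retained labeled samples straight from vertex space (no voxel round
    trip), for decoding tests."""
    from odcdecode.decode import session_samples

    series = [r.series for r in session.runs]
    designs = [r.design for r in session.runs]
    return session_samples(series, designs, depths=depths)
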