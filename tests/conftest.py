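"""Shared fixtures: expensive reference computations are session-scoped so
the suite solves/renders each one only once."""

import numpy as np
import pytest

import cortexflow as cf
from cortexflow.spot_tracking import TrackingParams


@pytest.fixture(scope="session")
def reference_solution():
    """PDE solution at the PAR-2-like reference point (D = 0.1 µm²/s,
    k_on = k_off = 0.005 s⁻¹, 500 s flow + 1500 s relaxation)."""
    return cf.solve_pde(cf.PdeParams(D=0.1, k_off=0.005))


@pytest.fixture(scope="session")
def reference_metrics(reference_solution):
    return cf.compute_metrics(reference_solution)


@pytest.fixture(scope="session")
def tracking_fixture():
    """Rendered movie of 12 well-separated simulated particles plus ground
    truth (deterministic seed)."""
    return cf.make_fixtures("tracking", seed=1)


@pytest.fixture(scope="session")
def tracked_fixture(tracking_fixture):
    params = TrackingParams(feature_size=7, intensity_threshold=20.0,
                            min_separation=2.0, max_displacement=4.0,
                            min_track_length=11)
    tracked = cf.track_stack(tracking_fixture["stack"], params)
    return {"tracked": tracked, **tracking_fixture}


@pytest.fixture(scope="session")
def piv_translation():
    """Speckle stack rigidly translated by (3.0, −1.5) px/frame, and its
    recovered flow field."""
    from cortexflow.flow_field import PivParams, piv

    flow = cf.FlowField.uniform(0.3, -0.15, extent=(20.0, 15.0), spacing=1.0)
    cfg = cf.SimulationConfig(n_particles=0, long_axis=20.0, short_axis=15.0,
                              pixel_size=0.1, frame_interval=1.0, duration=5.0,
                              background_noise_sd=1.0, spot_amplitude=150.0, seed=5)
    stack = cf.render_cortex_texture(flow, cfg, n_frames=4)
    field = piv(stack, PivParams(velocity_limit=5.0, time_average=1))
    return {"stack": stack, "field": field, "truth_px": (3.0, -1.5),
            "scale": stack.pixel_size / stack.frame_interval}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
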