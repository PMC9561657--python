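import numpy as np
import pytest

import sarcomorph as sm
from sarcomorph import tracing

from helpers import MATCHED_TEMPLATE, MAX_TILT_DEG  # noqa: F401


@pytest.fixture(scope="session")
def grid_phantom():
    """Mouse-like phantom: delta=0.4, grid mitochondria, 3 periods, 10 nm."""
    spec = sm.preset_spec("mouse_like", n_periods=3, seed=1)
    return sm.build_phantom(spec)


@pytest.fixture(scope="session")
def grid_ground_truth(grid_phantom):
    return sm.ground_truth(grid_phantom)


@pytest.fixture(scope="session")
def tracing_phantom():
    """Straight-filament phantom at tracing resolution (5 nm voxels,
    61 filaments spanning one full sarcomere)."""
    spec = sm.preset_spec("tracing", n_periods=1, half_xy_nm=240.0, seed=1)
    return sm.build_phantom(spec)


@pytest.fixture(scope="session")
def traced_filaments(tracing_phantom):
    """Correlation + tracing run once on the noiseless tracing phantom."""
    gray = sm.render_grayscale(tracing_phantom, snr=np.inf)
    tmpl = tracing.CylinderTemplateParams(**MATCHED_TEMPLATE)
    fields = tracing.cylinder_correlation(gray, tmpl, max_tilt_deg=MAX_TILT_DEG)
    return tracing.trace_lines(fields)
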