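import warnings

import numpy as np
import pytest

from vasomorph.congruence3d import build_all_surfaces, max_feasible_t
from vasomorph.synthio import SyntheticSpec, generate_bed, fit_bed

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def control_spec():
    return SyntheticSpec(n=400, seed=11)


@pytest.fixture(scope="session")
def control_bed(control_spec):
    return generate_bed(control_spec)


@pytest.fixture(scope="session")
def control_fit(control_bed):
    fit, intervals = fit_bed(control_bed, ed_range=(10, 50))
    return fit


@pytest.fixture(scope="session")
def control_intervals(control_bed):
    fit, intervals = fit_bed(control_bed, ed_range=(10, 50))
    return intervals


@pytest.fixture(scope="session")
def surfaces(control_fit):
    """Variant transformation surfaces for the shared control line."""
    return build_all_surfaces(control_fit)


@pytest.fixture(scope="session")
def feasible_t(control_fit):
    """Largest feasible deviation per variant for the shared control line."""
    return {v: max_feasible_t(control_fit, v) for v in range(1, 20)}
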