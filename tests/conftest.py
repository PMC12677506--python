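import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import t1relax as tr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ti_grid():
    """The 50-point inversion-time grid, 100-5000 ms step 100."""
    return tr.DEFAULT_TI_MS.copy()


@pytest.fixture(scope="session")
def two_component():
    """Well-separated two-component model (ratio > 4)."""
    return tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])


@pytest.fixture(scope="session")
def small_suite():
    """One noisy two-component composite dataset (fixed seed)."""
    cfg = tr.SuiteConfig(combinations=("Comb-3",))
    return tr.build_composite_suite(cfg, seed=11)[0]
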