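import numpy as np
import pytest

from gnplem import (
    CellGeometry,
    IrradiationConfig,
    KernelCalibration,
    LQParams,
    make_power_law_kernel,
)
from gnplem.lem import run_scenario


@pytest.fixture(scope="session")
def geom():
    return CellGeometry()


@pytest.fixture(scope="session")
def kernel_10nm():
    return make_power_law_kernel(10.0)


@pytest.fixture(scope="session")
def lq():
    return LQParams()


@pytest.fixture(scope="session")
def study_scale_reductions():
    """Scenario-averaged LEM reductions at the full study scale.

    367,000 GNPs, 10⁴ nucleus integration points, 3 seeds per scenario, for
    both 10 nm and 2 nm particles under the default calibrated kernel. This
    is the expensive fixture shared by the dosimetry acceptance checks.
    """
    seeds = (0, 1, 2)
    out = {}
    for diameter in (10.0, 2.0):
        for scenario in ("uniform_cytoplasm", "perinuclear", "vesicle"):
            df = run_scenario(scenario, 367_000, diameter, seeds=seeds)
            out[(diameter, scenario)] = float(df["reduction_pct"].mean())
    return out
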