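import numpy as np
import pytest

from infusekit.fixtures import adult_single_drug, manifold_fixture, pediatric_single_drug, pediatric_two_drug
from infusekit.policy import ControlParams
from infusekit.transport import DrugSpec, GridSpec


@pytest.fixture(scope="session")
def adult_setup():
    """Adult envelope: manifold, drugs, (carrier, drug rates)."""
    return adult_single_drug()


@pytest.fixture(scope="session")
def pediatric_setup():
    return pediatric_single_drug()


@pytest.fixture(scope="session")
def two_drug_setup():
    return pediatric_two_drug()


@pytest.fixture(scope="session")
def coarse_grid():
    """Desk-scale grid used by most closed-loop tests."""
    return GridSpec(dx_mm=0.5, dt_s=0.5)


@pytest.fixture(scope="session")
def rl_grid():
    """Coarser grid for training-loop tests."""
    return GridSpec(dx_mm=1.0, dt_s=1.0)


def make_params(qc, qd, ratio=5.0, wt=1.0, **kw):
    return ControlParams(
        qc_set=qc, qd_set=dict(qd), qc_max=ratio * qc,
        qd_max={p: ratio * q for p, q in qd.items()}, wt=wt, **kw,
    )


@pytest.fixture(scope="session")
def adult_params(adult_setup):
    _, _, (qc, qd) = adult_setup
    return make_params(qc, qd)
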