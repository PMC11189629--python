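import math

import pytest

from wormrod.cross_section import SectionGeometry, MaterialMap
from wormrod.late_elongation import CycleSchedule, RodCycleModel, late_geometry


@pytest.fixture(scope="session")
def homogeneous_section():
    """A near-homogeneous section for classical-rod oracles.

    The layer boundaries are pushed to the rim and the muscle contrast is
    switched off so the section is a uniform incompressible cylinder to
    within 1e-4 in any stiffness.
    """
    geom = SectionGeometry(R3=10.0, R2p=9.9999999, R2=9.9999998, L=100.0,
                           muscle_band_halfthickness=0.02)
    mats = MaterialMap(mu_epidermis=1e5, mu_actin=1e5, mu_inner=1e5,
                       mu_muscle=1.00001e5)
    return geom, mats


@pytest.fixture(scope="session")
def late_geom():
    return late_geometry()


@pytest.fixture(scope="session")
def default_model():
    """Rod cycle model for the default wild-type schedule (cached)."""
    return RodCycleModel(CycleSchedule())
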