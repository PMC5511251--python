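import numpy as np
import pytest

from fiberdiff import (
    CircularLattice,
    CylinderUnit,
    HierarchicalModel,
    Profile1D,
    default_geometry,
    paper_scenarios,
)


@pytest.fixture(scope="session")
def wt_model() -> HierarchicalModel:
    """Four 106 Å-diameter units on a 160 Å circle."""
    return HierarchicalModel(
        unit=CylinderUnit(r=53.0),
        inner=CircularLattice(4, 80.0),
        outer=CircularLattice(1, 0.0),
    )


@pytest.fixture(scope="session")
def a2v_model() -> HierarchicalModel:
    """Three 36 Å units in a 132 Å bundle, three bundles on a 196 Å circle."""
    return HierarchicalModel(
        unit=CylinderUnit(r=18.0),
        inner=CircularLattice(3, 48.0),
        outer=CircularLattice(3, 98.0),
    )


@pytest.fixture(scope="session")
def scenarios() -> dict:
    return {sc.name: sc for sc in paper_scenarios()}


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture
def simple_profile() -> Profile1D:
    q = np.linspace(0.05, 0.25, 40)
    return Profile1D(q=q, intensity=1.0 + np.sin(10 * q) ** 2, label="simple")
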