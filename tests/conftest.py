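import numpy as np
import pytest

from thermospectra.model_core import (
    InteractionMatrix,
    Model,
    ModelState,
    ResourceParams,
    SpeciesParams,
    WeightGrid,
)
from thermospectra.dynamics_engine import SolverConfig


@pytest.fixture
def species_one():
    return SpeciesParams(
        name="fish",
        w0=1e-3,
        Wi=100.0,
        wmat=20.0,
        h=20.0,
        ks=2.0,
        mu0=0.6,
        Rmax=1e8,
        beta=100.0,
        sigma=1.0,
        theta_R=(1.0,),
        F=0.2,
    )


@pytest.fixture
def resource_one():
    return ResourceParams(
        name="plankton", r0=4.0, kappa=1e11, lambda_=2.05, w_min=1e-7, w_max=1.0
    )


@pytest.fixture
def tiny_model(species_one, resource_one):
    """One species, one resource, coarse grid: fast but fully coupled."""
    return Model([species_one], [resource_one], bins_per_decade=10)


@pytest.fixture
def default_model_coarse():
    """The 3-species archetype community on a coarse grid."""
    from thermospectra.synthetic_data import default_model

    return default_model(bins_per_decade=10)


@pytest.fixture
def fast_solver():
    return SolverConfig(dt=0.2, t_max=150.0, steady_tol=1e-4)


@pytest.fixture
def toy_grid():
    """A 3-bin grid with hand-friendly numbers for quadrature oracles."""
    w = np.array([1.0, 2.0, 4.0])
    dw = np.array([1.0, 2.0, 4.0])
    return WeightGrid(
        w=w,
        dw=dw,
        species_ranges={"fish": (0, 3)},
        resource_ranges={"plankton": (0, 3)},
    )
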