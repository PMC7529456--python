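import numpy as np
import pytest

from cordclose import BilayerVesselModel, baseline_parameters
from cordclose.constitutive import ActiveTone, FiberFamily, LayerMaterial, VesselGeometry
from cordclose.params import VesselParameters


@pytest.fixture(scope="session")
def params():
    return baseline_parameters()


@pytest.fixture(scope="session")
def model(params):
    return BilayerVesselModel(params)


@pytest.fixture(scope="session")
def uniform_model(params):
    """Comparator wall: outer-layer material and contractility throughout."""
    return BilayerVesselModel.uniform_wall(params)


@pytest.fixture(scope="session")
def outer_material(params):
    return params.outer


@pytest.fixture(scope="session")
def inner_material(params):
    return params.inner


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def thin_ring_model():
    """Thin single-material neo-Hookean tube for classical benchmarks."""
    geom = VesselGeometry(A=200.0, B=205.0, C=210.0, lambda_z=1.0)
    mat = LayerMaterial(mu=3.0)
    par = VesselParameters(geometry=geom, inner=mat, outer=mat,
                           tone=ActiveTone(T_act=0.0))
    return BilayerVesselModel(par)
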