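import pytest

from mitralgeom import MeshResolution, ValveParameters, mesh_valve


@pytest.fixture(scope="session")
def default_params() -> ValveParameters:
    return ValveParameters()


@pytest.fixture(scope="session")
def default_mesh(default_params):
    """Coupled valve mesh at a moderate resolution (forced grid points included)."""
    return mesh_valve(default_params, MeshResolution(100, 25))
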