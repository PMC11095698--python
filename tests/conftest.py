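import numpy as np
import pytest
from hypothesis import settings

from angiomt import (
    FixtureSpec,
    TransportParams,
    classify_domains,
    generate_network,
    mesh_segmented_image,
    solve_transport,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def network_seg():
    """A mid-coverage branching network with two islands (deterministic)."""
    spec = FixtureSpec(target_coverage=0.3, islands=2, seed=1)
    mask = generate_network(spec)
    return classify_domains(mask)


@pytest.fixture(scope="session")
def network_mesh(network_seg):
    return mesh_segmented_image(network_seg)


@pytest.fixture(scope="session")
def mm_solution(network_mesh):
    """Michaelis-Menten solve at the physiological demonstration parameters."""
    params = TransportParams.demo("mm")
    sol = solve_transport(network_mesh, params)
    return sol, params


@pytest.fixture(scope="session")
def bar_seg():
    """Full-width horizontal vessel bar (20 px tall) in a 100x100 image."""
    from angiomt.image import BinaryImage

    mask = np.zeros((100, 100), dtype=bool)
    mask[40:60, :] = True
    return classify_domains(BinaryImage(mask, 5e-6))


@pytest.fixture(scope="session")
def bar_mesh(bar_seg):
    return mesh_segmented_image(bar_seg)
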