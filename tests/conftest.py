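import numpy as np
import pytest

import tricotkit
from tricotkit import DesignSpec, Package, TrialDesign, read_design_csv


@pytest.fixture(scope="session")
def example_design() -> TrialDesign:
    """The bundled 20-package, 10-option published example design."""
    return read_design_csv(tricotkit.example_design_path())


@pytest.fixture
def toy_design() -> TrialDesign:
    """Two disjoint packages over six options."""
    spec = DesignSpec(
        n_options=6,
        n_packages=2,
        option_names=("X", "Y", "Z", "U", "V", "W"),
        seed=0,
    )
    return TrialDesign(
        spec=spec,
        packages=(
            Package(package_id=1, options=("X", "Y", "Z")),
            Package(package_id=2, options=("U", "V", "W")),
        ),
    )


@pytest.fixture
def xyz_design() -> TrialDesign:
    spec = DesignSpec(
        n_options=3, n_packages=1, option_names=("X", "Y", "Z"), seed=0
    )
    return TrialDesign(
        spec=spec, packages=(Package(package_id=1, options=("X", "Y", "Z")),)
    )


def random_connected_graph(rng: np.random.Generator, t: int):
    """Random weighted connected graph used by Kirchhoff property tests."""
    from tricotkit import ConcurrenceGraph

    w = np.zeros((t, t), dtype=int)
    # random spanning tree guarantees connectivity
    nodes = list(rng.permutation(t))
    for k in range(1, t):
        a, b = nodes[k], nodes[int(rng.integers(k))]
        w[a, b] = w[b, a] = int(rng.integers(1, 4))
    extra = rng.integers(0, 2 * t)
    for _ in range(int(extra)):
        a, b = rng.integers(t, size=2)
        if a != b:
            w[a, b] = w[b, a] = w[a, b] + 1
    return ConcurrenceGraph(nodes=tuple(f"n{i}" for i in range(t)), weights=w)
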