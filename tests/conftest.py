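import numpy as np
import pytest

from arbormetry.morphology import Morphology
from arbormetry.synthetic import generate_aii, make_fixture


def build_path_morphology(diameters, spacing=1.0, axis="x"):
    """A single unbranched path with a prescribed diameter profile."""
    n = len(diameters)
    k = {"x": 0, "y": 1, "z": 2}[axis]
    xyz = np.zeros((n, 3))
    xyz[:, k] = spacing * np.arange(n)
    return Morphology(
        ids=np.arange(1, n + 1),
        parents=np.concatenate([[-1], np.arange(n - 1)]),
        xyz=xyz,
        radius=np.asarray(diameters, dtype=float) / 2.0,
        labels=np.zeros(n, dtype=int),
    )


@pytest.fixture(scope="session")
def aii_cell():
    """One deterministic synthetic bistratified cell with ground truth."""
    return generate_aii(seed=1)


@pytest.fixture(scope="session")
def aii_population_small():
    """A small deterministic population for recovery checks."""
    from arbormetry.synthetic import generate_population

    return generate_population(n=6, seed=7)


@pytest.fixture()
def cylinder():
    return make_fixture("cylinder")


@pytest.fixture()
def y_tree():
    return make_fixture("y_tree")
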