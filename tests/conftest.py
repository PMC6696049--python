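import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from twnkit.energetics import PotentialParams
from twnkit.fixtures import make_toy_ligand


@pytest.fixture(scope="session")
def params() -> PotentialParams:
    return PotentialParams()


@pytest.fixture(scope="session")
def rod_ligand():
    """Default 12-atom rod: 4 head, 4 linker (one L'), 4 tail."""
    return make_toy_ligand()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_water(rng, center, scale=0.0):
    """A randomly oriented rigid water at (or jittered around) ``center``."""
    from twnkit.fixtures import _TEMPLATE, _random_rotation
    from twnkit.io import WaterMolecule

    pos = np.asarray(center, dtype=float) + scale * rng.normal(size=3)
    sites = _TEMPLATE @ _random_rotation(rng).T + pos
    return WaterMolecule(sites[0], sites[1], sites[2])
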