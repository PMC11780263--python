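import numpy as np
import pytest

from comdyn.structures import BeadStructure
from comdyn.synthetic import BundleSpec, make_two_state_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default two-state bundle fixture (deterministic, seed 0)."""
    return make_two_state_bundle()


@pytest.fixture(scope="session")
def small_bundle():
    """Smaller, scaffold-free bundle for cheap geometric tests."""
    return make_two_state_bundle(
        BundleSpec(residues_per_helix=20, scaffold=False, seed=1)
    )


def make_chain(coords, chain="A", resid_start=1, label="", resnames=None):
    """Hand-rolled helper to build a BeadStructure from bare coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return BeadStructure(
        chain_ids=np.array([chain] * n, dtype=object),
        resids=np.arange(resid_start, resid_start + n),
        resnames=np.array(
            ["ALA"] * n if resnames is None else resnames, dtype=object
        ),
        coords=coords,
        label=label,
        source="test",
    )


@pytest.fixture
def chain_factory():
    return make_chain
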