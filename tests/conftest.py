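"""Shared small fixtures for the unit suite."""

import numpy as np
import pytest

from ribogate.structures import MolecularStructure
from ribogate.topology import build_single_basin, shadow_contact_map


def bead_chain(n: int, seed: int = 0, spacing: float = 2.5,
               noise: float = 1.0) -> MolecularStructure:
    """Random-walk chain of n bonded LB beads (single chain L)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, noise, (n, 3)) + np.array([spacing, 0.0, 0.0])
    return MolecularStructure(
        atom_name=["BD"] * n,
        res_id=np.arange(1, n + 1),
        res_name=["LB"] * n,
        chain_id=["L"] * n,
        coord=np.cumsum(steps, axis=0),
    )


@pytest.fixture
def chain6():
    return bead_chain(6, seed=0)


@pytest.fixture
def chain6_topology(chain6):
    return build_single_basin(chain6, shadow_contact_map(chain6))


@pytest.fixture(scope="session")
def gate_system():
    from ribogate.synth import make_gate_system
    return make_gate_system()
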