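"""Shared fixtures: synthetic networks, landscapes and structures.

Expensive objects (the two-basin toy landscape, polymer networks) are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdcm.ensemble import build_landscape
from mdcm.network import DCMParameters, build_network
from mdcm.synthetic import make_ensemble_toy, make_polymer_protein

TOY_PARAMS = DCMParameters(u_sol=-2.0, v_nat=-0.3)
TOY_T_GRID = np.linspace(150, 1000, 35)


@pytest.fixture(scope="session")
def toy_params():
    return TOY_PARAMS


@pytest.fixture(scope="session")
def two_basin_net(toy_params):
    """Rotor chain with three strong cooperative H-bonds: shows a genuine
    two-basin landscape with a saddle at its melting temperature."""
    return make_ensemble_toy(
        n_rotors=5, n_hbonds=3, params=toy_params, seed=0, u_range=(-4.5, -3.5)
    )


@pytest.fixture(scope="session")
def two_basin_landscape(two_basin_net, toy_params):
    return build_landscape(two_basin_net, toy_params, T_grid=TOY_T_GRID, mech=True)


@pytest.fixture(scope="session")
def tiny_net(toy_params):
    """4 rotors + 2 H-bonds: small enough for fully explicit enumeration in
    test-side oracles."""
    return make_ensemble_toy(
        n_rotors=4, n_hbonds=2, params=toy_params, seed=2, u_range=(-4.0, -1.5)
    )


@pytest.fixture(scope="session")
def helix_atoms():
    atoms, annotations, designed = make_polymer_protein(6, "helix_like", seed=0)
    return atoms, annotations, designed


@pytest.fixture(scope="session")
def helix_net(helix_atoms, toy_params):
    atoms, _, _ = helix_atoms
    return build_network(atoms, toy_params)
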