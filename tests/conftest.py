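"""Shared fixtures: small seeded ensembles and titrations."""

import numpy as np
import pytest

from dendricomplex.dendrimer_model import DendrimerSpec, build_topology
from dendricomplex.synthetic_data import (
    BeadDendrimerModel,
    gen_complex_ensemble,
    gen_dendrimer_ensemble,
)


@pytest.fixture(scope="session")
def rigid_ensemble():
    """Small PPI-like bead ensemble: high stiffness, narrow size distribution."""
    topo = build_topology(DendrimerSpec("PPI", 3))
    return gen_dendrimer_ensemble(BeadDendrimerModel(
        topology=topo, stiffness=50.0, target_rog=1.284, n_frames=20, seed=11))


@pytest.fixture(scope="session")
def flexible_ensemble():
    """Small PAMAM-like bead ensemble: low stiffness, broad size distribution."""
    topo = build_topology(DendrimerSpec("PAMAM", 3))
    return gen_dendrimer_ensemble(BeadDendrimerModel(
        topology=topo, stiffness=4.0, target_rog=1.46, n_frames=20, seed=11))


@pytest.fixture(scope="session")
def internal_complex(rigid_ensemble):
    return gen_complex_ensemble(rigid_ensemble, n_ligands=10, depth="internal",
                                seed=3)


@pytest.fixture(scope="session")
def surface_complex(rigid_ensemble):
    return gen_complex_ensemble(rigid_ensemble, n_ligands=10, depth="surface",
                                seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
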