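"""Shared fixtures: hand-built skeletons and a small synthetic preparation."""

import numpy as np
import pytest

from glomsim.cablesim import MembraneParams, SynapseParams
from glomsim.morphology import (
    SWC_DENDRITE,
    SWC_SOMA,
    Morphology,
    build_compartmental_model,
)
from glomsim.synthetic import CircuitSpec, MorphologySpec, make_bundle


def make_chain(n_nodes: int, spacing: float = 10.0, radius: float = 0.5,
               soma_radius: float = 4.0) -> Morphology:
    """Soma at the origin plus an unbranched dendrite along +x."""
    ids = np.arange(1, n_nodes + 2)
    parents = np.arange(-1, n_nodes)
    xyz = np.zeros((n_nodes + 1, 3))
    xyz[1:, 0] = spacing * np.arange(1, n_nodes + 1)
    radii = np.full(n_nodes + 1, radius)
    radii[0] = soma_radius
    labels = np.full(n_nodes + 1, SWC_DENDRITE)
    labels[0] = SWC_SOMA
    return Morphology(ids=ids, parents=parents, xyz=xyz, radius=radii, labels=labels)


def make_y_tree(arm_nodes: int = 5, spacing: float = 10.0, radius: float = 0.5) -> Morphology:
    """Soma → stem → fork into two arms (three cables)."""
    rows = [(1, SWC_SOMA, 0.0, 0.0, 0.0, 4.0, -1)]
    nid = 2
    # stem along +x
    for k in range(1, arm_nodes + 1):
        rows.append((nid, SWC_DENDRITE, k * spacing, 0.0, 0.0, radius, nid - 1))
        nid += 1
    fork = nid - 1
    for direction in (+1.0, -1.0):
        parent = fork
        for k in range(1, arm_nodes + 1):
            rows.append(
                (nid, SWC_DENDRITE, arm_nodes * spacing + k * spacing * 0.7071,
                 direction * k * spacing * 0.7071, 0.0, radius, parent)
            )
            parent = nid
            nid += 1
    return Morphology(
        ids=np.array([r[0] for r in rows]),
        parents=np.array([-1 if r[6] == -1 else r[6] - 1 for r in rows]),
        xyz=np.array([[r[2], r[3], r[4]] for r in rows]),
        radius=np.array([r[5] for r in rows]),
        labels=np.array([r[1] for r in rows]),
    )


@pytest.fixture(scope="session")
def membrane() -> MembraneParams:
    return MembraneParams()


@pytest.fixture(scope="session")
def syn() -> SynapseParams:
    return SynapseParams()


@pytest.fixture(scope="session")
def chain_model(membrane):
    """Unbranched 500 µm dendrite, d = 1 µm, discretized."""
    morph = make_chain(50, spacing=10.0, radius=0.5)
    return build_compartmental_model(morph, membrane)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic preparation reused by simulation-heavy tests."""
    return make_bundle(
        CircuitSpec(),
        MorphologySpec(target_path_length=800.0),
        seed=0,
    )
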