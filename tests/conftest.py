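"""Shared fixtures.  Expensive model builds are session-scoped so the
deterministic cage ensembles are computed once per run."""

import numpy as np
import pytest

from ccpo import topology as topo
from ccpo import peptides as pep
from ccpo import builder as bld
from ccpo.polyhedra import build_polyhedron
from ccpo.synth import sphere_bead_model


@pytest.fixture(scope="session")
def library():
    return pep.packaged_library()


@pytest.fixture(scope="session")
def bipyramid_topology():
    return topo.bipyramid_reference_topology()


@pytest.fixture(scope="session")
def bipyramid_assignment(bipyramid_topology, library):
    return pep.assign_segments(
        bipyramid_topology, library,
        pep.AssignmentPolicy(mirror_reuse=True, interface_variant="SH"))


@pytest.fixture(scope="session")
def dimer_topology():
    return topo.ChainTopology(segments=((0, 1), (0, 1)),
                              pairing={0: 1, 1: 0},
                              orientations={(0, 1): "parallel"})


@pytest.fixture(scope="session")
def antiparallel_dimer_topology():
    return topo.ChainTopology(segments=((0, 1), (1, 0)),
                              pairing={0: 1, 1: 0},
                              orientations={(0, 1): "antiparallel"})


@pytest.fixture(scope="session")
def bipyramid_ensemble(bipyramid_topology, bipyramid_assignment, library):
    """10-replica seeded ensemble of the single-chain bipyramid."""
    params = bld.BuildParams(replicas=10, seed=42)
    return bld.generate_ensemble(bipyramid_topology, bipyramid_assignment,
                                 params=params, library=library)


@pytest.fixture(scope="session")
def dense_sphere_beads():
    """3000 beads uniformly filling a 5 nm sphere (coords in A)."""
    return sphere_bead_model(5.0, 3000, seed=11)


@pytest.fixture(scope="session")
def tetrahedron():
    return build_polyhedron("tetrahedron")
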