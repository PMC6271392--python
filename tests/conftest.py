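"""Shared fixtures: one synthetic two-state system built once per session.

The standard system is a two-helix mini-bundle with a 6-bead united-atom
ligand threaded through it — large enough to exercise every term type
(CG chain, UA chain, Schiff link, local/non-local pairs, tethers) and
small enough that dynamics-based tests run in seconds.
"""

import numpy as np
import pytest

import rhodosim as rs

#: Free-energy drop of the fixture A→B transition (kcal/mol), the study
#: condition of the transition tests; magnitude matches the instability
#: of a photoisomerized chromophore state.
FIXTURE_DELTA_G = -10.0


@pytest.fixture(scope="session")
def spec():
    return rs.FixtureSpec(
        n_helices=2,
        residues_per_helix=10,
        loop_length=4,
        ligand_length=6,
        seed=1,
        perturbation=0.05,
        flip_dihedral_index=2,
        flip_angle_deg=180.0,
    )


@pytest.fixture(scope="session")
def pair(spec):
    return rs.make_two_state_pair(spec)


@pytest.fixture(scope="session")
def models(pair):
    A, B, topo = pair
    params = rs.ParameterTable()
    mA = rs.map_to_multiscale(A, topo["active_site"], links=topo["links"], params=params)
    mB = rs.map_to_multiscale(B, topo["active_site"], links=topo["links"], params=params)
    return mA, mB, topo, params


@pytest.fixture(scope="session")
def termsets(models):
    mA, mB, topo, params = models
    tsA = rs.parameterize_from_reference(rs.build_topology(mA, params=params), mA, params)
    tsB = rs.parameterize_from_reference(rs.build_topology(mB, params=params), mB, params)
    return tsA, tsB


@pytest.fixture(scope="session")
def bistable(termsets):
    tsA, tsB = termsets
    return rs.build_bistable_ff(tsA, tsB, deltaG_AB=FIXTURE_DELTA_G, epsilon=0.5)


@pytest.fixture(scope="session")
def flip_quad(models):
    """Center indices (i, j, k, l) of the flipped ligand dihedral."""
    mA, _, topo, _ = models
    lig = [mA.center_index("R", 1, f"C{i + 1}") for i in range(6)]
    d0 = topo["flip_dihedral_index"]
    return tuple(lig[d0: d0 + 4])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
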