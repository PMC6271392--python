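"""Mapping, topology enumeration, parameterization, tether machinery."""

import itertools

import numpy as np
import pytest

import rhodosim as rs
from rhodosim.errors import BuildError, ConfigurationError, UsageError
from rhodosim.units import KB_KCAL_MOL_K


def ca_trace(n, spacing=3.8):
    # gently zig-zag chain: realistic non-collinear geometry
    text = []
    for i in range(n):
        y = 0.6 * (i % 2)
        z = 0.3 * (i % 3)
        text.append(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{i * spacing:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    return rs.read_pdb("\n".join(text) + "\nEND\n")


class TestMapping:
    def test_pure_cg_count(self):
        m = rs.map_to_multiscale(ca_trace(10))
        assert m.n_centers == 10
        assert m.is_cg.all()
        assert m.masses[0] == pytest.approx(71.08)  # alanine residue mass

    def test_cg_plus_ua_count(self, pair):
        A, _, topo = pair
        m = rs.map_to_multiscale(A, topo["active_site"], links=topo["links"])
        n_bundle = topo["n_bundle_atoms"]
        assert m.n_centers == n_bundle + 6
        assert int((~m.is_cg).sum()) == 6
        # CG beads first, UA centers last (chromophore region at the end)
        kinds = [c.kind for c in m.centers]
        assert kinds == ["CG"] * n_bundle + ["UA"] * 6

    def test_per_atom_selection_keeps_backbone_bead(self):
        # selecting two "side-chain-like" atoms leaves the residue's CA bead
        s = ca_trace(5)
        from rhodosim.structure_io import Atom, Structure

        extra = [
            Atom("CB", "C", "LYS", 3, "A", (7.6, 1.5, 0.0)),
            Atom("CG", "C", "LYS", 3, "A", (7.6, 3.0, 0.0)),
        ]
        atoms = list(s.atoms)
        atoms = atoms[:3] + extra + atoms[3:]
        s2 = Structure(atoms=atoms)
        m = rs.map_to_multiscale(s2, ["A:3:CB", "A:3:CG"])
        assert m.n_centers == 5 + 2
        assert sum(c.kind == "CG" for c in m.centers) == 5

    def test_empty_structure_and_missing_ca_errors(self):
        from rhodosim.structure_io import Atom, Structure

        with pytest.raises(UsageError):
            rs.map_to_multiscale(Structure(atoms=[]))
        s = Structure(atoms=[Atom("CB", "C", "ALA", 1, "A", (0.0, 0.0, 0.0))])
        with pytest.raises(BuildError):
            rs.map_to_multiscale(s)

    def test_ua_masses_include_hydrogens(self, models):
        mA, _, _, _ = models
        ua = [c for c in mA.centers if c.kind == "UA"]
        assert all(c.mass == pytest.approx(14.027) for c in ua)  # CH2-like beads


class TestTopology:
    def test_four_bead_chain_enumeration(self):
        m = rs.map_to_multiscale(ca_trace(4))
        ts = rs.build_topology(m, cutoff_local=6.0, cutoff_nonlocal=12.0)
        kinds = {}
        for t in ts:
            kinds.setdefault(t.kind, []).append(t)
        assert len(kinds.get("bond", [])) == 3
        assert len(kinds.get("angle", [])) == 2
        assert len(kinds.get("dihedral", [])) == 1
        # 1-4 pair sits at 11.4 Å (just inside non-local cutoff): the only pair
        nonbonded = kinds.get("morse", []) + kinds.get("lj", [])
        assert all(t.locality == "nonlocal" for t in nonbonded)

    def test_unbonded_pair_classified_local(self):
        from rhodosim.structure_io import Atom, Structure

        s = Structure(
            atoms=[
                Atom("CA", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
                Atom("CA", "C", "ALA", 5, "B", (5.0, 0.0, 0.0)),
            ]
        )
        m = rs.map_to_multiscale(s)
        ts = rs.build_topology(m, cutoff_local=6.0, cutoff_nonlocal=12.0)
        nb = [t for t in ts if t.kind == "morse"]
        assert len(nb) == 1
        assert nb[0].locality == "local"
        assert nb[0].params["rmin"] == pytest.approx(5.0)

    def test_partition_is_exhaustive_and_exclusive(self, models):
        # brute-force oracle: every non-excluded pair within the outer cutoff
        # appears exactly once, with the correct locality class
        mA, _, _, params = models
        cl, cn = 6.5, 12.0
        ts = rs.build_topology(mA, cl, cn, params)
        bonds = {tuple(sorted(t.centers)) for t in ts if t.kind == "bond"}
        one_three = set()
        neigh = {}
        for a, b in bonds:
            neigh.setdefault(a, set()).add(b)
            neigh.setdefault(b, set()).add(a)
        for j, ns in neigh.items():
            for i, k in itertools.combinations(sorted(ns), 2):
                one_three.add((i, k))
        X = mA.reference_coords
        seen = {}
        for t in ts:
            if t.kind in ("morse", "lj", "hbond-morse"):
                seen.setdefault(tuple(sorted(t.centers)), []).append(t.locality)
        for i, j in itertools.combinations(range(mA.n_centers), 2):
            pair = (i, j)
            r = np.linalg.norm(X[i] - X[j])
            if pair in bonds or pair in one_three or r > cn:
                assert pair not in seen
            else:
                assert seen[pair] == ["local" if r <= cl else "nonlocal"]

    def test_cutoff_order_validated(self, models):
        mA, _, _, _ = models
        with pytest.raises(UsageError):
            rs.build_topology(mA, cutoff_local=12.0, cutoff_nonlocal=6.0)

    def test_schiff_link_creates_interface_bond(self, models, termsets):
        mA, _, topo, _ = models
        tsA, _ = termsets
        link_blocks = [t.block for t in tsA if t.kind == "bond" and t.block == "UA-CG"]
        assert link_blocks, "expected at least the Schiff-linkage interface bond"


class TestParameterization:
    def test_equilibria_measured_from_reference(self, termsets, models):
        tsA, _ = termsets
        mA, _, _, _ = models
        X = mA.reference_coords
        for t in tsA:
            if t.kind == "bond":
                r = np.linalg.norm(X[t.centers[0]] - X[t.centers[1]])
                assert t.params["r0"] == pytest.approx(r, abs=1e-9)

    def test_secondary_structure_dependent_stiffness(self, termsets, models):
        tsA, _ = termsets
        mA, _, _, _ = models
        ks = {"H": set(), "C": set()}
        for t in tsA:
            if t.kind == "angle" and t.block == "CG-CG":
                label = mA.centers[t.centers[1]].ss
                ks.setdefault(label, set()).add(float(t.params["k"]))
        assert ks["H"] == {30.0}
        assert ks["C"] == {10.0}

    def test_missing_constant_names_key(self, models):
        with pytest.raises(ConfigurationError, match="cg.bond.k"):
            table = rs.ParameterTable()
            table._values.pop("cg.bond.k")
            mA, _, _, _ = models
            rs.parameterize_from_reference(rs.build_topology(mA), mA, table)

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            rs.ParameterTable({"not.a.key": 1.0})

    def test_reference_is_stationary_point_of_bonded_plus_local(self, termsets, models):
        tsA, _ = termsets
        mA, _, _, _ = models
        _, F = rs.energy_and_forces(tsA.bonded_and_local(), mA.reference_coords)
        assert np.abs(F).max() <= 1e-6


class TestMembraneExposure:
    def test_empty_slab_and_saturating_percentile(self, models):
        mA, _, _, _ = models
        with pytest.raises(UsageError):
            rs.flag_membrane_exposed(mA, (1.0, 1.0))
        z = mA.reference_coords[:, 2]
        m = rs.flag_membrane_exposed(mA, (z.min() - 1, z.max() + 1), percentile=0.0)
        assert m.membrane_exposed[m.is_cg].all()
        m2 = rs.flag_membrane_exposed(mA, (z.max() + 10, z.max() + 20))
        assert not m2.membrane_exposed.any()

    def test_percentile_flags_half_in_slab(self):
        m = rs.map_to_multiscale(
            rs.make_helix_bundle(rs.FixtureSpec(n_helices=1, residues_per_helix=20))
        )
        z = m.reference_coords[:, 2]
        m = rs.flag_membrane_exposed(m, (float(z.min()) - 1, float(z.max()) + 1),
                                     percentile=50.0)
        n_in = m.n_centers
        assert abs(int(m.membrane_exposed.sum()) - n_in // 2) <= 1

    def test_only_flagged_beads_get_tethers(self, models, termsets):
        mA, _, _, _ = models
        tsA, _ = termsets
        z = mA.reference_coords[:, 2]
        m = rs.flag_membrane_exposed(mA, (float(z.min()) - 1, float(z.max()) + 1),
                                     percentile=80.0)
        ts = rs.add_tethers(tsA, m, 1.0)
        tether_targets = {t.centers[0] for t in ts if t.kind == "tether"}
        assert tether_targets == set(np.nonzero(m.membrane_exposed)[0])


class TestTetherCalibration:
    def _single_bead_model(self, mass=10.0):
        from rhodosim.model_builder import Center, MultiScaleModel, Selection

        c = Center("CG", "", "A", 1, "ALA", "CA", mass, "C")
        m = MultiScaleModel(
            centers=[c],
            reference_coords=np.zeros((1, 3)),
            active_site=Selection(None),
        )
        m.membrane_exposed = np.array([True])
        return m

    def test_recovers_known_stiffness_by_equipartition(self):
        # a free tethered bead has ⟨Δr²⟩ = 3·k_B·T/K, so the scan must pick
        # the grid point the target profile was generated from
        m = self._single_bead_model()
        ts = rs.TermSet([])
        T = 300.0
        K_true = 2.0
        target = np.array([np.sqrt(3 * KB_KCAL_MOL_K * T / K_true)])
        best, table = rs.calibrate_tether(
            m, ts, target, T_K=T, grid=[0.5, 1.0, 2.0, 4.0, 8.0],
            n_steps=24000, seed=11,
        )
        assert best == K_true
        assert len(table) == 5 and table["mse"].notna().all()

    def test_single_candidate_forced(self):
        m = self._single_bead_model()
        target = np.array([0.5])
        best, _ = rs.calibrate_tether(
            m, rs.TermSet([]), target, grid=[3.0], n_steps=500, seed=1
        )
        assert best == 3.0

    def test_wrong_profile_length_rejected(self):
        m = self._single_bead_model()
        with pytest.raises(UsageError):
            rs.calibrate_tether(m, rs.TermSet([]), np.zeros(4), grid=[1.0])
        with pytest.raises(UsageError):
            rs.calibrate_tether(m, rs.TermSet([]), np.zeros(1), grid=[-1.0])
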