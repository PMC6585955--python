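"""Scaffold scaling, generic assembly, rigid relaxation and the refine contract."""

import numpy as np
import pytest

from cagecraft import cages, core, topology
from cagecraft.errors import ContractViolationError, PlacementError
from cagecraft.functional_groups import FRAGMENT_KEY
from cagecraft.periodic_data import atomic_mass
from cagecraft.polymers import MonomerSpec, assemble_linear


def tri4di6_placements(trialdehyde, diamine):
    t = cages.get_cage_topology("Tri4Di6")
    placements = {("vertex", v.id): trialdehyde for v in t.vertices}
    placements.update({("edge", e.id): diamine for e in t.edges})
    return t, placements


class TestScaffold:
    def test_scale_is_max_bonder_bonder_distance(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        s = max(
            topology.max_bonder_bonder_distance(b) for b in placements.values()
        )
        scaffold = topology.build_scaffold(t, placements)
        assert scaffold.scale == pytest.approx(s)
        for pos in scaffold.vertex_pos.values():
            assert np.linalg.norm(pos) == pytest.approx(s * np.sqrt(3))

    def test_determinism(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        s1 = topology.build_scaffold(t, placements)
        s2 = topology.build_scaffold(t, placements)
        for vid in s1.vertex_pos:
            np.testing.assert_array_equal(s1.vertex_pos[vid], s2.vertex_pos[vid])

    def test_topicity_mismatch_names_the_position(self, diamine):
        t = cages.get_cage_topology("Tri4Di6")
        placements = {("vertex", v.id): diamine for v in t.vertices}
        placements.update({("edge", e.id): diamine for e in t.edges})
        with pytest.raises(PlacementError, match="vertex 0"):
            topology.build_scaffold(t, placements)


class TestAssembly:
    def test_conservation_laws_tetrahedral_cage(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        cage = topology.assemble(t, placements)
        # 4 x 18 + 6 x 12 atoms in; each of 12 imine bonds deletes 2 H + 1 O
        assert cage.molecule.n_atoms == 4 * 18 + 6 * 12 - 12 * 3
        assert len(cage.assembly_bonds) == 2 * len(t.edges)
        bonds_in = 4 * trialdehyde.molecule.n_bonds + 6 * diamine.molecule.n_bonds
        # each deleted H removes 1 bond, each deleted O removes 1 (double) bond
        assert cage.molecule.n_bonds == bonds_in + 12 - 12 * 3
        mass_in = 4 * trialdehyde.molecule.mass() + 6 * diamine.molecule.mass()
        deleted = 12 * (2 * atomic_mass("H") + atomic_mass("O"))
        assert cage.molecule.mass() == pytest.approx(mass_in - deleted, abs=1e-9)

    def test_every_bonder_bonds_exactly_once(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        cage = topology.assemble(t, placements)
        m = cage.molecule
        assembly_ends = []
        for i in cage.assembly_bonds:
            assembly_ends += [m.bonds[i].a, m.bonds[i].b]
        assert len(assembly_ends) == len(set(assembly_ends))
        # every surviving N and carbonyl C participates in exactly one new bond
        ends = {m.atoms[i].element for i in assembly_ends}
        assert ends == {"N", "C"}

    def test_direct_mode_bonds_equal_edges(self, trialdehyde, triamine):
        t = cages.get_cage_topology("Tri1Tri1")
        placements = {("vertex", 0): trialdehyde, ("vertex", 1): triamine}
        out = topology.assemble(t, placements)
        assert len(out.assembly_bonds) == len(t.edges) == 3

    def test_assembly_is_deterministic(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        c1 = topology.assemble(t, placements)
        c2 = topology.assemble(t, placements)
        np.testing.assert_array_equal(c1.molecule.coords(), c2.molecule.coords())


class TestRelaxation:
    def test_single_bond_dimer_reaches_target(self, dialdehyde, diamine):
        chain = assemble_linear(
            "AB",
            {"A": MonomerSpec("A", dialdehyde), "B": MonomerSpec("B", diamine)},
            1,
        )
        topology.relax_assembly_bonds(chain, max_iter=200, tol=1e-4)
        bond = chain.molecule.bonds[chain.assembly_bonds[0]]
        coords = chain.molecule.coords()
        length = np.linalg.norm(coords[bond.a] - coords[bond.b])
        target = topology.default_target_length(chain.molecule, bond)
        assert length == pytest.approx(target, abs=1e-3)

    def test_fixed_point_no_motion(self, dialdehyde, diamine):
        chain = assemble_linear(
            "AB",
            {"A": MonomerSpec("A", dialdehyde), "B": MonomerSpec("B", diamine)},
            1,
        )
        topology.relax_assembly_bonds(chain, max_iter=500, tol=1e-6)
        frozen = chain.molecule.coords().copy()
        topology.relax_assembly_bonds(chain, max_iter=50, tol=1e-6)
        np.testing.assert_allclose(chain.molecule.coords(), frozen, atol=1e-6)

    def test_objective_monotone_and_fragments_rigid(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        cage = topology.assemble(t, placements)
        m = cage.molecule
        fragments = np.array(m.properties[FRAGMENT_KEY])
        coords0 = m.coords().copy()
        intra = [
            (b.a, b.b, np.linalg.norm(coords0[b.a] - coords0[b.b]))
            for b in m.bonds
            if not b.is_assembly_bond
        ]
        objectives = [topology.assembly_bond_objective(cage)]
        for _ in range(10):
            topology.relax_assembly_bonds(cage, max_iter=1)
            objectives.append(topology.assembly_bond_objective(cage))
        assert all(b <= a + 1e-12 for a, b in zip(objectives, objectives[1:]))
        assert objectives[-1] < objectives[0]
        coords = m.coords()
        for a_idx, b_idx, ref in intra:
            assert fragments[a_idx] == fragments[b_idx]
            assert np.linalg.norm(coords[a_idx] - coords[b_idx]) == pytest.approx(
                ref, abs=1e-9
            )


class TestRefineContract:
    def test_identity_plugin_is_a_no_op(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        cage = topology.assemble(t, placements)
        before = cage.molecule.coords().copy()
        topology.refine(cage, lambda m: m)
        np.testing.assert_array_equal(cage.molecule.coords(), before)
        assert cage.molecule.properties["refinement_history"]

    def test_relaxation_adapter_matches_direct_call(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        c1 = topology.assemble(t, placements)
        c2 = topology.assemble(t, placements)
        topology.relax_assembly_bonds(c1, max_iter=20)

        def adapter(m):
            tmp = topology.AssembledMolecule(m, c2.topology, c2.placements, c2.assembly_bonds)
            topology.relax_assembly_bonds(tmp, max_iter=20)
            return tmp.molecule

        topology.refine(c2, adapter)
        np.testing.assert_allclose(c2.molecule.coords(), c1.molecule.coords(), atol=1e-12)

    def test_atom_deleting_plugin_violates_contract(self, trialdehyde, diamine):
        t, placements = tri4di6_placements(trialdehyde, diamine)
        cage = topology.assemble(t, placements)

        def vandal(m):
            return core.Molecule(m.atoms[:-1], [], [m.coords()[:-1]])

        with pytest.raises(ContractViolationError):
            topology.refine(cage, vandal)
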