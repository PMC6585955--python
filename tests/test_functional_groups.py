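"""Functional-group matching, filename deduction and the react/delete steps."""

import itertools

import networkx as nx
import pytest

from cagecraft import core, functional_groups as fg
from cagecraft.periodic_data import atomic_mass


class TestMatching:
    def test_amine_on_ethylenediamine(self):
        m = core.load_molecule("NCCN", "smiles")
        matches = fg.match_functional_groups(m, "amine")
        assert len(matches) == 2
        for match in matches:
            (bonder,) = match.bonder_ids
            assert m.atoms[bonder].element == "N"
            assert len(match.deleter_ids) == 2
            assert all(m.atoms[i].element == "H" for i in match.deleter_ids)

    def test_aldehyde_on_trialdehyde(self, trialdehyde):
        matches = fg.match_functional_groups(trialdehyde.molecule, "aldehyde")
        assert len(matches) == 3
        for match in matches:
            assert trialdehyde.molecule.atoms[match.bonder_ids[0]].element == "C"
            assert [trialdehyde.molecule.atoms[i].element for i in match.deleter_ids] == ["O"]

    def test_no_match_gives_empty_list(self, methane):
        assert fg.match_functional_groups(methane, "amine") == []

    def test_unknown_group_lists_known_names(self, methane):
        with pytest.raises(KeyError, match="amine"):
            fg.match_functional_groups(methane, "vinyl_ether")

    def test_matches_are_atom_disjoint_and_ordered(self):
        m = core.load_molecule("NCC(CN)CN", "smiles")
        matches = fg.match_functional_groups(m, "amine")
        assert len(matches) == 3
        all_atoms = [i for match in matches for i in match.atom_ids]
        assert len(all_atoms) == len(set(all_atoms))
        firsts = [min(match.atom_ids) for match in matches]
        assert firsts == sorted(firsts)

    @pytest.mark.parametrize(
        "smiles,group,pattern_graph",
        [
            # pattern graphs: node elements + edges, simple enough for an
            # independent subgraph-monomorphism oracle
            ("NCCN", "amine", (["N", "H", "H"], [(0, 1), (0, 2)])),
            ("O=Cc1cc(C=O)cc(C=O)c1", "aldehyde", (["C", "O", "H"], [(0, 1), (0, 2)])),
            ("BrCCBr", "bromine", (["*", "Br"], [(0, 1)])),
            ("SCCS", "thiol", (["S", "H", "C"], [(0, 1), (0, 2)])),
        ],
    )
    def test_matching_agrees_with_subgraph_oracle(self, smiles, group, pattern_graph):
        """Matched atom sets equal a brute-force subgraph-isomorphism search."""
        m = core.load_molecule(smiles, "smiles")
        assert m.n_atoms <= 30
        host = nx.Graph()
        for atom in m.atoms:
            host.add_node(atom.index, element=atom.element)
        host.add_edges_from((b.a, b.b) for b in m.bonds)
        elements, edges = pattern_graph
        patt = nx.Graph()
        for i, el in enumerate(elements):
            patt.add_node(i, element=el)
        patt.add_edges_from(edges)
        matcher = nx.algorithms.isomorphism.GraphMatcher(
            host,
            patt,
            node_match=lambda h, p: p["element"] == "*" or h["element"] == p["element"],
        )
        oracle_hits = {
            frozenset(mapping) for mapping in matcher.subgraph_monomorphisms_iter()
        }
        # replicate greedy disjoint selection on the oracle's candidates
        chosen, used = [], set()
        for hit in sorted(oracle_hits, key=lambda h: (min(h), tuple(sorted(h)))):
            if used & hit:
                continue
            used |= hit
            chosen.append(hit)
        ours = {frozenset(match.atom_ids) for match in fg.match_functional_groups(m, group)}
        assert ours == set(map(frozenset, chosen))


class TestFilenameDeduction:
    @pytest.mark.parametrize(
        "path,expected",
        [
            ("mono_amine_1.mol", "amine"),
            ("block7.mol", None),
            ("x_carboxylic_acid.mol", "carboxylic_acid"),
            ("/tmp/dir/My_Aldehyde.pdb", "aldehyde"),
        ],
    )
    def test_longest_substring_rule(self, path, expected):
        assert fg.deduce_fg_from_filename(path) == expected


class TestReaction:
    def _merged_imine_pair(self):
        """Diamine and dialdehyde side by side with attached matches."""
        a = core.load_molecule("NCCN", "smiles")
        b = core.load_molecule("O=CCC=O", "smiles")
        atoms = [core.Atom(x.element) for x in a.atoms] + [
            core.Atom(x.element) for x in b.atoms
        ]
        off = a.n_atoms
        bonds = [core.Bond(x.a, x.b, x.order) for x in a.bonds] + [
            core.Bond(x.a + off, x.b + off, x.order) for x in b.bonds
        ]
        import numpy as np

        coords = np.vstack([a.coords(), b.coords() + [10, 0, 0]])
        m = core.Molecule(atoms, bonds, [coords])
        matches = fg.match_functional_groups(a, "amine") + [
            fg.FunctionalGroupMatch(
                x.fg_name,
                tuple(i + off for i in x.atom_ids),
                tuple(i + off for i in x.bonder_ids),
                tuple(i + off for i in x.deleter_ids),
            )
            for x in fg.match_functional_groups(b, "aldehyde")
        ]
        fg.attach_matches(m, matches)
        return m, matches

    def test_imine_reaction_deletes_two_h_and_one_o(self):
        m, matches = self._merged_imine_pair()
        n0, mass0 = m.n_atoms, m.mass()
        amine, aldehyde = matches[0], matches[2]
        fg.react_pair(m, amine.bonder_ids[0], aldehyde.bonder_ids[0])
        assert m.bonds[-1].is_assembly_bond
        deleted_mass = sum(
            atomic_mass(m.atoms[i].element)
            for i in (*amine.deleter_ids, *aldehyde.deleter_ids)
        )
        m = fg.delete_marked_atoms(m)
        assert m.n_atoms == n0 - 3  # two amine H plus the carbonyl O
        assert m.mass() == pytest.approx(mass0 - deleted_mass, abs=1e-9)
        assert sum(b.is_assembly_bond for b in m.bonds) == 1

    def test_repeat_reaction_on_same_pair_errors(self):
        m, matches = self._merged_imine_pair()
        fg.react_pair(m, matches[0].bonder_ids[0], matches[2].bonder_ids[0])
        with pytest.raises(ValueError, match="already bonded"):
            fg.react_pair(m, matches[0].bonder_ids[0], matches[2].bonder_ids[0])

    def test_same_match_both_sides_errors(self):
        m = core.load_molecule("NCCN", "smiles")
        fg.attach_matches(m, fg.match_functional_groups(m, "amine"))
        bonder = fg.get_attached_matches(m)[0].bonder_ids[0]
        with pytest.raises(ValueError):
            fg.react_pair(m, bonder, bonder)

    def test_halide_coupling_marks_two_halogens(self):
        m = core.load_molecule("BrCCBr", "smiles")
        matches = fg.match_functional_groups(m, "bromine")
        assert len(matches) == 2
        assert all(m.atoms[x.deleter_ids[0]].element == "Br" for x in matches)

    def test_delete_with_no_marks_is_identity(self, methane):
        m = methane.copy()
        out = fg.delete_marked_atoms(m)
        assert core.molecules_equal(out, methane)


class TestRegistration:
    def test_runtime_registration_roundtrip(self):
        defn = fg.FGDefinition("nitrile_test", "[C]#[N]", (0,), (1,))
        fg.register_functional_group(defn)
        try:
            assert fg.get_functional_group("nitrile_test") is defn
            m = core.load_molecule("N#CCC#N", "smiles")
            assert len(fg.match_functional_groups(m, "nitrile_test")) == 2
        finally:
            fg._load_database().pop("nitrile_test")

    def test_overlapping_slots_rejected(self):
        with pytest.raises(ValueError):
            fg.FGDefinition("bad", "[N]([H])[H]", (0,), (0, 1))
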