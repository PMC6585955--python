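"""Data model, format round-trips and rigid-body geometry."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform, pdist

from cagecraft import core
from cagecraft.errors import FormatError, SchemaError, StateError


class TestLoading:
    def test_smiles_gets_explicit_hydrogens_and_one_conformer(self):
        m = core.load_molecule("NCCN", "smiles")
        assert m.n_atoms == 12
        counts = {e: sum(a.element == e for a in m.atoms) for e in ("N", "C", "H")}
        assert counts == {"N": 2, "C": 2, "H": 8}
        assert len(m.conformers) == 1

    def test_smiles_embedding_is_deterministic(self):
        c1 = core.load_molecule("NCCN", "smiles").coords()
        c2 = core.load_molecule("NCCN", "smiles").coords()
        np.testing.assert_array_equal(c1, c2)

    def test_molblock_methane(self, methane):
        assert methane.n_atoms == 5
        assert methane.n_bonds == 4

    def test_empty_source_is_a_format_error(self):
        with pytest.raises(FormatError):
            core.load_molecule("", "mol")
        with pytest.raises(FormatError):
            core.load_molecule("not-a-smiles-((", "smiles")

    def test_unknown_format_tag(self):
        with pytest.raises(ValueError, match="format"):
            core.load_molecule("NCCN", "mol2")


class TestWriting:
    @pytest.mark.parametrize("fmt", ["mol", "pdb"])
    def test_round_trip_preserves_graph(self, fmt):
        m = core.load_molecule("NCCN", "smiles")
        m2 = core.load_molecule(core.write_molecule(m, fmt), fmt)
        assert m2.n_atoms == m.n_atoms
        assert sorted(a.element for a in m2.atoms) == sorted(a.element for a in m.atoms)
        key = lambda b: tuple(sorted((b.a, b.b)))
        assert sorted(map(key, m2.bonds)) == sorted(map(key, m.bonds))

    def test_xyz_preserves_coordinates(self, make_molecule):
        m = make_molecule(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        text = core.write_molecule(m, "xyz")
        m2 = core.load_molecule(text, "xyz")
        np.testing.assert_allclose(m2.coords(), m.coords(), atol=1e-4)

    def test_coordinate_format_without_conformer_errors(self):
        m = core.Molecule([core.Atom("C")], [])
        with pytest.raises(StateError):
            core.write_molecule(m, "xyz")

    def test_empty_molecule_mol_errors(self):
        m = core.Molecule([], [], [np.zeros((0, 3))])
        with pytest.raises(StateError):
            core.write_molecule(m, "mol")


class TestJson:
    def test_round_trip_identity(self, methane):
        m2 = core.json_load(core.json_dump(methane))
        assert core.molecules_equal(methane, m2)

    def test_flags_and_shifts_survive(self, make_molecule):
        m = make_molecule(["C", "N"], [[0, 0, 0], [1.4, 0, 0]])
        m.bonds.append(core.Bond(0, 1, 1, (1, 0, 0), is_assembly_bond=True))
        m.cell = core.UnitCell(np.eye(3) * 10, periodic_dims=3)
        m2 = core.json_load(core.json_dump(m))
        assert m2.bonds[0].is_assembly_bond
        assert m2.bonds[0].lattice_shift == (1, 0, 0)
        assert core.molecules_equal(m, m2)

    def test_truncated_and_foreign_json_raise_schema_error(self, methane):
        text = core.json_dump(methane)
        with pytest.raises(SchemaError):
            core.json_load(text[: len(text) // 2])
        with pytest.raises(SchemaError):
            core.json_load('{"hello": "world"}')


class TestGeometry:
    def test_centroid_examples(self, make_molecule):
        m = make_molecule(["C", "C"], [[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(core.centroid(m), [1, 0, 0])
        tet = make_molecule(
            ["C"] * 4, [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        )
        np.testing.assert_allclose(core.centroid(tet), [0, 0, 0], atol=1e-12)
        single = make_molecule(["C"], [[3, 4, 0]])
        np.testing.assert_allclose(core.centroid(single), [3, 4, 0])

    def test_center_of_mass(self, make_molecule):
        hh = make_molecule(["H", "H"], [[0, 0, 0], [1, 0, 0]])
        np.testing.assert_allclose(core.center_of_mass(hh), [0.5, 0, 0])
        ch = make_molecule(["C", "H"], [[0, 0, 0], [1, 0, 0]])
        assert core.center_of_mass(ch)[0] == pytest.approx(1.008 / 13.019, abs=1e-4)

    def test_com_equals_centroid_for_homonuclear(self, make_molecule):
        rng = np.random.default_rng(0)
        m = make_molecule(["C"] * 7, rng.normal(size=(7, 3)))
        np.testing.assert_allclose(core.center_of_mass(m), core.centroid(m), atol=1e-12)

    def test_max_diameter_examples_and_bruteforce(self, make_molecule):
        m = make_molecule(["C", "C"], [[0, 0, 0], [3, 0, 0]])
        assert core.max_diameter(m) == pytest.approx(3.0)
        sq = make_molecule(["C"] * 4, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert core.max_diameter(sq) == pytest.approx(np.sqrt(2))
        rng = np.random.default_rng(7)
        cloud = rng.normal(size=(50, 3)) * 5
        m = make_molecule(["C"] * 50, cloud)
        brute = max(
            np.linalg.norm(cloud[i] - cloud[j])
            for i in range(50)
            for j in range(i + 1, 50)
        )
        assert core.max_diameter(m) == pytest.approx(brute, abs=1e-12)
        with pytest.raises(ValueError):
            core.max_diameter(make_molecule(["C"], [[0, 0, 0]]))


class TestRigidTransforms:
    def test_translation_moves_centroid(self, methane):
        m = methane.copy()
        before = core.centroid(m)
        core.apply_rigid_transform(m, np.eye(3), [1, 0, 0])
        np.testing.assert_allclose(core.centroid(m), before + [1, 0, 0], atol=1e-12)

    def test_half_turn_about_z(self, make_molecule):
        m = make_molecule(["C"], [[1, 0, 0]])
        rot = core.rotation_about_axis([0, 0, 1], np.pi)
        core.apply_rigid_transform(m, rot, [0, 0, 0])
        np.testing.assert_allclose(m.coords()[0], [-1, 0, 0], atol=1e-12)

    def test_random_rotations_preserve_distance_matrix(self, methane):
        from scipy.spatial.transform import Rotation

        ref = squareform(pdist(methane.coords()))
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = methane.copy()
            rot = Rotation.random(random_state=rng).as_matrix()
            core.apply_rigid_transform(m, rot, rng.normal(size=3))
            np.testing.assert_allclose(squareform(pdist(m.coords())), ref, atol=1e-9)

    def test_improper_rotation_rejected(self, methane):
        bad = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(ValueError):
            core.apply_rigid_transform(methane.copy(), bad, [0, 0, 0])
        with pytest.raises(ValueError):
            core.apply_rigid_transform(methane.copy(), np.eye(3) * 2, [0, 0, 0])


class TestAlignVectors:
    def test_quarter_turn(self, make_molecule):
        m = make_molecule(["C", "C"], [[0, 0, 0], [1, 0, 0]])
        core.align_vectors(m, [1, 0, 0], [0, 1, 0])
        v = m.coords()[1] - m.coords()[0]
        assert np.dot(v, [0, 1, 0]) / np.linalg.norm(v) >= 1 - 1e-9

    def test_parallel_is_identity(self, methane):
        m = methane.copy()
        before = m.coords().copy()
        core.align_vectors(m, [1, 2, 3], [2, 4, 6])
        np.testing.assert_allclose(m.coords(), before, atol=1e-12)

    def test_antiparallel_is_deterministic_half_turn(self, make_molecule):
        results = []
        for _ in range(2):
            m = make_molecule(["C", "C"], [[0, 0, 0], [1, 0, 0]])
            core.align_vectors(m, [1, 0, 0], [-1, 0, 0])
            v = m.coords()[1] - m.coords()[0]
            assert np.dot(v, [-1, 0, 0]) >= 1 - 1e-9
            results.append(m.coords().copy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_random_pairs_align_within_tolerance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            f, t = rng.normal(size=3), rng.normal(size=3)
            rot = core.rotation_between_vectors(f, t)
            image = rot @ (f / np.linalg.norm(f))
            cos = np.dot(image, t / np.linalg.norm(t))
            assert cos >= 1 - 1e-9

    def test_zero_vector_rejected(self, methane):
        with pytest.raises(ValueError):
            core.align_vectors(methane.copy(), [0, 0, 0], [1, 0, 0])
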