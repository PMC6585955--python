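"""Molecular data model, rigid-body geometry and file/JSON round-tripping.

The in-memory :class:`Molecule` is a deliberately small graph-plus-
coordinates container.  It differs from an RDKit mol in two ways that
matter for supramolecular assembly: every bond can carry an integer
lattice-shift vector (for bonds that cross a periodic cell boundary)
and a flag marking it as created during assembly rather than present
in a building block.  RDKit does the heavy lifting for parsing and
writing the standard chemical formats; conversion helpers keep the two
representations in sync.

Coordinates are Cartesian angstroms.  Atom indices are 0-based
everywhere in the API; they become 1-based only inside MOL/PDB
records, where the format demands it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .errors import FormatError, SchemaError, StateError
from .periodic_data import atomic_mass, is_known_element

JSON_SCHEMA_VERSION = 1

#: bond orders: 1, 2, 3 or the string "aromatic"
BondOrder = "int | str"


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    index: int = 0

    def __post_init__(self) -> None:
        if not is_known_element(self.element):
            raise ValueError(f"unknown element symbol: {self.element!r}")


@dataclass
class Bond:
    a: int
    b: int
    order: "int | str" = 1
    lattice_shift: tuple[int, int, int] = (0, 0, 0)
    is_assembly_bond: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("bond endpoints must differ")
        self.lattice_shift = tuple(int(x) for x in self.lattice_shift)
        if self.order not in (1, 2, 3, "aromatic"):
            raise ValueError(f"unsupported bond order: {self.order!r}")

    @property
    def is_periodic(self) -> bool:
        return any(self.lattice_shift)


@dataclass
class UnitCell:
    """Lattice vectors, row convention: ``vectors[i]`` is the i-th vector in A."""

    vectors: np.ndarray
    periodic_dims: int = 3

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.vectors)) < 1e-9:
            raise ValueError("lattice vectors must be linearly independent")
        if self.periodic_dims not in (2, 3):
            raise ValueError("periodic_dims must be 2 or 3")


class Molecule:
    """Atoms, bonds and one or more conformer coordinate sets."""

    def __init__(
        self,
        atoms: "list[Atom]",
        bonds: "list[Bond]",
        conformers: "list[np.ndarray] | None" = None,
        properties: "dict | None" = None,
        cell: "UnitCell | None" = None,
    ) -> None:
        self.atoms = list(atoms)
        for i, atom in enumerate(self.atoms):
            atom.index = i
        self.bonds = list(bonds)
        n = len(self.atoms)
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond ({bond.a},{bond.b}) exceeds atom count {n}")
        self.conformers: list[np.ndarray] = []
        for conf in conformers or []:
            self.add_conformer(conf)
        self.properties = dict(properties or {})
        self.cell = cell

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def is_periodic(self) -> bool:
        return self.cell is not None

    def add_conformer(self, coords: np.ndarray) -> int:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"conformer shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        self.conformers.append(coords.copy())
        return len(self.conformers) - 1

    def coords(self, conformer: int = 0) -> np.ndarray:
        try:
            return self.conformers[conformer]
        except IndexError:
            raise IndexError(
                f"no conformer {conformer}; molecule has {len(self.conformers)}"
            ) from None

    def copy(self) -> "Molecule":
        m = Molecule(
            [replace(a) for a in self.atoms],
            [replace(b) for b in self.bonds],
            [c.copy() for c in self.conformers],
            json.loads(json.dumps(self.properties)) if self.properties else {},
            UnitCell(self.cell.vectors.copy(), self.cell.periodic_dims)
            if self.cell
            else None,
        )
        return m

    def mass(self) -> float:
        return float(sum(atomic_mass(a.element) for a in self.atoms))

    def graph(self) -> nx.MultiGraph:
        """Bond graph with element node labels and order edge labels."""
        g = nx.MultiGraph()
        for atom in self.atoms:
            g.add_node(atom.index, element=atom.element)
        for bond in self.bonds:
            g.add_edge(bond.a, bond.b, order=bond.order)
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Molecule({self.n_atoms} atoms, {self.n_bonds} bonds, "
            f"{len(self.conformers)} conformer(s))"
        )


def molecules_equal(m1: Molecule, m2: Molecule, coord_tol: "float | None" = 1e-6) -> bool:
    """Field-for-field equality; ``coord_tol=None`` skips coordinates."""
    if [a.element for a in m1.atoms] != [a.element for a in m2.atoms]:
        return False
    if [a.formal_charge for a in m1.atoms] != [a.formal_charge for a in m2.atoms]:
        return False
    key = lambda b: (b.a, b.b, str(b.order), b.lattice_shift, b.is_assembly_bond)
    if sorted(map(key, m1.bonds)) != sorted(map(key, m2.bonds)):
        return False
    if coord_tol is not None:
        if len(m1.conformers) != len(m2.conformers):
            return False
        for c1, c2 in zip(m1.conformers, m2.conformers):
            if not np.allclose(c1, c2, atol=coord_tol):
                return False
    if (m1.cell is None) != (m2.cell is None):
        return False
    if m1.cell is not None and not np.allclose(m1.cell.vectors, m2.cell.vectors):
        return False
    return True


# ---------------------------------------------------------------------------
# RDKit interconversion
# ---------------------------------------------------------------------------

def _rdkit():
    from rdkit import Chem

    return Chem


_ORDER_TO_RD = {1: "SINGLE", 2: "DOUBLE", 3: "TRIPLE", "aromatic": "AROMATIC"}


def to_rdkit(m: Molecule, conformer: "int | None" = 0):
    """Build an (unsanitized) RDKit mol mirroring this molecule."""
    Chem = _rdkit()
    rw = Chem.RWMol()
    for atom in m.atoms:
        rd_atom = Chem.Atom(atom.element)
        rd_atom.SetFormalCharge(atom.formal_charge)
        rd_atom.SetNoImplicit(True)
        rw.AddAtom(rd_atom)
    for bond in m.bonds:
        bt = getattr(Chem.BondType, _ORDER_TO_RD[bond.order])
        rw.AddBond(bond.a, bond.b, bt)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    if conformer is not None and m.conformers:
        conf = Chem.Conformer(m.n_atoms)
        for i, xyz in enumerate(m.coords(conformer)):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol.AddConformer(conf, assignId=True)
    return mol


def from_rdkit(rdmol) -> Molecule:
    """Convert an RDKit mol (hydrogens should already be explicit)."""
    _rd_to_order = {
        "SINGLE": 1,
        "DOUBLE": 2,
        "TRIPLE": 3,
        "AROMATIC": "aromatic",
    }
    atoms = [
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetIdx())
        for a in rdmol.GetAtoms()
    ]
    bonds = []
    for b in rdmol.GetBonds():
        name = str(b.GetBondType())
        order = _rd_to_order.get(name, 1)
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    conformers = [
        np.array(conf.GetPositions(), dtype=float)
        for conf in rdmol.GetConformers()
    ]
    return Molecule(atoms, bonds, conformers)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_source(source: str) -> str:
    if os.path.isfile(source):
        with open(source) as fh:
            return fh.read()
    return source


def _fallback_embed(rdmol, seed: int = 42) -> None:
    """Deterministic spring-layout coordinates when distance geometry fails.

    Crude by design: only used for exotic patterns RDKit cannot embed.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    g = nx.Graph()
    g.add_nodes_from(range(rdmol.GetNumAtoms()))
    g.add_edges_from(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()
    )
    pos = nx.spring_layout(g, dim=3, seed=seed, scale=0.75 * g.number_of_nodes() ** 0.5)
    conf = Chem.Conformer(rdmol.GetNumAtoms())
    for i in range(rdmol.GetNumAtoms()):
        x, y, z = (1.5 * pos[i]).tolist()
        conf.SetAtomPosition(i, Point3D(x, y, z))
    rdmol.AddConformer(conf, assignId=True)


def _embed(rdmol, seed: int = 42):
    """Seeded distance-geometry embedding; reproducible across runs."""
    from rdkit.Chem import AllChem

    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            _fallback_embed(rdmol, seed)
    return rdmol


def load_molecule(source: str, format: str) -> Molecule:
    """Load a molecule from a file path or in-memory text.

    ``format`` is one of ``mol`` (V2000), ``pdb``, ``xyz``, ``smiles`` or
    ``smarts``.  Line notations get deterministic 3D coordinates
    (distance-geometry embedding, fixed seed).  The result always has
    explicit hydrogens and exactly one conformer.
    """
    Chem = _rdkit()
    fmt = format.lower()
    if fmt in ("mol", "sdf"):
        text = _read_source(source)
        if not text.strip():
            raise FormatError("empty MOL input")
        rdmol = Chem.MolFromMolBlock(text, removeHs=False, sanitize=True)
        if rdmol is None:
            raise FormatError(f"unparseable MOL block (first line: {text.splitlines()[0]!r})")
        rdmol = Chem.AddHs(rdmol, addCoords=True)
        return from_rdkit(rdmol)
    if fmt == "pdb":
        text = _read_source(source)
        if not text.strip():
            raise FormatError("empty PDB input")
        rdmol = Chem.MolFromPDBBlock(text, removeHs=False, sanitize=True)
        if rdmol is None:
            raise FormatError("unparseable PDB block")
        rdmol = Chem.AddHs(rdmol, addCoords=True)
        return from_rdkit(rdmol)
    if fmt == "xyz":
        return _load_xyz(_read_source(source))
    if fmt == "smiles":
        smi = _read_source(source).strip()
        rdmol = Chem.MolFromSmiles(smi)
        if rdmol is None:
            raise FormatError(f"unparseable SMILES: {smi!r}")
        rdmol = Chem.AddHs(rdmol)
        _embed(rdmol)
        return from_rdkit(rdmol)
    if fmt == "smarts":
        sma = _read_source(source).strip()
        rdmol = Chem.MolFromSmarts(sma)
        if rdmol is None:
            raise FormatError(f"unparseable SMARTS: {sma!r}")
        rdmol = Chem.RWMol(rdmol).GetMol()
        rdmol.UpdatePropertyCache(strict=False)
        try:
            Chem.SanitizeMol(rdmol, catchErrors=True)
            rdmol = Chem.AddHs(rdmol)
            _embed(rdmol)
        except Exception:
            _fallback_embed(rdmol)
        return from_rdkit(rdmol)
    raise ValueError(f"unknown format: {format!r}")


def _load_xyz(text: str) -> Molecule:
    lines = text.splitlines()
    if not lines:
        raise FormatError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"bad XYZ count line: {lines[0]!r}") from None
    atoms, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"bad XYZ atom line: {ln!r}")
        atoms.append(Atom(parts[0]))
        coords.append([float(v) for v in parts[1:4]])
    if len(atoms) != n:
        raise FormatError(f"XYZ promises {n} atoms, found {len(atoms)}")
    return Molecule(atoms, [], [np.array(coords)])


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_molecule(m: Molecule, format: str, conformer: int = 0) -> str:
    """Serialize to ``mol``, ``pdb``, ``xyz`` or ``smiles`` text."""
    Chem = _rdkit()
    fmt = format.lower()
    if fmt != "smiles" and not m.conformers:
        raise StateError(f"format {fmt!r} needs coordinates but molecule has no conformer")
    if fmt == "mol":
        if m.n_atoms == 0:
            raise StateError("cannot write a MOL record for an empty molecule")
        rdmol = to_rdkit(m, conformer)
        return Chem.MolToMolBlock(rdmol, kekulize=False)
    if fmt == "pdb":
        rdmol = to_rdkit(m, conformer)
        return Chem.MolToPDBBlock(rdmol)
    if fmt == "xyz":
        lines = [str(m.n_atoms), "generated by cagecraft"]
        for atom, xyz in zip(m.atoms, m.coords(conformer)):
            lines.append(
                f"{atom.element:<3s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "smiles":
        rdmol = to_rdkit(m, conformer=None)
        return Chem.MolToSmiles(rdmol)
    raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# JSON persistence (schema version 1)
# ---------------------------------------------------------------------------

def json_dump(m: Molecule) -> str:
    payload = {
        "schema": JSON_SCHEMA_VERSION,
        "atoms": [
            {"element": a.element, "charge": a.formal_charge} for a in m.atoms
        ],
        "bonds": [
            {
                "a": b.a,
                "b": b.b,
                "order": b.order,
                "lattice_shift": list(b.lattice_shift),
                "is_assembly_bond": b.is_assembly_bond,
            }
            for b in m.bonds
        ],
        "conformers": [c.tolist() for c in m.conformers],
        "properties": m.properties,
        "cell": None
        if m.cell is None
        else {
            "vectors": m.cell.vectors.tolist(),
            "periodic_dims": m.cell.periodic_dims,
        },
    }
    return json.dumps(payload, indent=1)


def json_load(text: str) -> Molecule:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from None
    if not isinstance(payload, dict):
        raise SchemaError("top-level JSON value must be an object")
    if payload.get("schema") != JSON_SCHEMA_VERSION:
        raise SchemaError(f"bad or missing key 'schema': {payload.get('schema')!r}")
    for key in ("atoms", "bonds", "conformers"):
        if key not in payload:
            raise SchemaError(f"missing key {key!r}")
    try:
        atoms = [Atom(a["element"], a.get("charge", 0)) for a in payload["atoms"]]
        bonds = [
            Bond(
                b["a"],
                b["b"],
                b["order"] if isinstance(b["order"], str) else int(b["order"]),
                tuple(b.get("lattice_shift", (0, 0, 0))),
                bool(b.get("is_assembly_bond", False)),
            )
            for b in payload["bonds"]
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed atom/bond record: {exc}") from None
    cell = None
    if payload.get("cell") is not None:
        cell = UnitCell(
            np.array(payload["cell"]["vectors"]),
            int(payload["cell"]["periodic_dims"]),
        )
    return Molecule(
        atoms,
        bonds,
        [np.array(c, dtype=float) for c in payload["conformers"]],
        payload.get("properties", {}),
        cell,
    )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def centroid(m: Molecule, conformer: int = 0) -> np.ndarray:
    """Unweighted arithmetic mean of the atom positions."""
    coords = m.coords(conformer)
    if coords.shape[0] == 0:
        raise ValueError("centroid of an empty molecule is undefined")
    return coords.mean(axis=0)


def center_of_mass(m: Molecule, conformer: int = 0) -> np.ndarray:
    """Mass-weighted mean position using standard atomic masses."""
    coords = m.coords(conformer)
    masses = np.array([atomic_mass(a.element) for a in m.atoms])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def max_diameter(m: Molecule, conformer: int = 0) -> float:
    """Largest centre-to-centre distance between any two atoms."""
    coords = m.coords(conformer)
    if coords.shape[0] < 2:
        raise ValueError("max_diameter needs at least two atoms")
    return float(pdist(coords).max())


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthonormal")
    if not math.isclose(np.linalg.det(rotation), 1.0, abs_tol=1e-8):
        raise ValueError("rotation matrix must be proper (det=+1)")
    return rotation


def apply_rigid_transform(
    m: Molecule,
    rotation: np.ndarray,
    translation: np.ndarray,
    conformer: int = 0,
) -> Molecule:
    """Apply ``x -> R x + t`` to every atom of the chosen conformer, in place."""
    rotation = _check_rotation(rotation)
    translation = np.asarray(translation, dtype=float).reshape(3)
    coords = m.coords(conformer)
    m.conformers[conformer] = coords @ rotation.T + translation
    return m


def rotation_between_vectors(from_vec: np.ndarray, to_vec: np.ndarray) -> np.ndarray:
    """Proper rotation taking ``from_vec`` direction onto ``to_vec`` direction.

    The anti-parallel case has no unique axis; it is resolved
    deterministically by rotating 180 degrees about the normalized
    cross product of ``from_vec`` with the Cartesian basis vector least
    aligned with it.
    """
    f = np.asarray(from_vec, dtype=float)
    t = np.asarray(to_vec, dtype=float)
    nf, nt = np.linalg.norm(f), np.linalg.norm(t)
    if nf < 1e-12 or nt < 1e-12:
        raise ValueError("cannot align a zero vector")
    f, t = f / nf, t / nt
    c = float(np.clip(np.dot(f, t), -1.0, 1.0))
    if c >= 1.0 - 1e-12:
        return np.eye(3)
    if c <= -1.0 + 1e-12:
        basis = np.eye(3)[np.argmin(np.abs(f))]
        axis = np.cross(f, basis)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(math.pi * axis).as_matrix()
    axis = np.cross(f, t)
    angle = math.atan2(np.linalg.norm(axis), c)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def align_vectors(
    m: Molecule,
    from_vec: np.ndarray,
    to_vec: np.ndarray,
    conformer: int = 0,
) -> Molecule:
    """Rotate the conformer (about its centroid) so ``from_vec`` maps onto ``to_vec``."""
    rot = rotation_between_vectors(from_vec, to_vec)
    pivot = centroid(m, conformer)
    coords = m.coords(conformer)
    m.conformers[conformer] = (coords - pivot) @ rot.T + pivot
    return m


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation of *angle* radians about *axis*."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be nonzero")
    return Rotation.from_rotvec(angle * axis / n).as_matrix()
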