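"""Periodic 2D covalent organic frameworks.

Four 2-periodic nets are supported — honeycomb (*hcb*), hexagonal
(*hxl*), square (*sql*) and kagome (*kgm*).  A multi-topic block sits
on every vertex (3-topic for hcb, 6-topic for hxl, 4-topic for sql
and kgm) with its bonder atoms flat on the xy plane, a ditopic block
sits on every edge, and bonds that close onto a translated image of
the cell carry an integer lattice-shift vector.  The net definitions
use the standard crystallographic descriptions: fractional vertex
positions and edge shift vectors chosen so every edge has the same
length; coordinates are normalized so the unit edge length is 1
before the block-size scaling shared with cage assembly is applied.

The assembled cell can be serialized to a generic lattice-input text
(cell vectors + Cartesian coordinates + explicit connectivity with
shift annotations) or an extended-XYZ file, and finite molecular
"islands" of any nx x ny size can be carved out with hydrogen caps
replacing the severed periodic bonds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import core
from .building_blocks import BuildingBlock
from .errors import ApplicabilityError, PlacementError
from .functional_groups import FRAGMENT_KEY
from .periodic_data import covalent_radius
from .topology import AssembledMolecule, Edge, TopologySpec, Vertex, assemble

_SQRT3 = math.sqrt(3.0)

#: out-of-plane spacing of the single layer, in angstroms
LAYER_SPACING = 30.0


@dataclass(frozen=True)
class NetSpec:
    """A 2-periodic net: fractional vertices, shifted edges, unit cell."""

    name: str
    cell_2d: tuple  # ((ax, ay), (bx, by)) before edge-length normalization
    vertices: tuple  # fractional (fx, fy) pairs
    edges: tuple  # (u, v, (sx, sy)) triples
    coordination: int

    def unit_edge_length(self) -> float:
        a = np.array(self.cell_2d[0])
        b = np.array(self.cell_2d[1])
        u, v, (sx, sy) = self.edges[0]
        fu = np.array(self.vertices[u])
        fv = np.array(self.vertices[v]) + (sx, sy)
        return float(np.linalg.norm((fv[0] - fu[0]) * a + (fv[1] - fu[1]) * b))


_HEX_CELL = ((1.0, 0.0), (-0.5, _SQRT3 / 2))

_NETS = {
    "hcb": NetSpec(
        "hcb",
        _HEX_CELL,
        ((1 / 3, 2 / 3), (2 / 3, 1 / 3)),
        ((0, 1, (0, 0)), (0, 1, (-1, 0)), (0, 1, (0, 1))),
        coordination=3,
    ),
    "hxl": NetSpec(
        "hxl",
        _HEX_CELL,
        ((0.0, 0.0),),
        ((0, 0, (1, 0)), (0, 0, (0, 1)), (0, 0, (1, 1))),
        coordination=6,
    ),
    "sql": NetSpec(
        "sql",
        ((1.0, 0.0), (0.0, 1.0)),
        ((0.0, 0.0),),
        ((0, 0, (1, 0)), (0, 0, (0, 1))),
        coordination=4,
    ),
    "kgm": NetSpec(
        "kgm",
        _HEX_CELL,
        ((0.5, 0.0), (0.0, 0.5), (0.5, 0.5)),
        (
            (0, 2, (0, 0)),
            (1, 2, (0, 0)),
            (0, 1, (1, 0)),
            (0, 2, (0, -1)),
            (1, 2, (-1, 0)),
            (0, 1, (0, -1)),
        ),
        coordination=4,
    ),
}

_ALIASES = {
    "honeycomb": "hcb",
    "hexagonal": "hxl",
    "square": "sql",
    "kagome": "kgm",
}


def cof_net_names() -> list[str]:
    return list(_NETS)


def get_cof_net(name: str) -> NetSpec:
    key = _ALIASES.get(name.lower(), name.lower())
    if key not in _NETS:
        raise KeyError(
            f"unknown net {name!r}; known: {', '.join([*_NETS, *_ALIASES])}"
        )
    return _NETS[key]


def net_to_topology(net: NetSpec, vertex_rotation: float = 0.0) -> TopologySpec:
    """Expand a net into a periodic :class:`~cagecraft.topology.TopologySpec`.

    Cartesian unit coordinates are scaled so the edge length is 1; the
    third lattice vector is a placeholder normal that is reset to the
    fixed layer spacing after block-size scaling.
    """
    L0 = net.unit_edge_length()
    a = np.array([*net.cell_2d[0], 0.0]) / L0
    b = np.array([*net.cell_2d[1], 0.0]) / L0
    c = np.array([0.0, 0.0, 10.0])
    vertices = [
        Vertex(i, fx * a + fy * b) for i, (fx, fy) in enumerate(net.vertices)
    ]
    edges = [
        Edge(eid, (u, v), None, (sx, sy, 0))
        for eid, (u, v, (sx, sy)) in enumerate(net.edges)
    ]
    return TopologySpec(
        net.name,
        vertices,
        edges,
        "cof_2d",
        "blocks_on_edges",
        core.UnitCell(np.array([a, b, c]), periodic_dims=2),
        vertex_rotation,
    )


def assemble_cof(
    net_name: str,
    multitopic: BuildingBlock,
    ditopic: BuildingBlock,
    vertex_rotation: float = 0.0,
    edge_flags: "dict[int, bool] | None" = None,
    cell_scale: "float | None" = None,
) -> AssembledMolecule:
    """Assemble one periodic unit cell of a 2D COF.

    ``vertex_rotation`` (degrees, about z) rotates every vertex block
    in-plane, producing structural isomers for asymmetric blocks.
    ``cell_scale`` overrides the automatic block-size scale factor.
    """
    net = get_cof_net(net_name)
    if multitopic.topicity != net.coordination:
        raise PlacementError(
            f"net {net.name!r} needs a {net.coordination}-topic vertex block, "
            f"got topicity {multitopic.topicity}"
        )
    if ditopic.topicity != 2:
        raise PlacementError("edge blocks must be ditopic")
    t = net_to_topology(net, vertex_rotation)
    if cell_scale is not None:
        t.vertices = [
            Vertex(v.id, v.unit_position * cell_scale, v.edge_ids, v.alignment_choice)
            for v in t.vertices
        ]
        t.cell = core.UnitCell(
            np.vstack([t.cell.vectors[:2] * cell_scale, t.cell.vectors[2:]]), 2
        )
    placements = {("vertex", v.id): multitopic for v in t.vertices}
    placements.update({("edge", e.id): ditopic for e in t.edges})
    out = assemble(t, placements, edge_parallel=edge_flags)
    # the out-of-plane vector is a fixed single-layer spacing, not block-scaled
    vecs = out.molecule.cell.vectors.copy()
    vecs[2] = (0.0, 0.0, LAYER_SPACING)
    out.molecule.cell = core.UnitCell(vecs, periodic_dims=2)
    out.topology.cell = out.molecule.cell
    return out


# ---------------------------------------------------------------------------
# Periodic output
# ---------------------------------------------------------------------------

def write_periodic_cell(a: AssembledMolecule, format: str = "lattice_input") -> str:
    """Serialize a periodic assembly; byte-deterministic.

    ``lattice_input`` is a generic GULP-style text: a cell block, a
    Cartesian coordinate block and an explicit connectivity list in
    which periodic bonds carry their lattice-shift vectors.
    ``xyz_extended`` emits coordinates with the cell on the comment
    line (extended-XYZ convention).
    """
    if not a.is_periodic:
        raise ApplicabilityError("molecule is not periodic; write it as mol/xyz instead")
    m = a.molecule
    coords = m.coords(0)
    vecs = m.cell.vectors
    if format == "lattice_input":
        lines = [f"# cagecraft lattice_input v1: {a.topology.name}", "vectors"]
        for v in vecs:
            lines.append(f"  {v[0]:12.6f} {v[1]:12.6f} {v[2]:12.6f}")
        lines.append(f"cartesian {m.n_atoms}")
        for atom, xyz in zip(m.atoms, coords):
            lines.append(
                f"  {atom.element:<3s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}"
            )
        lines.append(f"connectivity {m.n_bonds}")
        for b in m.bonds:
            tag = " assembly" if b.is_assembly_bond else ""
            sx, sy, sz = b.lattice_shift
            lines.append(f"  {b.a} {b.b} {b.order} {sx} {sy} {sz}{tag}")
        return "\n".join(lines) + "\n"
    if format == "xyz_extended":
        flat = " ".join(f"{x:.6f}" for x in vecs.flatten())
        lines = [str(m.n_atoms), f'Lattice="{flat}" Properties=species:S:1:pos:R:3']
        for atom, xyz in zip(m.atoms, coords):
            lines.append(
                f"{atom.element:<3s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown periodic format: {format!r}")


# ---------------------------------------------------------------------------
# Molecular islands
# ---------------------------------------------------------------------------

def carve_island(a: AssembledMolecule, nx: int, ny: int) -> core.Molecule:
    """Cut a finite nx x ny supercell out of a periodic framework.

    Bonds whose shifted image falls inside the supercell become real
    bonds; severed boundary bonds are replaced by hydrogen caps placed
    along the former bond vector at the capped atom's covalent radius
    plus that of hydrogen.  Every dangling end of a severed bond is
    capped, so the atom count is ``nx * ny * atoms_per_cell + caps``.
    """
    if not a.is_periodic:
        raise ApplicabilityError("carve_island needs a periodic assembly")
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    m = a.molecule
    coords = m.coords(0)
    vecs = m.cell.vectors
    n_cell = m.n_atoms

    def cell_offset(i: int, j: int) -> np.ndarray:
        return i * vecs[0] + j * vecs[1]

    atoms, new_coords, bonds = [], [], []
    index = {}
    for i in range(nx):
        for j in range(ny):
            for k, atom in enumerate(m.atoms):
                index[(i, j, k)] = len(atoms)
                atoms.append(core.Atom(atom.element, atom.formal_charge))
                new_coords.append(coords[k] + cell_offset(i, j))

    caps = []  # (host index in new numbering, cap position)
    rH = covalent_radius("H")
    for i in range(nx):
        for j in range(ny):
            for bond in m.bonds:
                sx, sy, _ = bond.lattice_shift
                if (sx, sy) == (0, 0):
                    bonds.append(
                        core.Bond(
                            index[(i, j, bond.a)],
                            index[(i, j, bond.b)],
                            bond.order,
                            (0, 0, 0),
                            bond.is_assembly_bond,
                        )
                    )
                    continue
                ti, tj = i + sx, j + sy
                if 0 <= ti < nx and 0 <= tj < ny:
                    bonds.append(
                        core.Bond(
                            index[(i, j, bond.a)],
                            index[(ti, tj, bond.b)],
                            bond.order,
                            (0, 0, 0),
                            bond.is_assembly_bond,
                        )
                    )
                else:
                    # outgoing end: cap atom a towards the missing image of b
                    host = index[(i, j, bond.a)]
                    target = coords[bond.b] + cell_offset(ti, tj)
                    caps.append((host, m.atoms[bond.a].element, target))
                si, sj = i - sx, j - sy
                if not (0 <= si < nx and 0 <= sj < ny):
                    # incoming end: cap atom b towards the missing image of a
                    host = index[(i, j, bond.b)]
                    target = coords[bond.a] + cell_offset(si, sj)
                    caps.append((host, m.atoms[bond.b].element, target))

    for host, element, target in caps:
        pos = np.array(new_coords[host])
        direction = target - pos
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        cap_pos = pos + direction * (covalent_radius(element) + rH)
        cap_idx = len(atoms)
        atoms.append(core.Atom("H"))
        new_coords.append(cap_pos)
        bonds.append(core.Bond(host, cap_idx, 1))

    island = core.Molecule(atoms, bonds, [np.array(new_coords)])
    island.properties["island"] = {
        "net": a.topology.name,
        "nx": nx,
        "ny": ny,
        "atoms_per_cell": n_cell,
        "caps": len(caps),
    }
    return island
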