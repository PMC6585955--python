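"""Topology graphs and the generic four-step assembly driver.

A topology is a graph of vertices and edges with idealized unit
coordinates.  Assembly proceeds in the classic four steps: (i) place
and align every building block at its position, (ii) form bonds
between designated bonder atoms, (iii) remove the deleter atoms, and
(iv) optionally refine the geometry.  Step (iv) is delegated to a
plug-in; the one refiner shipped here, :func:`relax_assembly_bonds`,
shrinks only the bonds created during assembly while moving each
original building block as a rigid body, so every bond that existed
before assembly keeps its length exactly.

Three placement modes cover all supported materials:

* ``blocks_on_edges`` — multi-topic blocks on vertices, ditopic
  linkers on edges; every edge contributes two assembly bonds.
* ``direct_vertex_vertex`` — vertex blocks bond directly, one bond
  per edge (edge positions only steer the bonder pairing).
* ``alternating_vertices`` — as direct, for topologies whose two
  vertex sets alternate (e.g. tetratopic on an octahedron against
  tritopic on the surrounding cube corners).

Periodic topologies carry a unit cell; edges may close onto a
translated image of their second endpoint, recorded as an integer
lattice-shift vector that is propagated onto the bonds they create.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import building_blocks as bb
from . import core
from .building_blocks import BuildingBlock
from .errors import (
    ContractViolationError,
    DegenerateGeometryError,
    PlacementError,
)
from .functional_groups import (
    FRAGMENT_KEY,
    MATCH_KEY,
    attach_matches,
    delete_marked_atoms,
    get_attached_matches,
    react_pair,
)
from .periodic_data import covalent_radius

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Topology data model
# ---------------------------------------------------------------------------

@dataclass
class Vertex:
    id: int
    unit_position: np.ndarray
    edge_ids: list[int] = field(default_factory=list)
    alignment_choice: int = 0

    def __post_init__(self) -> None:
        self.unit_position = np.asarray(self.unit_position, dtype=float).reshape(3)


@dataclass
class Edge:
    id: int
    endpoints: tuple[int, int]
    unit_position: "np.ndarray | None" = None
    lattice_shift: tuple[int, int, int] = (0, 0, 0)
    parallel_flag: bool = True

    def __post_init__(self) -> None:
        if self.unit_position is not None:
            self.unit_position = np.asarray(self.unit_position, dtype=float).reshape(3)
        self.lattice_shift = tuple(int(x) for x in self.lattice_shift)


@dataclass
class TopologySpec:
    name: str
    vertices: list[Vertex]
    edges: list[Edge]
    family: str
    placement_mode: str = "blocks_on_edges"
    cell: "core.UnitCell | None" = None
    #: extra roll (degrees, about +z) of vertex blocks; 2D-net isomer control
    vertex_rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.placement_mode not in (
            "blocks_on_edges",
            "direct_vertex_vertex",
            "alternating_vertices",
        ):
            raise ValueError(f"unknown placement mode: {self.placement_mode!r}")
        known = {v.id for v in self.vertices}
        for e in self.edges:
            if not set(e.endpoints) <= known:
                raise ValueError(f"edge {e.id} references unknown vertex")
            if any(e.lattice_shift) and self.cell is None:
                raise ValueError(f"edge {e.id} has a lattice shift but no cell is set")
        # populate vertex edge lists when the definition left them empty
        if all(not v.edge_ids for v in self.vertices):
            by_id = {v.id: v for v in self.vertices}
            for e in self.edges:
                by_id[e.endpoints[0]].edge_ids.append(e.id)
                if e.endpoints[1] != e.endpoints[0] or any(e.lattice_shift):
                    by_id[e.endpoints[1]].edge_ids.append(e.id)

    @property
    def is_periodic(self) -> bool:
        return self.cell is not None

    def vertex(self, vid: int) -> Vertex:
        for v in self.vertices:
            if v.id == vid:
                return v
        raise KeyError(vid)

    def incident_ends(self, vid: int) -> "list[tuple[int, int]]":
        """Incident (edge id, end) pairs; a self-loop edge is incident twice."""
        pairs = []
        for e in self.edges:
            if e.endpoints[0] == vid:
                pairs.append((e.id, 0))
            if e.endpoints[1] == vid:
                pairs.append((e.id, 1))
        # order by appearance in the vertex's edge list, then by end
        order = {eid: k for k, eid in enumerate(self.vertex(vid).edge_ids)}
        pairs.sort(key=lambda p: (order.get(p[0], len(order)), p[0], p[1]))
        return pairs

    def degree(self, vid: int) -> int:
        return len(self.incident_ends(vid))

    def copy(self) -> "TopologySpec":
        return TopologySpec(
            self.name,
            [Vertex(v.id, v.unit_position.copy(), list(v.edge_ids), v.alignment_choice)
             for v in self.vertices],
            [Edge(e.id, e.endpoints, None if e.unit_position is None else e.unit_position.copy(),
                  e.lattice_shift, e.parallel_flag)
             for e in self.edges],
            self.family,
            self.placement_mode,
            core.UnitCell(self.cell.vectors.copy(), self.cell.periodic_dims)
            if self.cell else None,
            self.vertex_rotation,
        )


@dataclass
class AssembledMolecule:
    """An assembled supramolecule plus its construction provenance."""

    molecule: core.Molecule
    topology: TopologySpec
    placements: dict
    assembly_bonds: list[int]

    @property
    def is_periodic(self) -> bool:
        return self.molecule.is_periodic

    def fragment_ids(self) -> list[int]:
        return list(self.molecule.properties.get(FRAGMENT_KEY, []))


# ---------------------------------------------------------------------------
# Scaffold
# ---------------------------------------------------------------------------

def max_bonder_bonder_distance(block: BuildingBlock) -> float:
    """Largest distance between any two (per-group) bonder atoms."""
    pts = block.coords()[block.bonder_ids()]
    d = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = max(d, float(np.linalg.norm(pts[i] - pts[j])))
    return d


@dataclass
class Scaffold:
    scale: float
    vertex_pos: dict
    edge_pos: dict
    edge_dir: dict
    centroid: np.ndarray
    cell: "core.UnitCell | None"


def build_scaffold(t: TopologySpec, placements: dict) -> Scaffold:
    """Scale the unit topology so blocks cannot overlap their bond targets.

    The scale factor is the largest bonder-bonder distance over all
    placed blocks; unit coordinates (and the unit cell, if any) are
    multiplied by it, preserving the relative geometry exactly.
    """
    _check_placements(t, placements)
    s = max(max_bonder_bonder_distance(blk) for blk in placements.values())
    if s <= 0:
        raise PlacementError("all blocks have coincident bonder atoms; cannot scale")
    cell = None
    cell_vectors = None
    if t.cell is not None:
        cell_vectors = t.cell.vectors * s
        cell = core.UnitCell(cell_vectors, t.cell.periodic_dims)
    vertex_pos = {v.id: v.unit_position * s for v in t.vertices}
    edge_pos, edge_dir = {}, {}
    for e in t.edges:
        p_u = vertex_pos[e.endpoints[0]]
        p_v = vertex_pos[e.endpoints[1]].copy()
        if any(e.lattice_shift):
            p_v = p_v + np.asarray(e.lattice_shift, dtype=float) @ cell_vectors
        if e.unit_position is not None:
            edge_pos[e.id] = e.unit_position * s
        else:
            edge_pos[e.id] = 0.5 * (p_u + p_v)
        d = p_v - p_u
        n = np.linalg.norm(d)
        if n < 1e-9:
            raise PlacementError(f"edge {e.id} has coincident endpoints")
        edge_dir[e.id] = d / n
    centroid = np.mean([vertex_pos[v.id] for v in t.vertices], axis=0)
    return Scaffold(s, vertex_pos, edge_pos, edge_dir, centroid, cell)


def _check_placements(t: TopologySpec, placements: dict) -> None:
    for v in t.vertices:
        key = ("vertex", v.id)
        if key not in placements:
            raise PlacementError(f"no block placed on vertex {v.id}")
        got = placements[key].topicity
        need = t.degree(v.id)
        if got != need:
            raise PlacementError(
                f"vertex {v.id} needs topicity {need}, block has {got}"
            )
    if t.placement_mode == "blocks_on_edges":
        for e in t.edges:
            key = ("edge", e.id)
            if key not in placements:
                raise PlacementError(f"no block placed on edge {e.id}")
            if placements[key].topicity != 2:
                raise PlacementError(
                    f"edge {e.id} needs a ditopic block, got topicity "
                    f"{placements[key].topicity}"
                )


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _roll_angle(axis: np.ndarray, current: np.ndarray, target: np.ndarray) -> float:
    """Signed angle about *axis* taking the projection of *current* onto *target*'s."""
    c = current - np.dot(current, axis) * axis
    t = target - np.dot(target, axis) * axis
    nc, nt = np.linalg.norm(c), np.linalg.norm(t)
    if nc < 1e-9 or nt < 1e-9:
        raise DegenerateGeometryError("roll angle undefined (vector parallel to axis)")
    c, t = c / nc, t / nt
    cos = float(np.clip(np.dot(c, t), -1, 1))
    sin = float(np.dot(axis, np.cross(c, t)))
    return math.atan2(sin, cos)


def _transform_block(block: BuildingBlock, rot: np.ndarray, pivot: np.ndarray,
                     translation: np.ndarray) -> None:
    coords = block.coords()
    block.molecule.conformers[block.active_conformer] = (
        (coords - pivot) @ rot.T + pivot + translation
    )


def place_ditopic_on_edge(
    block: BuildingBlock,
    edge_position: np.ndarray,
    edge_direction: np.ndarray,
    scaffold_centroid: np.ndarray,
    parallel: bool = True,
) -> BuildingBlock:
    """Position a ditopic block on an edge.

    The bonder centroid lands on the edge position and the
    bonder-bonder axis is aligned parallel (or anti-parallel) with the
    edge.  A final roll about the edge axis points the block's bulk
    away from the scaffold centroid, keeping cage cavities open.
    """
    b = block.copy()
    target_axis = edge_direction if parallel else -edge_direction
    rot = core.rotation_between_vectors(bb.bonder_direction_vector(b), target_axis)
    _transform_block(b, rot, bb.bonder_centroid(b), np.zeros(3))
    # roll so the centroid-centroid vector points outward
    radial = edge_position - scaffold_centroid
    try:
        angle = _roll_angle(
            edge_direction / np.linalg.norm(edge_direction),
            bb.centroid_centroid_vector(b),
            radial,
        )
        roll = core.rotation_about_axis(edge_direction, angle)
        _transform_block(b, roll, bb.bonder_centroid(b), np.zeros(3))
    except DegenerateGeometryError:
        logger.warning(
            "edge block %r has no off-axis bulk; placed without roll", b.label
        )
    _transform_block(b, np.eye(3), np.zeros(3), edge_position - bb.bonder_centroid(b))
    return b


def place_multitopic_on_vertex(
    block: BuildingBlock,
    vertex_position: np.ndarray,
    outward_axis: np.ndarray,
    designated_target: np.ndarray,
    alignment_choice: int = 0,
) -> BuildingBlock:
    """Position a tri-/tetra-topic block on a vertex.

    The bonder plane normal is aligned with the outward vertex axis,
    then the block is rolled about that axis so the chosen bonder atom
    (``alignment_choice``) comes as close as possible to its
    designated edge target — each choice yields a distinct structural
    isomer for asymmetric blocks.
    """
    b = block.copy()
    axis = outward_axis / np.linalg.norm(outward_axis)
    rot = core.rotation_between_vectors(bb.bonder_plane_normal(b), axis)
    _transform_block(b, rot, bb.bonder_centroid(b), np.zeros(3))
    bonders = b.bonder_ids()
    choice = bonders[alignment_choice % len(bonders)]
    current = b.coords()[choice] - bb.bonder_centroid(b)
    try:
        angle = _roll_angle(axis, current, designated_target - vertex_position)
        roll = core.rotation_about_axis(axis, angle)
        _transform_block(b, roll, bb.bonder_centroid(b), np.zeros(3))
    except DegenerateGeometryError:
        logger.warning("vertex block %r roll is degenerate; skipped", b.label)
    _transform_block(b, np.eye(3), np.zeros(3), vertex_position - bb.bonder_centroid(b))
    return b


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _merge_blocks(placed: "list[tuple[tuple, BuildingBlock]]") -> tuple:
    """Concatenate positioned blocks into one molecule with global numbering."""
    atoms, bonds, coords = [], [], []
    fragments: list[int] = []
    block_matches: dict = {}
    offset = 0
    for frag_id, (key, blk) in enumerate(placed):
        mol = blk.molecule
        for a in mol.atoms:
            atoms.append(core.Atom(a.element, a.formal_charge))
        for bd in mol.bonds:
            bonds.append(
                core.Bond(bd.a + offset, bd.b + offset, bd.order,
                          bd.lattice_shift, bd.is_assembly_bond)
            )
        coords.append(blk.coords())
        fragments.extend([frag_id] * mol.n_atoms)
        shifted = []
        for match in blk.fg_matches:
            shifted.append(
                type(match)(
                    match.fg_name,
                    tuple(i + offset for i in match.atom_ids),
                    tuple(i + offset for i in match.bonder_ids),
                    tuple(i + offset for i in match.deleter_ids),
                )
            )
        block_matches[key] = shifted
        offset += mol.n_atoms
    merged = core.Molecule(atoms, bonds, [np.vstack(coords)])
    merged.properties[FRAGMENT_KEY] = fragments
    attach_matches(merged, [m for ms in block_matches.values() for m in ms])
    return merged, block_matches


def assemble(
    t: TopologySpec,
    placements: dict,
    vertex_alignments: "dict[int, int] | None" = None,
    edge_parallel: "dict[int, bool] | None" = None,
) -> AssembledMolecule:
    """Run the place/bond/delete pipeline for any topology.

    ``placements`` maps ``("vertex", id)`` / ``("edge", id)`` to
    building blocks.  ``vertex_alignments`` picks, per vertex, which
    bonder atom targets the vertex's first edge; ``edge_parallel``
    flips ditopic linkers relative to their edge direction.
    """
    t = t.copy()
    if vertex_alignments:
        for vid, choice in vertex_alignments.items():
            t.vertex(vid).alignment_choice = int(choice)
    if edge_parallel:
        by_id = {e.id: e for e in t.edges}
        for eid, flag in edge_parallel.items():
            by_id[eid].parallel_flag = bool(flag)

    scaffold = build_scaffold(t, placements)
    cellv = scaffold.cell.vectors if scaffold.cell is not None else None

    def end_offset(e: Edge, end: int) -> np.ndarray:
        if end == 1 and any(e.lattice_shift):
            return np.asarray(e.lattice_shift, dtype=float) @ cellv
        return np.zeros(3)

    # --- step (i): placement ---------------------------------------------
    placed: "list[tuple[tuple, BuildingBlock]]" = []
    for v in t.vertices:
        key = ("vertex", v.id)
        block = placements[key]
        pos = scaffold.vertex_pos[v.id]
        if t.family == "cof_2d":
            # 2D nets: bonder plane lies flat on xy, normal along +z
            outward = np.array([0.0, 0.0, 1.0])
        else:
            outward = pos - scaffold.centroid
            if np.linalg.norm(outward) < 1e-9:
                outward = np.array([0.0, 0.0, 1.0])
        first_edge, first_end = t.incident_ends(v.id)[0]
        e = next(e for e in t.edges if e.id == first_edge)
        target = scaffold.edge_pos[first_edge] - end_offset(e, first_end)
        if block.topicity == 2:
            # a ditopic block on a 2-degree vertex is aligned like an edge block
            positioned = place_ditopic_on_edge(
                block, pos, scaffold.edge_dir[first_edge], scaffold.centroid
            )
        else:
            positioned = place_multitopic_on_vertex(
                block, pos, outward, target, v.alignment_choice
            )
        if t.family == "cof_2d" and t.vertex_rotation:
            roll = core.rotation_about_axis(
                np.array([0.0, 0.0, 1.0]), math.radians(t.vertex_rotation)
            )
            _transform_block(positioned, roll, bb.bonder_centroid(positioned), np.zeros(3))
        placed.append((key, positioned))
    if t.placement_mode == "blocks_on_edges":
        for e in t.edges:
            key = ("edge", e.id)
            positioned = place_ditopic_on_edge(
                placements[key],
                scaffold.edge_pos[e.id],
                scaffold.edge_dir[e.id],
                scaffold.centroid,
                e.parallel_flag,
            )
            placed.append((key, positioned))

    merged, block_matches = _merge_blocks(placed)
    coords = merged.coords(0)

    free: dict = {
        key: [m.bonder_ids[0] for m in ms] for key, ms in block_matches.items()
    }

    # --- step (ii): bond formation ---------------------------------------
    new_bonds: "list[tuple[int, int, tuple[int, int, int]]]" = []
    if t.placement_mode == "blocks_on_edges":
        # assign each edge block's two bonders to the edge's two ends
        edge_end_bonder: dict = {}
        for e in t.edges:
            b0, b1 = free[("edge", e.id)]
            p_u = scaffold.vertex_pos[e.endpoints[0]]
            if np.linalg.norm(coords[b0] - p_u) <= np.linalg.norm(coords[b1] - p_u):
                edge_end_bonder[e.id] = {0: b0, 1: b1}
            else:
                edge_end_bonder[e.id] = {0: b1, 1: b0}
        edges_by_id = {e.id: e for e in t.edges}
        for v in t.vertices:
            ends = t.incident_ends(v.id)
            bonders = list(free[("vertex", v.id)])
            choice = v.alignment_choice % len(bonders)
            # designated pairing first, then greedy nearest
            pairs = [(bonders.pop(choice), ends[0])]
            remaining_ends = list(ends[1:])
            while bonders:
                best = None
                for gb in bonders:
                    for ee in remaining_ends:
                        e = edges_by_id[ee[0]]
                        partner = edge_end_bonder[ee[0]][ee[1]]
                        ppos = coords[partner] - end_offset(e, ee[1])
                        dist = float(np.linalg.norm(coords[gb] - ppos))
                        cand = (dist, ee[0], ee[1], gb)
                        if best is None or cand < best:
                            best = cand
                _, eid, end, gb = best
                bonders.remove(gb)
                remaining_ends.remove((eid, end))
                pairs.append((gb, (eid, end)))
            for gb, (eid, end) in pairs:
                e = edges_by_id[eid]
                partner = edge_end_bonder[eid][end]
                shift = e.lattice_shift if (end == 1 and any(e.lattice_shift)) else (0, 0, 0)
                new_bonds.append((partner, gb, shift))
    else:  # direct vertex-vertex bonding (edge positions steer the pairing)
        for e in sorted(t.edges, key=lambda e: e.id):
            u, v = e.endpoints
            off = end_offset(e, 1)
            target = scaffold.edge_pos[e.id]
            best = None
            for gu in free[("vertex", u)]:
                for gv in free[("vertex", v)]:
                    if gu == gv:
                        continue
                    mid = 0.5 * (coords[gu] + coords[gv] + off)
                    dist = float(np.linalg.norm(coords[gu] - coords[gv] - off))
                    steer = float(np.linalg.norm(mid - target))
                    cand = (dist + steer, gu, gv)
                    if best is None or cand < best:
                        best = cand
            if best is None:
                raise PlacementError(f"no free bonder pair left for edge {e.id}")
            _, gu, gv = best
            free[("vertex", u)].remove(gu)
            free[("vertex", v)].remove(gv)
            new_bonds.append((gu, gv, e.lattice_shift))

    for a_idx, b_idx, shift in new_bonds:
        react_pair(merged, a_idx, b_idx, order=1)
        merged.bonds[-1].lattice_shift = tuple(shift)

    # --- step (iii): deleter removal --------------------------------------
    merged = delete_marked_atoms(merged)
    if scaffold.cell is not None:
        merged.cell = scaffold.cell

    assembly_bond_ids = [
        i for i, bd in enumerate(merged.bonds) if bd.is_assembly_bond
    ]
    placement_labels = {
        f"{kind}:{pid}": (blk.label or f"block{n}")
        for n, ((kind, pid), blk) in enumerate(placements.items())
    }
    return AssembledMolecule(merged, t, placement_labels, assembly_bond_ids)


# ---------------------------------------------------------------------------
# Constrained relaxation (step iv, built-in refiner)
# ---------------------------------------------------------------------------

def default_target_length(m: core.Molecule, bond: core.Bond) -> float:
    """Chemistry-neutral target: sum of the covalent radii of the pair."""
    return covalent_radius(m.atoms[bond.a].element) + covalent_radius(
        m.atoms[bond.b].element
    )


def assembly_bond_objective(a: AssembledMolecule, target_length_fn=None) -> float:
    """Sum of squared deviations of assembly-bond lengths from their targets."""
    fn = target_length_fn or default_target_length
    m = a.molecule
    coords = m.coords(0)
    cellv = m.cell.vectors if m.cell is not None else None
    total = 0.0
    for i in a.assembly_bonds:
        bond = m.bonds[i]
        pb = coords[bond.b]
        if any(bond.lattice_shift):
            pb = pb + np.asarray(bond.lattice_shift, dtype=float) @ cellv
        d = float(np.linalg.norm(coords[bond.a] - pb))
        total += (d - fn(m, bond)) ** 2
    return total


def relax_assembly_bonds(
    a: AssembledMolecule,
    target_length_fn=None,
    max_iter: int = 500,
    tol: float = 1e-3,
) -> AssembledMolecule:
    """Shrink assembly bonds to target length by rigid-fragment descent.

    Cyclic coordinate descent over the original building-block
    fragments: each fragment in turn takes a closed-form translation
    step (exact for a single bond) and a small-angle rotation line
    search about its centroid, each accepted only if the objective
    does not increase.  Intra-fragment geometry is therefore exactly
    preserved.  Runs until every assembly bond is within ``tol`` of
    its target or ``max_iter`` sweeps have been done.
    """
    fn = target_length_fn or default_target_length
    m = a.molecule
    if not a.assembly_bonds:
        raise ValueError("molecule has no assembly bonds to relax")
    coords = m.coords(0).copy()
    cellv = m.cell.vectors if m.cell is not None else None
    fragments = np.asarray(m.properties.get(FRAGMENT_KEY, [0] * m.n_atoms))
    frag_ids = sorted(set(fragments.tolist()))
    frag_atoms = {f: np.where(fragments == f)[0] for f in frag_ids}

    bonds = []
    for i in a.assembly_bonds:
        bond = m.bonds[i]
        off = (
            np.asarray(bond.lattice_shift, dtype=float) @ cellv
            if any(bond.lattice_shift)
            else np.zeros(3)
        )
        bonds.append((bond.a, bond.b, off, fn(m, bond)))

    def objective(xyz: np.ndarray) -> float:
        total = 0.0
        for ia, ib, off, d_star in bonds:
            d = float(np.linalg.norm(xyz[ia] - (xyz[ib] + off)))
            total += (d - d_star) ** 2
        return total

    def residuals(xyz: np.ndarray) -> float:
        return max(
            abs(float(np.linalg.norm(xyz[ia] - (xyz[ib] + off))) - d_star)
            for ia, ib, off, d_star in bonds
        )

    current = objective(coords)
    for _ in range(max_iter):
        if residuals(coords) <= tol:
            break
        for f in frag_ids:
            idx = frag_atoms[f]
            touching = [
                (ia, ib, off, d_star, ia in set(idx.tolist()))
                for ia, ib, off, d_star in bonds
                if fragments[ia] == f or fragments[ib] == f
            ]
            touching = [
                trow for trow in touching
                if fragments[trow[0]] != fragments[trow[1]]
            ]
            if not touching:
                continue
            # closed-form translation step (exact for a single bond)
            step = np.zeros(3)
            torque = np.zeros(3)
            pivot = coords[idx].mean(axis=0)
            for ia, ib, off, d_star, a_in_f in touching:
                if a_in_f:
                    own, other = coords[ia], coords[ib] + off
                else:
                    own, other = coords[ib] + off, coords[ia]
                delta = other - own
                d = float(np.linalg.norm(delta))
                if d < 1e-12:
                    continue
                force = delta * (1.0 - d_star / d)
                step += force
                torque += np.cross(own - pivot, force)
            step /= len(touching)
            scale = 1.0
            for _try in range(25):
                trial = coords.copy()
                trial[idx] = coords[idx] + scale * step
                if objective(trial) <= current + 1e-15:
                    coords, current = trial, objective(trial)
                    break
                scale *= 0.5
            # small-angle rotation line search about the torque axis
            tn = np.linalg.norm(torque)
            if tn > 1e-12:
                axis = torque / tn
                pivot = coords[idx].mean(axis=0)
                best, best_obj = None, current
                for angle in (0.2, 0.1, 0.05, 0.02, 0.01, 0.005):
                    rot = core.rotation_about_axis(axis, angle)
                    trial = coords.copy()
                    trial[idx] = (coords[idx] - pivot) @ rot.T + pivot
                    val = objective(trial)
                    if val < best_obj - 1e-15:
                        best, best_obj = trial, val
                if best is not None:
                    coords, current = best, best_obj

    m.conformers[0] = coords
    history = m.properties.setdefault("refinement_history", [])
    history.append({"refiner": "relax_assembly_bonds", "objective": current})
    return a


def refine(a: AssembledMolecule, plugin) -> AssembledMolecule:
    """Apply a third-party refinement plug-in to the assembled molecule.

    The contract: the plug-in receives the molecule, returns a
    molecule with identical atom count, element sequence and bond
    list, and may only change coordinates.  Anything else raises
    :class:`ContractViolationError`.
    """
    before = a.molecule
    elements = [atom.element for atom in before.atoms]
    n_bonds = before.n_bonds
    result = plugin(before)
    if result is None:
        result = before
    if (
        result.n_atoms != len(elements)
        or [atom.element for atom in result.atoms] != elements
        or result.n_bonds != n_bonds
    ):
        raise ContractViolationError(
            "refinement plug-in changed atom/bond identity"
        )
    before.conformers[0] = result.coords(0).copy()
    history = before.properties.setdefault("refinement_history", [])
    history.append({"refiner": getattr(plugin, "__name__", repr(plugin))})
    return a
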