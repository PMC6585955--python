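"""Porous organic cage topologies, nomenclature, assembly and cavity size.

Cage topologies are named ``XpmYn``: X and Y are the two building
block types (``Di``, ``Tri`` or ``Tet`` for di-, tri- and tetratopic),
m and n count how many of each the cage contains, and p — omitted
when 1 — counts how many Y blocks sit on each X-X connection.  X is
always the block with at least as many reactive groups as Y.

The registry holds 14 topologies in four families:

* **Tri+Di** (6): ``Tri2Di3``, ``Tri4Di6`` (tetrahedron), ``Tri4Di6b``
  (an alternative embedding of the same graph), ``Tri6Di9`` (trigonal
  prism), ``Tri8Di12`` (cube), ``Tri20Di30`` (dodecahedron);
* **Tet+Di** (4): ``Tet2Di4``, ``Tet3Di6``, ``Tet4Di8``, ``Tet6Di12``
  (octahedron);
* **Tri+Tri** (3): ``Tri1Tri1``, ``Tri2Tri2``, ``Tri4Tri4`` — vertex
  blocks bond directly, nothing sits on the edges;
* **Tet+Tri** (1): ``Tet6Tri8`` — tetratopic and tritopic blocks on
  alternating vertex shells (octahedron inside a cube).

Vertex coordinates are the standard polyhedra; multigraph topologies
(two vertices joined by several linkers) carry explicit edge
positions spread around the connecting axis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import core
from .building_blocks import BuildingBlock
from .errors import PlacementError
from .periodic_data import vdw_radius
from .topology import AssembledMolecule, Edge, TopologySpec, Vertex, assemble

_TOPICITY = {"Di": 2, "Tri": 3, "Tet": 4}


@dataclass(frozen=True)
class CageTopologyName:
    """Structured form of the XpmYn cage nomenclature."""

    X: str
    m: int
    Y: str
    n: int
    p: int = 1


def topology_name(spec: CageTopologyName) -> str:
    """Render the canonical ``XpmYn`` string (p omitted when 1)."""
    for t in (spec.X, spec.Y):
        if t not in _TOPICITY:
            raise ValueError(f"unknown building-block type {t!r}")
    if _TOPICITY[spec.X] < _TOPICITY[spec.Y]:
        raise ValueError(
            "X must have at least as many reactive end groups as Y "
            f"({spec.X} < {spec.Y})"
        )
    if spec.m < 1 or spec.n < 1 or spec.p < 1:
        raise ValueError("m, n and p must be positive")
    p = str(spec.p) if spec.p > 1 else ""
    return f"{spec.X}{p}{spec.m}{spec.Y}{spec.n}"


# ---------------------------------------------------------------------------
# Geometry builders
# ---------------------------------------------------------------------------

def _ring(k: int, radius: float = 1.0, z: float = 0.0, phase: float = 0.0):
    return [
        np.array(
            [
                radius * math.cos(phase + 2 * math.pi * i / k),
                radius * math.sin(phase + 2 * math.pi * i / k),
                z,
            ]
        )
        for i in range(k)
    ]


def _tetrahedron():
    return [np.array(p, dtype=float) for p in
            [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]]


def _cube():
    return [np.array(p, dtype=float)
            for p in itertools.product((-1.0, 1.0), repeat=3)]


def _octahedron():
    pts = []
    for axis in range(3):
        for sign in (1.0, -1.0):
            p = np.zeros(3)
            p[axis] = sign
            pts.append(p)
    return pts


def _dodecahedron():
    phi = (1 + math.sqrt(5)) / 2
    raw = [np.array(p, dtype=float) for p in itertools.product((-1, 1), repeat=3)]
    for sb in (-1, 1):
        for sc in (-1, 1):
            raw.append(np.array([0.0, sb / phi, sc * phi]))
            raw.append(np.array([sb / phi, sc * phi, 0.0]))
            raw.append(np.array([sb * phi, 0.0, sc / phi]))
    return raw


def _edges_by_distance(points, cutoff_factor: float = 1.05):
    """All pairs at (approximately) the minimal pairwise distance."""
    dmin = min(
        np.linalg.norm(p - q)
        for p, q in itertools.combinations(points, 2)
    )
    return [
        (i, j)
        for (i, p), (j, q) in itertools.combinations(enumerate(points), 2)
        if np.linalg.norm(p - q) <= dmin * cutoff_factor
    ]


def _spec(name, family, verts, edge_defs, mode="blocks_on_edges"):
    vertices = [Vertex(i, p) for i, p in enumerate(verts)]
    edges = []
    for eid, (u, v, pos) in enumerate(edge_defs):
        edges.append(Edge(eid, (u, v), pos))
    return TopologySpec(name, vertices, edges, family, mode)


def _build_tri2di3():
    verts = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    edge_defs = [(0, 1, p) for p in _ring(3, radius=1.0)]
    return _spec("Tri2Di3", "tri_di", verts, edge_defs)


def _build_tri4di6():
    verts = _tetrahedron()
    edge_defs = [(i, j, None) for i, j in itertools.combinations(range(4), 2)]
    return _spec("Tri4Di6", "tri_di", verts, edge_defs)


def _build_tri4di6b():
    # same K4 graph as Tri4Di6 on a squashed tetrahedron; a distinct
    # idealized shape gives access to a different structural isomer
    verts = [
        np.array([1.4, 0.0, 0.6]),
        np.array([-1.4, 0.0, 0.6]),
        np.array([0.0, 1.4, -0.6]),
        np.array([0.0, -1.4, -0.6]),
    ]
    edge_defs = [(i, j, None) for i, j in itertools.combinations(range(4), 2)]
    return _spec("Tri4Di6b", "tri_di", verts, edge_defs)


def _build_tri6di9():
    top = _ring(3, radius=1.0, z=0.9, phase=math.pi / 2)
    bottom = _ring(3, radius=1.0, z=-0.9, phase=math.pi / 2)
    verts = top + bottom
    edge_defs = [(0, 1, None), (1, 2, None), (2, 0, None),
                 (3, 4, None), (4, 5, None), (5, 3, None),
                 (0, 3, None), (1, 4, None), (2, 5, None)]
    return _spec("Tri6Di9", "tri_di", verts, edge_defs)


def _build_tri8di12():
    verts = _cube()
    edge_defs = [(i, j, None) for i, j in _edges_by_distance(verts)]
    return _spec("Tri8Di12", "tri_di", verts, edge_defs)


def _build_tri20di30():
    verts = _dodecahedron()
    edge_defs = [(i, j, None) for i, j in _edges_by_distance(verts)]
    return _spec("Tri20Di30", "tri_di", verts, edge_defs)


def _build_tet2di4():
    verts = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    edge_defs = [(0, 1, p) for p in _ring(4, radius=1.0)]
    return _spec("Tet2Di4", "tet_di", verts, edge_defs)


def _build_tet3di6():
    verts = _ring(3, radius=1.0, phase=math.pi / 2)
    edge_defs = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        mid = 0.5 * (verts[i] + verts[j])
        edge_defs.append((i, j, mid + np.array([0.0, 0.0, 0.55])))
        edge_defs.append((i, j, mid + np.array([0.0, 0.0, -0.55])))
    return _spec("Tet3Di6", "tet_di", verts, edge_defs)


def _build_tet4di8():
    verts = _ring(4, radius=1.0)
    edge_defs = []
    for i, j in ((0, 1), (1, 2), (2, 3), (3, 0)):
        mid = 0.5 * (verts[i] + verts[j])
        edge_defs.append((i, j, mid + np.array([0.0, 0.0, 0.55])))
        edge_defs.append((i, j, mid + np.array([0.0, 0.0, -0.55])))
    return _spec("Tet4Di8", "tet_di", verts, edge_defs)


def _build_tet6di12():
    verts = _octahedron()
    edge_defs = [(i, j, None) for i, j in _edges_by_distance(verts)]
    return _spec("Tet6Di12", "tet_di", verts, edge_defs)


def _build_tri1tri1():
    verts = [np.array([0.0, 0.0, 0.5]), np.array([0.0, 0.0, -0.5])]
    edge_defs = [(0, 1, p) for p in _ring(3, radius=0.7)]
    return _spec("Tri1Tri1", "tri_tri", verts, edge_defs, mode="direct_vertex_vertex")


def _build_tri2tri2():
    verts = _tetrahedron()
    edge_defs = [(i, j, None) for i, j in itertools.combinations(range(4), 2)]
    return _spec("Tri2Tri2", "tri_tri", verts, edge_defs, mode="direct_vertex_vertex")


def _build_tri4tri4():
    verts = _cube()
    edge_defs = [(i, j, None) for i, j in _edges_by_distance(verts)]
    return _spec("Tri4Tri4", "tri_tri", verts, edge_defs, mode="direct_vertex_vertex")


def _build_tet6tri8():
    tet_verts = [p * 1.1 for p in _octahedron()]        # ids 0-5, degree 4
    tri_verts = [p * 0.85 for p in _cube()]             # ids 6-13, degree 3
    verts = tet_verts + tri_verts
    edge_defs = []
    for ci, corner in enumerate(tri_verts):
        for oi, face in enumerate(tet_verts):
            axis = int(np.argmax(np.abs(face)))
            if np.sign(face[axis]) == np.sign(corner[axis]):
                edge_defs.append((oi, 6 + ci, None))
    return _spec("Tet6Tri8", "tet_tri", verts, edge_defs, mode="alternating_vertices")


_REGISTRY = {
    "Tri2Di3": _build_tri2di3,
    "Tri4Di6": _build_tri4di6,
    "Tri4Di6b": _build_tri4di6b,
    "Tri6Di9": _build_tri6di9,
    "Tri8Di12": _build_tri8di12,
    "Tri20Di30": _build_tri20di30,
    "Tet2Di4": _build_tet2di4,
    "Tet3Di6": _build_tet3di6,
    "Tet4Di8": _build_tet4di8,
    "Tet6Di12": _build_tet6di12,
    "Tri1Tri1": _build_tri1tri1,
    "Tri2Tri2": _build_tri2tri2,
    "Tri4Tri4": _build_tri4tri4,
    "Tet6Tri8": _build_tet6tri8,
}


def cage_topology_names() -> list[str]:
    return list(_REGISTRY)


def cage_families() -> dict:
    """Registry names grouped by family."""
    out: dict[str, list[str]] = {}
    for name in _REGISTRY:
        out.setdefault(get_cage_topology(name).family, []).append(name)
    return out


def get_cage_topology(name: str) -> TopologySpec:
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown cage topology {name!r}; known: {', '.join(_REGISTRY)}"
        )
    return _REGISTRY[name]()


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_cage(
    topology_name: str,
    blocks: "list[BuildingBlock]",
    vertex_alignments: "dict[int, int] | None" = None,
    edge_flags: "dict[int, bool] | None" = None,
    placement_map: "dict | None" = None,
    seed: "int | None" = None,
) -> AssembledMolecule:
    """Assemble a cage from a pool of building blocks.

    Without an explicit ``placement_map`` (position key -> block), a
    block of the correct topicity is chosen for every vertex and edge
    at random using ``seed`` — this is how multi-component cages with
    more than two distinct blocks are produced.
    """
    t = get_cage_topology(topology_name)
    placements: dict = {}
    rng = np.random.default_rng(seed)
    positions = [("vertex", v.id) for v in t.vertices]
    if t.placement_mode == "blocks_on_edges":
        positions += [("edge", e.id) for e in t.edges]
    for key in positions:
        if placement_map and key in placement_map:
            placements[key] = placement_map[key]
            continue
        need = t.degree(key[1]) if key[0] == "vertex" else 2
        pool = [blk for blk in blocks if blk.topicity == need]
        if not pool:
            raise PlacementError(
                f"no building block with topicity {need} available for {key}"
            )
        placements[key] = pool[int(rng.integers(len(pool)))]
    return assemble(t, placements, vertex_alignments, edge_flags)


def cavity_diameter(a: AssembledMolecule, conformer: int = 0) -> float:
    """Twice the centroid-to-nearest-atom-surface distance (vdW corrected).

    Negative values indicate a collapsed cavity (an atom overlaps the
    cage centroid).
    """
    m = a.molecule
    coords = m.coords(conformer)
    if coords.shape[0] == 0:
        raise ValueError("empty molecule has no cavity")
    center = coords.mean(axis=0)
    gaps = [
        float(np.linalg.norm(xyz - center)) - vdw_radius(atom.element)
        for atom, xyz in zip(m.atoms, coords)
    ]
    return 2.0 * min(gaps)
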