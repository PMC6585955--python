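"""Linear polymers, oligomers and dimers.

A chain is specified by a repeat-unit string (``"AB"``), a monomer
spec per letter, and a number of repeats.  Every monomer is a ditopic
building block placed along +x with its bonder-bonder axis on the
chain axis; each placement is flipped (anti-parallel) with the
monomer's ``flip_probability``, so head-to-tail (p=0), head-to-head
(p=1) and arbitrarily biased sequences are all reachable, and the
sequence is reproducible from the seed.

Adjacent blocks are joined bonder-to-bonder through the usual
react/delete machinery; the two chain-terminal bonder atoms never
react, so their functional groups (deleter atoms included) survive
intact as unreacted chain ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import building_blocks as bb
from . import core
from .building_blocks import BuildingBlock
from .errors import DegenerateGeometryError, TopicityError
from .functional_groups import (
    FRAGMENT_KEY,
    delete_marked_atoms,
    react_pair,
)
from .topology import (
    AssembledMolecule,
    Edge,
    TopologySpec,
    Vertex,
    _merge_blocks,
    _roll_angle,
    _transform_block,
    max_bonder_bonder_distance,
)

#: spacing multiplier between consecutive bonder centroids (clash guard)
SPACING_FACTOR = 1.1


@dataclass
class MonomerSpec:
    label: str
    block: BuildingBlock
    flip_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.block.topicity != 2:
            raise TopicityError(
                f"monomer {self.label!r}: polymers need ditopic blocks, "
                f"got topicity {self.block.topicity}"
            )
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")


def orientation_sequence(
    repeat: str,
    monomers: "dict[str, MonomerSpec]",
    n_repeats: int,
    seed: "int | None" = None,
) -> list[bool]:
    """Per-position flip decisions (True = anti-parallel) for the whole chain."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    for letter in repeat:
        if letter not in monomers:
            raise KeyError(f"repeat letter {letter!r} has no monomer spec")
    rng = np.random.default_rng(seed)
    flips = []
    for letter in repeat * n_repeats:
        u = float(rng.random())
        flips.append(u < monomers[letter].flip_probability)
    return flips


def assemble_linear(
    repeat: str,
    monomers: "dict[str, MonomerSpec]",
    n_repeats: int,
    seed: "int | None" = None,
) -> AssembledMolecule:
    """Assemble a linear chain of ``len(repeat) * n_repeats`` blocks.

    ``n_repeats=1`` with a two-letter repeat yields a dimer; a chain of
    k blocks always contains k-1 assembly bonds.
    """
    flips = orientation_sequence(repeat, monomers, n_repeats, seed)
    letters = list(repeat * n_repeats)

    placed = []
    x = 0.0
    axis = np.array([1.0, 0.0, 0.0])
    up = np.array([0.0, 0.0, 1.0])
    for i, (letter, flipped) in enumerate(zip(letters, flips)):
        block = monomers[letter].block.copy()
        direction = -axis if flipped else axis
        rot = core.rotation_between_vectors(bb.bonder_direction_vector(block), direction)
        _transform_block(block, rot, bb.bonder_centroid(block), np.zeros(3))
        try:  # deterministic roll: bulk towards +z
            angle = _roll_angle(axis, bb.centroid_centroid_vector(block), up)
            _transform_block(
                block, core.rotation_about_axis(axis, angle),
                bb.bonder_centroid(block), np.zeros(3),
            )
        except DegenerateGeometryError:
            pass
        _transform_block(
            block, np.eye(3), np.zeros(3),
            np.array([x, 0.0, 0.0]) - bb.bonder_centroid(block),
        )
        placed.append((("vertex", i), block))
        x += SPACING_FACTOR * max_bonder_bonder_distance(block)

    merged, block_matches = _merge_blocks(placed)
    coords = merged.coords(0)

    # each block's two bonders, sorted along the chain axis
    sorted_bonders = []
    for i in range(len(letters)):
        ids = [m.bonder_ids[0] for m in block_matches[("vertex", i)]]
        ids.sort(key=lambda g: float(coords[g][0]))
        sorted_bonders.append(ids)

    for i in range(len(letters) - 1):
        react_pair(merged, sorted_bonders[i][1], sorted_bonders[i + 1][0])
    merged = delete_marked_atoms(merged)

    k = len(letters)
    chain = TopologySpec(
        f"Linear[{repeat}x{n_repeats}]",
        [Vertex(i, np.array([float(i), 0.0, 0.0])) for i in range(k)],
        [Edge(i, (i, i + 1)) for i in range(k - 1)],
        "linear",
        "direct_vertex_vertex",
    )
    bonds = [i for i, b in enumerate(merged.bonds) if b.is_assembly_bond]
    labels = {
        f"vertex:{i}": (monomers[letter].block.label or letter)
        for i, letter in enumerate(letters)
    }
    out = AssembledMolecule(merged, chain, labels, bonds)
    out.molecule.properties["orientation_sequence"] = [bool(f) for f in flips]
    return out


def max_atom_separation(a: AssembledMolecule) -> float:
    """Distance between the two furthest atoms of the assembled chain."""
    return core.max_diameter(a.molecule)
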