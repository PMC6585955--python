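"""Building blocks: molecules plus tagged functional groups.

A :class:`BuildingBlock` wraps a molecule together with its matched
functional groups and exposes the geometric descriptors used to place
it on a topology:

* the **bonder centroid** — centroid of every atom that will form a
  new bond;
* the **bonder-bonder direction vector** (ditopic blocks) — the axis
  along which the two new bonds form;
* the **centroid-centroid direction vector** — from the bonder
  centroid towards the molecular centroid, i.e. towards the bulk of
  the block, used to point backbones away from a cage cavity;
* the **bonder plane normal** (tri-topic and higher) — normal of the
  plane through the first three bonder atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .errors import ConfigurationError, DegenerateGeometryError, TopicityError
from .functional_groups import (
    FunctionalGroupMatch,
    deduce_fg_from_filename,
    match_functional_groups,
)

_DEGENERATE_TOL = 1e-8


@dataclass
class BuildingBlock:
    molecule: core.Molecule
    fg_matches: list[FunctionalGroupMatch]
    active_conformer: int = 0
    label: "str | None" = None

    @property
    def topicity(self) -> int:
        return len(self.fg_matches)

    @property
    def fg_name(self) -> str:
        return self.fg_matches[0].fg_name

    def coords(self) -> np.ndarray:
        return self.molecule.coords(self.active_conformer)

    def bonder_ids(self) -> list[int]:
        """One bonder atom per functional group, in match order.

        Groups whose definition tags several bonder atoms contribute
        their first; topology placement operates on one bond per group.
        """
        return [match.bonder_ids[0] for match in self.fg_matches]

    def all_bonder_ids(self) -> list[int]:
        return [i for match in self.fg_matches for i in match.bonder_ids]

    def copy(self) -> "BuildingBlock":
        return BuildingBlock(
            self.molecule.copy(), list(self.fg_matches), self.active_conformer, self.label
        )


def make_building_block(
    m: core.Molecule,
    fg_name: "str | None" = None,
    source_name: "str | None" = None,
    label: "str | None" = None,
) -> BuildingBlock:
    """Tag a molecule's functional groups and wrap it as a building block.

    When ``fg_name`` is not given it is deduced from ``source_name``
    (typically the input filename).  At least two matches are required
    for assembly use.
    """
    if fg_name is None:
        if source_name is not None:
            fg_name = deduce_fg_from_filename(source_name)
        if fg_name is None:
            raise ConfigurationError(
                "no functional group specified and none deducible from the source name"
            )
    matches = match_functional_groups(m, fg_name)
    if len(matches) < 2:
        raise TopicityError(
            f"building blocks need >=2 functional groups; {fg_name!r} matched {len(matches)}"
        )
    return BuildingBlock(m, matches, label=label or source_name)


def block_from_smiles(smiles: str, fg_name: str, label: "str | None" = None) -> BuildingBlock:
    """Convenience: embed a SMILES string and tag its functional groups."""
    return make_building_block(
        core.load_molecule(smiles, "smiles"), fg_name, label=label or smiles
    )


# ---------------------------------------------------------------------------
# Alignment descriptors
# ---------------------------------------------------------------------------

def bonder_centroid(b: BuildingBlock) -> np.ndarray:
    """Unweighted centroid of all bonder atoms across all matches."""
    ids = b.all_bonder_ids()
    return b.coords()[ids].mean(axis=0)


def bonder_direction_vector(b: BuildingBlock) -> np.ndarray:
    """Unit vector from the bonder of match 0 to the bonder of match 1 (ditopic only)."""
    if b.topicity != 2:
        raise TopicityError(
            f"bonder_direction_vector applies to ditopic blocks, not topicity {b.topicity}"
        )
    p0, p1 = b.coords()[b.bonder_ids()]
    v = p1 - p0
    n = np.linalg.norm(v)
    if n < _DEGENERATE_TOL:
        raise DegenerateGeometryError("the two bonder atoms coincide")
    return v / n


def centroid_centroid_vector(b: BuildingBlock) -> np.ndarray:
    """Unit vector from the bonder centroid towards the molecular centroid."""
    v = core.centroid(b.molecule, b.active_conformer) - bonder_centroid(b)
    n = np.linalg.norm(v)
    if n < _DEGENERATE_TOL:
        raise DegenerateGeometryError(
            "molecular centroid coincides with the bonder centroid"
        )
    return v / n


def bonder_plane_normal(b: BuildingBlock) -> np.ndarray:
    """Unit normal of the plane through the first three bonder atoms.

    The sign is chosen to point *away* from the molecular bulk: the
    normal has non-negative dot product with the reversed
    centroid-centroid vector.  For blocks whose bulk lies in the
    bonder plane (the vector is degenerate) the sign falls back to
    making the normal's largest-magnitude component positive.
    """
    if b.topicity < 3:
        raise TopicityError(
            f"bonder_plane_normal needs topicity >= 3, got {b.topicity}"
        )
    p0, p1, p2 = b.coords()[b.bonder_ids()[:3]]
    normal = np.cross(p1 - p0, p2 - p0)
    n = np.linalg.norm(normal)
    if n < _DEGENERATE_TOL * max(1.0, np.linalg.norm(p1 - p0)):
        raise DegenerateGeometryError("first three bonder atoms are collinear")
    normal /= n
    try:
        ccv = centroid_centroid_vector(b)
        side = float(np.dot(normal, -ccv))
    except DegenerateGeometryError:
        side = 0.0
    if abs(side) < 1e-6:
        # bulk lies (numerically) in the bonder plane: sign by convention
        k = int(np.argmax(np.abs(normal)))
        return normal if normal[k] > 0 else -normal
    return normal if side >= 0 else -normal
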