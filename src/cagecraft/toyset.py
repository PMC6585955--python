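"""Small synthetic building blocks for tests, examples and demos.

Every function returns a fresh :class:`~cagecraft.building_blocks.BuildingBlock`
built from a SMILES string with deterministic embedded coordinates, so
the whole suite runs without any external structure files.  The set
covers di-, tri-, tetra- and hexa-topic amines, aldehydes and
halides — the combinations needed to exercise every cage family, the
linear polymer builder and all four 2D nets.
"""

from __future__ import annotations

from functools import lru_cache

from .building_blocks import BuildingBlock, make_building_block
from .core import Molecule, load_molecule

_CATALOG = {
    # label: (smiles, functional group)
    "diamine": ("NCCN", "amine"),                     # ethylenediamine, 12 atoms
    "diamine_asym": ("CC(N)CN", "amine"),             # propane-1,2-diamine
    "dialdehyde": ("O=Cc1ccc(C=O)cc1", "aldehyde"),   # terephthalaldehyde
    "dialdehyde_small": ("O=CCC=O", "aldehyde"),      # malondialdehyde
    "dibromide": ("BrCCBr", "bromine"),
    "triamine": ("NCC(CN)CN", "amine"),
    "trialdehyde": ("O=Cc1cc(C=O)cc(C=O)c1", "aldehyde"),  # 1,3,5-tricarbaldehyde, 18 atoms
    "tetraamine": ("NCC(CN)(CN)CN", "amine"),
    "tetraaldehyde": ("O=CCC(CC=O)(CC=O)CC=O", "aldehyde"),
    "hexaaldehyde": ("O=Cc1c(C=O)c(C=O)c(C=O)c(C=O)c1C=O", "aldehyde"),
}


@lru_cache(maxsize=None)
def _embedded(label: str) -> Molecule:
    smiles, _ = _CATALOG[label]
    return load_molecule(smiles, "smiles")


def toy_block(label: str) -> BuildingBlock:
    """A named toy building block with fresh (copyable) coordinates."""
    if label not in _CATALOG:
        raise KeyError(f"unknown toy block {label!r}; known: {', '.join(_CATALOG)}")
    _, fg = _CATALOG[label]
    return make_building_block(_embedded(label).copy(), fg, label=label)


def toy_block_names() -> list[str]:
    return list(_CATALOG)


def diamine() -> BuildingBlock:
    return toy_block("diamine")


def trialdehyde() -> BuildingBlock:
    return toy_block("trialdehyde")


def tetraaldehyde() -> BuildingBlock:
    return toy_block("tetraaldehyde")


def hexaaldehyde() -> BuildingBlock:
    return toy_block("hexaaldehyde")
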