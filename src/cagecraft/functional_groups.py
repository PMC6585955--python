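"""Functional-group database, matching, and the assembly "reaction".

A functional group is a set of atoms in a building block known to take
part in bond formation: its *bonder* atoms form the new bond and its
*deleter* atoms are removed once the bond exists (imine condensation,
for example, bonds the amine N to the aldehyde C while losing the two
amine hydrogens and the carbonyl oxygen).  Groups need not correspond
to textbook chemistry — users may register any pattern at runtime to
bond arbitrary atom sets.

The reaction itself is deliberately split in two steps that mirror the
assembly pipeline: :func:`react_pair` adds the flagged bond and only
*marks* the deleter atoms, so that many bonds can be formed against a
stable atom numbering; :func:`delete_marked_atoms` then removes every
marked atom at once and re-indexes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources

import yaml

from .core import Bond, Molecule, to_rdkit

#: molecule-property keys used for reaction bookkeeping
MATCH_KEY = "_fg_matches"
MARK_KEY = "_marked_for_deletion"
FRAGMENT_KEY = "fragments"


@dataclass(frozen=True)
class FGDefinition:
    """A named functional group: SMARTS pattern plus bonder/deleter slots."""

    name: str
    smarts: str
    bonder_slots: tuple[int, ...]
    deleter_slots: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bonder_slots", tuple(self.bonder_slots))
        object.__setattr__(self, "deleter_slots", tuple(self.deleter_slots))
        if set(self.bonder_slots) & set(self.deleter_slots):
            raise ValueError(f"{self.name}: bonder and deleter slots overlap")
        n = self._pattern().GetNumAtoms()
        for slot in (*self.bonder_slots, *self.deleter_slots):
            if not 0 <= slot < n:
                raise ValueError(f"{self.name}: slot {slot} outside pattern ({n} atoms)")

    def _pattern(self):
        from rdkit import Chem

        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"{self.name}: invalid SMARTS {self.smarts!r}")
        return patt


@dataclass(frozen=True)
class FunctionalGroupMatch:
    """One matched instance of a functional group inside a molecule."""

    fg_name: str
    atom_ids: tuple[int, ...]
    bonder_ids: tuple[int, ...]
    deleter_ids: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "fg_name": self.fg_name,
            "atom_ids": list(self.atom_ids),
            "bonder_ids": list(self.bonder_ids),
            "deleter_ids": list(self.deleter_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunctionalGroupMatch":
        return cls(
            d["fg_name"],
            tuple(d["atom_ids"]),
            tuple(d["bonder_ids"]),
            tuple(d["deleter_ids"]),
        )


# ---------------------------------------------------------------------------
# Database
# ---------------------------------------------------------------------------

_DATABASE: "dict[str, FGDefinition] | None" = None


def _load_database() -> dict[str, FGDefinition]:
    global _DATABASE
    if _DATABASE is None:
        text = resources.files("cagecraft.data").joinpath("functional_groups.yaml").read_text()
        payload = yaml.safe_load(text)
        _DATABASE = {
            entry["name"]: FGDefinition(
                entry["name"],
                entry["smarts"],
                tuple(entry["bonder_slots"]),
                tuple(entry["deleter_slots"]),
            )
            for entry in payload["groups"]
        }
    return _DATABASE


def functional_group_names() -> list[str]:
    return sorted(_load_database())


def get_functional_group(name: str) -> FGDefinition:
    db = _load_database()
    if name not in db:
        raise KeyError(
            f"unknown functional group {name!r}; known: {', '.join(sorted(db))}"
        )
    return db[name]


def register_functional_group(defn: FGDefinition, overwrite: bool = False) -> None:
    """Add a user-defined functional group to the runtime database."""
    db = _load_database()
    if defn.name in db and not overwrite:
        raise ValueError(f"functional group {defn.name!r} already registered")
    db[defn.name] = defn


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_functional_groups(m: Molecule, fg_name: str) -> list[FunctionalGroupMatch]:
    """Maximal atom-disjoint matches of a named group, deterministically ordered.

    Candidate substructure hits are sorted by their smallest atom index
    (ties by the full index tuple) and accepted greedily, skipping any
    hit that shares an atom with an already accepted one.  The result
    is therefore reproducible across runs and platforms.
    """
    defn = get_functional_group(fg_name)
    rdmol = to_rdkit(m, conformer=None)
    hits = rdmol.GetSubstructMatches(defn._pattern(), uniquify=True, maxMatches=100000)
    candidates = sorted(hits, key=lambda hit: (min(hit), tuple(sorted(hit)), hit))
    used: set[int] = set()
    matches: list[FunctionalGroupMatch] = []
    for hit in candidates:
        if used & set(hit):
            continue
        used.update(hit)
        matches.append(
            FunctionalGroupMatch(
                fg_name=fg_name,
                atom_ids=tuple(hit),
                bonder_ids=tuple(hit[i] for i in defn.bonder_slots),
                deleter_ids=tuple(hit[i] for i in defn.deleter_slots),
            )
        )
    matches.sort(key=lambda match: min(match.atom_ids))
    return matches


def deduce_fg_from_filename(path: str) -> "str | None":
    """Longest database group name occurring in the base filename, or ``None``."""
    base = os.path.basename(path).lower()
    found = [name for name in _load_database() if name.lower() in base]
    if not found:
        return None
    return max(found, key=len)


# ---------------------------------------------------------------------------
# Reaction bookkeeping
# ---------------------------------------------------------------------------

def attach_matches(m: Molecule, matches: list[FunctionalGroupMatch]) -> Molecule:
    """Record FG matches on the molecule so :func:`react_pair` can find them."""
    m.properties[MATCH_KEY] = [match.to_dict() for match in matches]
    return m


def get_attached_matches(m: Molecule) -> list[FunctionalGroupMatch]:
    return [FunctionalGroupMatch.from_dict(d) for d in m.properties.get(MATCH_KEY, [])]


def _match_of_bonder(m: Molecule, bonder: int) -> dict:
    for record in m.properties.get(MATCH_KEY, []):
        if bonder in record["bonder_ids"]:
            return record
    raise ValueError(f"atom {bonder} is not a bonder atom of any attached FG match")


def react_pair(m: Molecule, bonder_a: int, bonder_b: int, order: "int | str" = 1) -> Molecule:
    """Form one assembly bond between two bonder atoms and mark their deleters.

    Both atoms must be bonder atoms of *distinct* attached FG matches
    (see :func:`attach_matches`) and must not already be bonded.  The
    deleter atoms of both matches are queued for removal; call
    :func:`delete_marked_atoms` once all bonds are formed.
    """
    rec_a = _match_of_bonder(m, bonder_a)
    rec_b = _match_of_bonder(m, bonder_b)
    if rec_a is rec_b:
        raise ValueError("both bonder atoms belong to the same functional group match")
    for bond in m.bonds:
        if {bond.a, bond.b} == {bonder_a, bonder_b}:
            raise ValueError(f"atoms {bonder_a} and {bonder_b} are already bonded")
    m.bonds.append(Bond(bonder_a, bonder_b, order, is_assembly_bond=True))
    marked = m.properties.setdefault(MARK_KEY, [])
    for idx in (*rec_a["deleter_ids"], *rec_b["deleter_ids"]):
        if idx not in marked:
            marked.append(idx)
    return m


def delete_marked_atoms(m: Molecule) -> Molecule:
    """Remove all marked atoms, their incident bonds, and re-index contiguously.

    Assembly-bond flags and lattice shifts survive re-indexing; the
    per-atom ``fragments`` annotation and the attached FG matches are
    remapped alongside the atoms.
    """
    marked = set(m.properties.get(MARK_KEY, []))
    if not marked:
        m.properties.pop(MARK_KEY, None)
        return m
    keep = [i for i in range(m.n_atoms) if i not in marked]
    remap = {old: new for new, old in enumerate(keep)}

    new_atoms = [m.atoms[i] for i in keep]
    new_bonds = []
    for bond in m.bonds:
        if bond.a in marked or bond.b in marked:
            continue
        bond.a, bond.b = remap[bond.a], remap[bond.b]
        new_bonds.append(bond)
    new_confs = [conf[keep] for conf in m.conformers]

    props = m.properties
    props.pop(MARK_KEY, None)
    if FRAGMENT_KEY in props:
        props[FRAGMENT_KEY] = [props[FRAGMENT_KEY][i] for i in keep]
    if MATCH_KEY in props:
        remapped = []
        for record in props[MATCH_KEY]:
            remapped.append(
                {
                    "fg_name": record["fg_name"],
                    "atom_ids": [remap[i] for i in record["atom_ids"] if i not in marked],
                    "bonder_ids": [remap[i] for i in record["bonder_ids"] if i not in marked],
                    "deleter_ids": [remap[i] for i in record["deleter_ids"] if i not in marked],
                }
            )
        props[MATCH_KEY] = remapped

    fresh = Molecule(new_atoms, new_bonds, new_confs, props, m.cell)
    return fresh
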