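"""Batch construction of supramolecule populations for screening.

Three generation modes mirror common screening strategies: exhaustive
enumeration of every (ditopic, multitopic, topology) combination,
uniform random sampling, and "chemically diverse" sampling in which
each random member is paired with an analog built from the pool
blocks *least* similar to its own (Dice similarity over circular
Morgan fingerprints, radius 2, 2048 bits).

Member identity, used for optional deduplication, is a canonical hash
of the assembled bond graph (element-labelled Weisfeiler-Lehman), so
two assemblies with the same connectivity collapse to one key even
when their coordinates differ.
"""

from __future__ import annotations

import logging
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .building_blocks import BuildingBlock
from .cages import assemble_cage
from .core import to_rdkit
from .topology import AssembledMolecule

logger = logging.getLogger(__name__)

FP_RADIUS = 2
FP_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """On-bit indices of a folded circular (Morgan) fingerprint."""

    bits: frozenset

    def __post_init__(self) -> None:
        if any(not 0 <= b < FP_BITS for b in self.bits):
            raise ValueError(f"fingerprint bits must lie in [0, {FP_BITS})")


@dataclass
class Population:
    members: list = field(default_factory=list)
    provenance: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def add(self, member: AssembledMolecule, record: dict) -> None:
        self.members.append(member)
        self.provenance.append(record)


def identity_key(a: AssembledMolecule) -> str:
    """Canonical identifier of the assembled bond graph."""
    g = nx.Graph()
    for atom in a.molecule.atoms:
        g.add_node(atom.index, element=atom.element)
    for bond in a.molecule.bonds:
        if g.has_edge(bond.a, bond.b):
            g[bond.a][bond.b]["order"] += f"+{bond.order}"
        else:
            g.add_edge(bond.a, bond.b, order=str(bond.order))
    return nx.weisfeiler_lehman_graph_hash(
        g, node_attr="element", edge_attr="order", iterations=4
    )


def block_smiles(block: BuildingBlock) -> str:
    """Canonical SMILES of a building block (identity/tie-break key)."""
    from rdkit import Chem

    mol = to_rdkit(block.molecule, conformer=None)
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # assembled or exotic valences: fall back to raw graph
        mol.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Fingerprints and similarity
# ---------------------------------------------------------------------------

def fingerprint(block: BuildingBlock) -> Fingerprint:
    """Radius-2, 2048-bit circular fingerprint of a building block."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = to_rdkit(block.molecule, conformer=None)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()))


def dice_similarity(f1: Fingerprint, f2: Fingerprint) -> float:
    """Dice coefficient ``2|A&B| / (|A|+|B|)``; 0 when both sets are empty."""
    total = len(f1.bits) + len(f2.bits)
    if total == 0:
        return 0.0
    return 2.0 * len(f1.bits & f2.bits) / total


# ---------------------------------------------------------------------------
# Generation modes
# ---------------------------------------------------------------------------

def _assemble(d: BuildingBlock, m: BuildingBlock, topology: str, seed: int):
    return assemble_cage(topology, [d, m], seed=seed)


def enumerate_combinations(
    ditopic: "list[BuildingBlock]",
    multitopic: "list[BuildingBlock]",
    topologies: "list[str]",
    dedup: bool = False,
    seed: int = 0,
) -> Population:
    """Every (ditopic, multitopic, topology) combination, in deterministic order."""
    if not ditopic or not multitopic or not topologies:
        raise ValueError("all three input lists must be non-empty")
    pop = Population()
    seen: set[str] = set()
    for topology in topologies:
        for mi, m in enumerate(multitopic):
            for di, d in enumerate(ditopic):
                member = _assemble(d, m, topology, seed)
                if dedup:
                    key = identity_key(member)
                    if key in seen:
                        continue
                    seen.add(key)
                pop.add(
                    member,
                    {
                        "mode": "all",
                        "topology": topology,
                        "ditopic": d.label or f"d{di}",
                        "multitopic": m.label or f"m{mi}",
                        "seed": seed,
                    },
                )
    return pop


def sample_random(
    ditopic: "list[BuildingBlock]",
    multitopic: "list[BuildingBlock]",
    topologies: "list[str]",
    k: int,
    seed: "int | None" = None,
) -> Population:
    """k members drawn uniformly (with replacement) over all combinations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    pop = Population()
    for _ in range(k):
        d = ditopic[int(rng.integers(len(ditopic)))]
        m = multitopic[int(rng.integers(len(multitopic)))]
        topology = topologies[int(rng.integers(len(topologies)))]
        member_seed = int(rng.integers(2**31 - 1))
        pop.add(
            _assemble(d, m, topology, member_seed),
            {
                "mode": "random",
                "topology": topology,
                "ditopic": d.label,
                "multitopic": m.label,
                "seed": member_seed,
            },
        )
    return pop


def _least_similar(block: BuildingBlock, pool: "list[BuildingBlock]") -> BuildingBlock:
    """Pool block with minimal Dice similarity to *block*; ties by canonical SMILES."""
    ref = fingerprint(block)
    scored = sorted(
        ((dice_similarity(ref, fingerprint(cand)), block_smiles(cand), i)
         for i, cand in enumerate(pool)),
    )
    return pool[scored[0][2]]


def sample_diverse(
    ditopic: "list[BuildingBlock]",
    multitopic: "list[BuildingBlock]",
    topologies: "list[str]",
    k: int,
    seed: "int | None" = None,
) -> Population:
    """Half random members, half "chemically diverse" analogs.

    Each of the k/2 random members spawns one analog in which every
    building block is replaced by the pool block least similar to it
    (per-slot search).  With single-block pools the analog equals the
    original and a warning is logged.
    """
    if k < 2 or k % 2:
        raise ValueError("k must be an even integer >= 2")
    random_half = sample_random(ditopic, multitopic, topologies, k // 2, seed)
    pop = Population(random_half.members, random_half.provenance)
    for record in list(random_half.provenance):
        d = next(b for b in ditopic if b.label == record["ditopic"])
        m = next(b for b in multitopic if b.label == record["multitopic"])
        if len(ditopic) == 1 or len(multitopic) == 1:
            logger.warning("pool of size 1: diverse analog equals the original")
        d2 = _least_similar(d, ditopic) if len(ditopic) > 1 else d
        m2 = _least_similar(m, multitopic) if len(multitopic) > 1 else m
        pop.add(
            _assemble(d2, m2, record["topology"], record["seed"]),
            {
                "mode": "diverse-analog",
                "topology": record["topology"],
                "ditopic": d2.label,
                "multitopic": m2.label,
                "seed": record["seed"],
            },
        )
    return pop


# ---------------------------------------------------------------------------
# Parallel batch application
# ---------------------------------------------------------------------------

def _apply_one(args):
    operation, member = args
    try:
        return ("ok", operation(member))
    except Exception:
        return ("err", traceback.format_exc(limit=3))


def batch_apply(p: Population, operation, n_workers: int = 1) -> Population:
    """Apply a pure per-member operation, optionally across processes.

    Results are identical in order and content for any worker count.
    A member whose operation raises is dropped from the output and the
    failure recorded in ``Population.failures``; it never aborts the
    batch.
    """
    jobs = [(operation, member) for member in p.members]
    if n_workers <= 1 or not jobs:
        results = [_apply_one(job) for job in jobs]
    else:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_apply_one, jobs))
    out = Population()
    for (status, value), record in zip(results, p.provenance):
        if status == "ok":
            out.add(value, dict(record))
        else:
            out.failures.append({"provenance": dict(record), "error": value})
    return out
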