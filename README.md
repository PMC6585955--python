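# cagecraft

**cagecraft** builds 3D models of supramolecular materials from small
molecular building blocks: porous organic cages (14 topologies in four
families), linear polymers and oligomers, and periodic 2D covalent
organic frameworks (COFs) — plus batch "populations" of assemblies for
high-throughput screening.  It is aimed at computational materials
chemists who need realistic starting structures for optimization,
property calculation or screening pipelines, without hand-placing a
single atom.

## How assembly works

A building block is a molecule carrying two or more tagged
**functional groups**.  Within each group, *bonder* atoms form new
bonds during assembly and *deleter* atoms are removed when they react
— for imine condensation, the amine N is the bonder and its two H
atoms are deleters, while the aldehyde contributes its carbonyl C as
bonder and loses the O.  Groups are matched by SMARTS pattern from a
shipped database (amine, aldehyde, carboxylic acid, halides, …) or
registered at runtime for arbitrary atom sets.

Every supramolecule is produced by the same four steps on a
**topology graph** (vertices and edges with idealized coordinates):

1. **Place** each block at its position, oriented by three descriptors:
   the bonder–bonder direction vector (ditopic blocks), the
   centroid–centroid vector (points at the block's bulk, used to keep
   cage cavities open), and the bonder-plane normal (3+-topic blocks).
2. **Bond** designated bonder pairs — two bonds per edge when ditopic
   linkers sit on edges, one per edge when vertex blocks connect
   directly.  In periodic nets, bonds that close onto a translated
   cell image carry an integer lattice-shift vector.
3. **Delete** the marked deleter atoms and re-index.
4. **Refine** (optional): the built-in refiner shrinks only the new
   assembly bonds toward the sum of the covalent radii of the bonded
   atoms, moving each original block as a rigid body, so all
   pre-existing bond lengths are preserved exactly.  Third-party
   optimizers plug in behind the same contract.

Cage topologies follow the `XpmYn` nomenclature (`Tri4Di6` = 4
tritopic + 6 ditopic blocks on a tetrahedron, `Tri8Di12` a cube,
`Tet6Tri8` alternating vertices, …).  COF nets cover *hcb*, *hxl*,
*sql* and *kgm*; periodic cells can be serialized with explicit
shifted connectivity or carved into finite hydrogen-capped "islands".

## Worked example

```python
from cagecraft import (assemble_cage, block_from_smiles, cavity_diameter,
                       relax_assembly_bonds, assembly_bond_objective)

tri = block_from_smiles("O=Cc1cc(C=O)cc(C=O)c1", "aldehyde")  # 18 atoms
di = block_from_smiles("NCCN", "amine")                        # 12 atoms

cage = assemble_cage("Tri4Di6", [tri, di], seed=42)
print(cage.molecule.n_atoms, len(cage.assembly_bonds))
relax_assembly_bonds(cage)
print(round(assembly_bond_objective(cage), 6), round(cavity_diameter(cage), 2))
```

prints

```
108 12
2e-06 7.26
```

108 atoms is exactly the conservation arithmetic 4·18 + 6·12 − 12·3:
twelve imine bonds form (two per edge) and each deletes three atoms.
After rigid-body relaxation the sum of squared bond-length deviations
is ~2·10⁻⁶ Å², i.e. every new bond sits at its target length, and the
cage has a 7.26 Å van-der-Waals-corrected cavity.

The `examples/` directory has one short script per capability (cage,
polymer, COF + island, population screening, I/O and tagging), and the
same functionality is reachable from the shell:

```sh
cagecraft assemble cage --topology Tri4Di6 \
    --block "smiles:O=Cc1cc(C=O)cc(C=O)c1=aldehyde" \
    --block "smiles:NCCN=amine" --seed 42 --relax -o cage.mol
```

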