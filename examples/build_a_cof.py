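"""Assemble a honeycomb (hcb) 2D framework cell and carve a finite island.

The tritopic block lies flat on the xy plane on each net vertex, the
ditopic block sits on each edge, and two of the six new bonds close
onto translated images of the cell (nonzero lattice shifts).
"""

from cagecraft import assemble_cof, block_from_smiles, carve_island, write_periodic_cell

trialdehyde = block_from_smiles("O=Cc1cc(C=O)cc(C=O)c1", "aldehyde")
diamine = block_from_smiles("NCCN", "amine")

cof = assemble_cof("honeycomb", trialdehyde, diamine, vertex_rotation=0.0)
periodic = [b for b in cof.molecule.bonds if b.is_assembly_bond and any(b.lattice_shift)]
print(f"atoms per cell: {cof.molecule.n_atoms}")
print(f"assembly bonds per cell: {len(cof.assembly_bonds)} ({len(periodic)} periodic)")

with open("cof.gin", "w") as fh:
    fh.write(write_periodic_cell(cof, "lattice_input"))
print("wrote cof.gin (cell vectors + coordinates + shifted connectivity)")

island = carve_island(cof, 3, 3)
info = island.properties["island"]
# severed boundary bonds are replaced by hydrogen caps, so
# atoms = nx*ny*atoms_per_cell + caps holds exactly
print(f"3x3 island: {island.n_atoms} atoms = 9*{info['atoms_per_cell']} + {info['caps']} caps")
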