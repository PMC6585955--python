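# Methods

This note records the model behind cagecraft's assembly engine, the
defaults that matter, the numerical choices, and the places where the
design was genuinely open.

## Molecular model

A molecule is an element-labelled bond graph plus one or more
conformer coordinate sets in Cartesian angstroms.  Two extensions
beyond a plain cheminformatics mol drive everything else:

* every bond carries an integer **lattice-shift** vector, `(0,0,0)`
  for ordinary bonds and nonzero for bonds that close onto a
  translated image of a periodic cell;
* every bond carries an **assembly flag** marking it as created by an
  assembly step rather than present in a building block.

RDKit does all format parsing and writing (MOL V2000, PDB, SMILES,
SMARTS) and supplies the substructure matcher and fingerprints; the
package's own JSON schema (versioned, `"schema": 1`) persists the two
extensions losslessly.  Line notations receive deterministic
distance-geometry coordinates (fixed seed 42) so that every structure
derived from a SMILES string is bit-reproducible across runs; a
spring-layout fallback covers patterns the embedder rejects.  Atomic
masses are CIAAW 2021 standard atomic weights, covalent radii Cordero
2008, van der Waals radii Bondi 1964 (H from Rowland & Taylor 1996),
all embedded in one table — no runtime lookups.

Atom indices are 0-based everywhere in the API and 1-based only
inside MOL/PDB records.

## Functional groups and the reaction model

A functional-group definition is a SMARTS pattern plus *bonder* and
*deleter* slot indices.  Matching takes the maximal atom-disjoint set
of hits, ordered and tie-broken by smallest atom index, which makes
match order (and therefore "the first three functional groups")
reproducible across platforms.  The reaction is deliberately
minimal: `react_pair` adds one flagged bond between two bonder atoms
of distinct matches and only *marks* both matches' deleters;
`delete_marked_atoms` removes all marks at once and re-indexes.  This
two-phase design keeps atom numbering stable while an arbitrary
number of bonds is formed.

New assembly bonds default to single order.  Whether an imine should
appear as C=N at assembly time is left to refinement plug-ins: bond
orders of freshly formed bonds are a chemistry-perception question
the geometric engine does not answer.

## Placement geometry

Three unit descriptors orient a block (all equivariant under rigid
motion, unit length to 1e-9):

* **bonder–bonder direction** (ditopic): bonder of match 0 to bonder
  of match 1;
* **centroid–centroid vector**: bonder centroid toward molecular
  centroid, i.e. toward the bulk; degenerate for centrosymmetric
  blocks, in which case edge placement skips the roll and logs a
  warning;
* **bonder-plane normal** (topicity ≥ 3): normal of the plane through
  the first three bonder atoms, signed to point away from the bulk.
  When the bulk lies numerically in the plane (|cos| < 1e-6, the
  planar-block case) the sign falls back to a fixed component
  convention; for planar blocks the two orientations are equivalent,
  so the instability is harmless, but equivariance tests use
  non-planar blocks.

Scaffold scale: unit topology coordinates are multiplied by the
largest bonder–bonder distance over all placed blocks.  This is the
smallest scale at which blocks cannot overlap their own bond targets;
any constant would do, because refinement owns realistic geometry.

Vertex placement aligns the plane normal with the outward vertex axis
and then rolls the block so the `alignment_choice`-th bonder comes
closest (closed-form azimuth match) to the vertex's first edge; each
choice is one structural isomer — three options for tritopic, four
for tetratopic blocks.  Edge placement aligns the bonder axis
parallel or anti-parallel with the edge (the `parallel_flag` isomer
control for asymmetric linkers), then rolls the bulk outward from the
scaffold centroid so cage cavities stay open.  Vertex blocks are not
re-aligned after edge blocks are placed (single forward pass).

Bond pairing: each edge block's two bonders are assigned to the
nearer edge end; at every vertex the designated pairing is made
first, then remaining bonders pair with remaining incident edge ends
greedily by distance, ties broken by ascending edge id.  In direct
vertex–vertex mode the free bonder pair minimizing distance (plus a
small steering term toward the edge's reference position, needed for
multi-edge topologies like `Tri1Tri1`) is bonded per edge.  Counting
rule: 2|E| assembly bonds with edge linkers, |E| without.

## Cage registry

Fourteen topologies in four families; vertex coordinates are the
standard polyhedra (tetrahedron, cube, octahedron, trigonal prism,
dodecahedron; axial pairs with ringed edge positions for the
multigraph cases `Tri2Di3`, `Tet2Di4`, `Tet3Di6`, `Tet4Di8`).
`Tri4Di6b` is the same K4 graph on a squashed tetrahedron — a second
idealized shape for the same stoichiometry.  The Tri+Tri family
connects vertex blocks directly; `Tet6Tri8` alternates tetratopic
blocks on an octahedron with tritopic blocks on the surrounding cube
corners (24 direct bonds).  Cavity diameter is
`2·min_i(|r_i − centroid| − r_vdW,i)`; negative values flag a
collapsed cavity.

## Polymers

Blocks are placed along +x with the bonder axis on the chain axis;
position i is flipped with its monomer's probability, drawn one
uniform variate per position from a seeded generator regardless of p
(so p = 0 and p = 1 are exact and the draw count is
input-independent).  Spacing between consecutive bonder centroids is
1.1× the current block's bonder–bonder distance — a clash guard,
since refinement sets real geometry.  Chain-terminal functional
groups never react, so their deleters survive as intact unreacted
ends; capping is left to users.

## 2D frameworks

Net data (fractional vertices, edge shift vectors) follow the
standard crystallographic descriptions: hcb = graphene positions
(2 vertices, 3 edges), hxl = triangular lattice (1 vertex, 3
self-edges), sql = square lattice (1 vertex, 2 self-edges), kgm =
edge-midpoints of the triangular lattice (3 vertices, 6 edges).  All
satisfy the handshake identity 2|E| = Σ coordination, and unit
coordinates are normalized to edge length 1 before block-size
scaling.  Vertex blocks lie with their bonder plane on xy (+z
normal), with an optional in-plane rotation as the isomer control;
the hexagonal net's vertex block must be 6-topic, square and kagome
4-topic, honeycomb 3-topic.  The out-of-plane lattice vector is a
fixed 30 Å single-layer spacing — stacking is downstream work.

Periodic cells serialize to a generic GULP-style `lattice_input`
block (no claim of dialect round-trip compatibility) or extended XYZ.
Island carving replicates the cell nx×ny, realizes interior shifted
bonds, and caps *every* dangling end of a severed boundary bond with
hydrogen at (covalent radius of host + covalent radius of H) along
the former bond vector; the atom count obeys
`nx·ny·atoms_per_cell + caps` exactly, with caps counted per dangling
end (a 1×1 island therefore has two caps per boundary-crossing bond,
one where it leaves and one where it would re-enter).

## Constrained relaxation

Objective: Σ(dᵢ − dᵢ*)² over assembly bonds, dᵢ* = covalent-radius
sum (chemistry-neutral).  Cyclic coordinate descent over rigid
original-block fragments: per fragment, a closed-form translation
step (exact for a single bond) with backtracking halving, then a
small-angle rotation line search about the net torque axis (angles
0.2 → 0.005 rad).  Steps are accepted only when the objective does
not increase, so descent is monotone by construction; intra-fragment
distances are untouched at machine precision.  Defaults
`max_iter=500`, `tol=1e-3` Å on the worst bond residual.  Periodic
bonds enter the objective with their shift offsets.  Third-party
optimizers attach through `refine`, whose contract (atom count,
element sequence and bond list preserved; coordinates free) is
enforced, with a provenance note recorded per call.

## Populations

Exhaustive mode assembles every (ditopic, multitopic, topology)
combination in deterministic order; random mode samples uniformly
with replacement from a seeded generator, giving each member its own
derived seed.  Diverse mode builds one analog per random member by
replacing each block with the pool block of *minimal* Dice similarity
(radius-2, 2048-bit circular fingerprints — the family's common
default, recorded here), ties broken by canonical SMILES.  The search
is per-slot (each block replaced independently) at O(pool) cost; a
joint search over block tuples would also fit the idea and is noted
as the alternative.  Identity for deduplication is an
element/order-labelled Weisfeiler–Lehman hash of the assembled bond
graph, which ignores coordinates by design.  `batch_apply` maps a
pure per-member operation serially or over a process pool with
order-stable results and per-member failure isolation.

## What the toy set does and does not show

The built-in blocks (ethylenediamine, terephthalaldehyde,
benzene-1,3,5-tricarbaldehyde, a neopentane-core tetraaldehyde,
benzenehexacarbaldehyde, simple halides) are real, embeddable
molecules spanning topicities 2–6 — enough to exercise every
topology, net and reaction path.  They are small and mostly rigid;
passing tests therefore demonstrate correct *bookkeeping and
geometry* (conservation laws, bond counts, determinism, placement
orientation), not that assembled structures are near an energy
minimum for large flexible blocks — that is exactly what the
refinement contract delegates.  Tests run at desk scale: the largest
routine assembly is the 540-atom `Tri20Di30` dodecahedron and a
3×3 kagome island (~1000 atoms), sizes chosen because every
bookkeeping law they check is size-exact rather than statistical.

## Known limitations

* Bond orders of assembly bonds stay single; no tautomer or
  protonation handling.
* Degree-2 vertices host ditopic blocks aligned to their first edge
  only (no such topology ships in the registry).
* 3D nets, interlayer stacking, window sizes, and any energy or
  electronic-property evaluation are out of scope; the refinement
  plug-in contract is the extension point.
* InChI output is omitted rather than guessed.
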