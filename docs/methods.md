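# Methods

## Model

`twnkit` analyses *topological water networks* (TWNs): cyclic arrangements
of 3–6 explicit 3-site waters mutually connected by hydrogen bonds in one
MD snapshot. Persistent TWNs in a binding pocket mark positions where
structured water sits in the apo protein — candidate pharmacophoric sites
where a ligand hydrogen-bonding group can profitably displace or mimic
water.

### Pair potential and hydrogen-bond criterion

Two waters *a*, *b* interact through

v(a,b) = k Σ_{i∈a} Σ_{j∈b} q_i q_j / r_ij + A / r_OO¹² − C / r_OO⁶

with the Coulomb sum over all nine site pairs (O, H, H × O, H, H) and the
Lennard-Jones term on the oxygen–oxygen distance only. Defaults:

| parameter | value | units | note |
|---|---|---|---|
| A | 582 000 | kcal·Å¹²·mol⁻¹ | LJ repulsion, O–O |
| C | 595 | kcal·Å⁶·mol⁻¹ | LJ dispersion, O–O |
| q_O / q_H | −0.834 / +0.417 | e | TIP3P-style site charges; neutral water enforced |
| k | 332.0636 | kcal·Å·mol⁻¹·e⁻² | standard conversion for q_i q_j e²/r in these units |
| threshold | −2.25 | kcal·mol⁻¹ | H-bond criterion, **inclusive** (≤) |
| prefilter | 3.5 | Å | O–O candidate cutoff, part of the H-bond definition |

A pair is hydrogen-bonded when its O–O distance is within the prefilter
**and** v(a,b) ≤ −2.25 kcal/mol. The distance condition is semantic, not
merely an optimisation: with these constants a near-linear dimer stays
below −2.25 kcal/mol out to ≈ 4.0 Å O–O (−3.5 at 3.5 Å), so an energy-only
criterion would admit stretched, already-broken contacts. The canonical
linear dimer at 2.8 Å O–O scores −6.17 kcal/mol, close to the TIP3P dimer
minimum, which is the consistency check fixing k: no other conversion
constant places the −2.25 criterion near the minimum of the pair-energy
distribution of liquid-density configurations. With a prefilter ≥ 4.0 Å
the graph provably equals the energy-only all-pairs construction; the test
suite verifies this empirically at 4.2 Å, and verifies at 3.5 Å that the
k-d-tree path equals the exhaustive O(n²) construction of the same
definition. Prefilters below 3.2 Å are rejected (they would cut genuine
H-bonds).

Periodic boxes must be orthorhombic. The minimum-image shift is computed
from the O–O displacement and applied to *all nine* site pairs, keeping
each molecule rigid; imaging sites independently would tear molecules
apart at the boundary. Charges default to the TIP3P-style values
regardless of the water model that produced the trajectory (they are
scoring parameters, not simulation parameters) and are overridable in the
config.

### Ring definition

A ring is a **chordless** simple cycle of length 3–6 in the per-frame
H-bond graph: consecutive members bonded, no bond between non-consecutive
members. Chordlessness matches chemical ring perception and prevents a
triangle's enclosing quadrilateral from being counted as a second network;
an all-simple-cycles mode (`--all-simple-cycles` / `chordless=False`) is
exposed for sensitivity analysis, since raw ring-size distributions that
would fix the convention externally are not generally available. Each ring
is reported once in canonical form (lowest water index first, then its
lower neighbour), and output order is deterministic. Enumeration is a DFS
over induced paths rooted at each cycle's minimum node; it is validated in
the tests against both a brute-force simple-cycle-plus-chord-filter oracle
and networkx's independent chordless-cycle generator.

The ring center is the unweighted centroid of the member **oxygens**
(oxygen carries 16/18 of the water mass; hydrogens mostly add noise). Mass
weighting over all sites is available. With a box, members are unwrapped
to the first member's image before averaging, so a boundary-straddling
ring gets a center on the cluster rather than mid-box.

### Site restriction and region occupancy

Waters are restricted to a sphere of default radius 25 Å centered on the
reference-ligand centroid (an explicit center can be given; the boundary
is inclusive). Each ring found inside is attributed to the region —
head, linker or tail — of the *nearest labelled ligand atom* within the
assignment cutoff (default 5 Å, tunable 3–7 Å for sensitivity), else it is
unassigned. Ties within 1 nÅ break by priority L′ > linker > head > tail.
Rings whose nearest labelled atom is the L′ atom (linker carbonyl) are
counted as linker and additionally flagged; the L′ fraction is reported
over linker rings. The L′ sub-flag uses its own cutoff, defaulting to the
assignment cutoff — whether a published "near the carbonyl" figure means a
distance cutoff or a sub-region partition is generally unstated, so the
flag-with-cutoff construction is the documented interpretation here.

Occupancy percentages are pooled over all frames (each ring instance
counts once per frame it appears in) and use **assigned rings as the
denominator**: head % + linker % + tail % = 100. Bulk-water rings inside
the site sphere but far from the ligand are counted as unassigned and
reported separately; a scene with zero assigned rings yields zero
percentages plus an explicit flag rather than NaNs.

### Shape similarity

Ligand and water-network shapes are compared on a common boolean voxel
grid (default 0.5 Å spacing). Ligand voxels lie within the Bondi van der
Waals radius of an in-scope atom; TWN voxels lie within a 1.4 Å water
probe radius of any member oxygen of any *ligand-proximal* ring — one
whose center lies within 2.0 Å (inclusive) of a ligand **heavy atom**.
Proximity to the nearest heavy atom, not to the ligand centroid, is the
operative reading: a centroid criterion at 2 Å would exclude essentially
every ring of an elongated ligand.

The default score is the **coverage** convention,
100 · |lig ∩ twn| / |lig|: the fraction of ligand (or region) volume
overlapped by ring-water density. This reproduces the qualitative pattern
expected of a ligand with a hydrophobic, never-hydrated tail — a low
whole-ligand score pulled down by the dry regions, and a high score when
the analysis is focused on a persistently hydrated carbonyl region. A
symmetric Tanimoto mode (|∩|/|∪|) is provided behind a flag; the exact
formula used by any particular published in-house code is not fixed by the
numbers it prints, so the convention is documented rather than claimed.

## Synthetic scenes

The fixture generator plants ground truth instead of simulating water:

- `make_ring` builds a planar regular polygon of 3–6 waters, each donating
  one hydrogen along the edge to its clockwise neighbour. The free
  hydrogen points radially outward in the ring plane, and the donor
  hydrogen is bent outward by 15°/5° for sizes 3/4 (edge length 2.75 Å);
  perfectly linear donors with out-of-plane free hydrogens fail the energy
  criterion for small rings (a 60° interior angle pushes the neighbour's
  sites into repulsion range), as real cyclic water clusters, which bend
  their H-bonds, suggest. Every generated ring is self-checked against
  the actual potential: adjacent pairs must be bonded, non-adjacent pairs
  must not — the fixtures stay coupled to the energetics rather than to a
  geometric assumption.
- `make_box` packs randomly oriented waters at liquid-like density with a
  minimum-image O–O exclusion (default 2.6 Å), seeded and reproducible.
- `make_toy_ligand` is a collinear 12-atom rod: 4 head, 4 linker (one
  mid-linker L′ oxygen), 4 tail atoms at 2.5 Å spacing.
- `plant_scene` distributes requested per-region ring counts over frames
  using a fixed slot table around the rod, at offsets 3.5–4.75 Å chosen so
  each slot's ring assigns to its intended region under the
  nearest-labelled-atom rule. Crowded slots plant only small rings so no
  inter-ring O–O contact comes within the prefilter; a generation-time
  self-check enforces center isolation (> 2 × prefilter), inter-ring O–O
  clearance, and intended region assignment, rather than trusting the
  static geometry. Noise waters are scattered in the site sphere ≥ 8.5 Å
  from every ligand atom (so any all-noise ring centroid stays beyond the
  5 Å assignment cutoff) and ≥ 4.5 Å from planted waters (no spurious
  edges): noise can only ever add *unassigned* rings, leaving planted
  percentages exact.
- `plant_proximal_shell` hugs one scope (default L′) with one ring per
  frame at 1.2 Å offset on a Fibonacci sphere of directions — an idealized
  persistently hydrated site inside the 2 Å COM cutoff, used for shape
  scoring.

What these fixtures do **not** emulate: liquid-water structure (no
RDF-matched disorder, no thermal ring deformation, no ring
formation/breakage kinetics), protein context, or competition between
overlapping networks. Passing the planted-truth tests therefore shows the
*machinery* is exact — parsing, graph construction, enumeration,
assignment and aggregation introduce no bias — not that the physics of a
real pocket is reproduced. Applying the toolkit to a real apo-MD ensemble
remains an external validation step requiring trajectories this package
deliberately does not produce.

## Problem sizes and numerical choices

Default demonstration scenes are sized for interactive use: the occupancy
scene plants 1000 rings (351 head / 649 linker, 487 at L′) over ~244
frames with 8 noise waters per frame, and the shape scene uses 120
one-ring frames; both run in seconds. Oracle tests use 100-water boxes at
~0.9 g/cm³ and random graphs with n ≤ 12, where exhaustive references are
exact and fast.

Numerical conventions, fixed for determinism: all boundary comparisons
(H-bond threshold, site radius, COM cutoff, assignment cutoff) are
inclusive (≤); O–O below 0.1 Å raises an overlap error; GRO coordinates
round-trip at 0.01 Å (format precision); voxel membership tests the voxel
*center* against sphere radii, so per-sphere voxel counts track analytic
volumes to within ~15 % at 0.5 Å spacing and joint rigid motions move
coverage scores by < 3 points (grid discretization). Empty frames give
empty graphs; empty site selections warn rather than fail.

## Limitations

- Orthorhombic boxes only; triclinic trajectories must be converted.
- 3-site waters only; 4/5-site and polarizable models are out of scope,
  as are geometric (distance–angle) H-bond criteria.
- No thermodynamic scoring of hydration sites and no ring-lifetime
  analysis across frames; frames are treated independently.
- Binary trajectory formats (XTC/DCD) are not read; convert to
  multi-model PDB or concatenated GRO first.
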