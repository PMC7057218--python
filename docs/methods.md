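# Methods

## The characteristic-vector representation

For any peptide window of at least three residues, the *characteristic
vector* (CV) runs from the centroid of the window's Cα atoms to the
centroid of its carbonyl O atoms.  Because helix formation aligns the
carbonyls with the helical axis while strand formation alternates them
across the chain, the CV field separates the two conformations cleanly:
over sliding tripeptide windows an ideal α-helix gives CV moduli near
2.2 Å with consecutive-CV angles of 5–10°, an ideal β-strand moduli near
1.4 Å with consecutive angles of 50–55°.  `cvfold` computes CVs for all
overlapping tripeptides (window 3, stride 1) of every connected stretch
and stores every pairwise relation — the angle between two CVs and the
Euclidean distance between their midpoints — in a complete graph, so both
local (adjacent-CV) and long-range (cross-fragment) geometry can be read
off the same object.

Two conventions deserve a note.  The CV–CV "distance" is taken between CV
*midpoints*; midpoints are symmetric under vector reversal, track the
position of the peptide in space and make the 6 Å sheet criterion
geometrically meaningful.  Origin–origin distance is available as a
configuration switch (`build_cv_graph(..., distance_mode="origin")`).
Angles are direction-only scalars in [0°, 180°]; no sign or dihedral is
attached.  Zero-modulus (degenerate) CVs are retained in the graph but
carry NaN angles and are excluded from all angle-based scoring.

## Penalty scoring and strictness

Each CV is scored against a helix hypothesis and a strand hypothesis with
a pseudo-distance built from three descriptors:

| descriptor | helix ideal | strand ideal | scale |
|---|---|---|---|
| CV modulus | 2.2 Å | 1.4 Å | 0.8 Å |
| mean angle to sequence-neighbour CVs | 7.5° | 52.5° | 45° |
| mean consecutive Cα–Cα spacing | 3.80 Å | 3.80 Å | 0.5 Å |

Each term is `min(1, |observed − ideal| / scale)` and the terms combine
with weights (0.50, 0.35, 0.15), so both scores live in [0, 1].  The CV is
labelled by the lower score only when the two scores differ by more than
the **strictness** threshold, otherwise it is coil.  Strictness is
per-hypothesis (defaults 0.5 for helices, 0.3 for strands — the values of
the reference library-generation run); raising it annotates shorter, more
ideal fragments, and the non-coil set shrinks monotonically because the
label test is a threshold on a strictness-independent score difference.
The ideals are the printed centre values of the two CV distributions; the
scales were fixed once, a priori, such that an ideal helix and an ideal
strand sit at score differences ≈0.85 (comfortably above any usable
strictness) while the bridge region between the basins stays balanced.
A small context refinement (up to 3 passes, capped at 10, ±5% of a score
per agreeing/conflicting sequence neighbour) lets labels stabilise before
they are frozen; iteration stops at a fixed point.

CV labels translate to residues by three ordered rules: (i) unanimity
among the residue's CVs; (ii) two helix CVs, no strand CV and a
helix-labelled following residue; (iii) a still-coil residue joining two
strand CVs and no helix CV, or one strand CV next to nearby coil.  Rules
(ii)–(iii) recover fragment termini.  Maximal same-label runs of at least
three residues become fragments; shorter runs revert to coil.

The per-residue confidence written to `strictnesses.pdb` is the maximum,
over the residue's CVs, of the largest strictness at which the CV would
still be annotated (the absolute score difference), scaled to [0, 100]
and placed in the B-factor column: red/low values flag ambiguous
geometry, e.g. carbonyls twisted off a helical axis.

## Sheets and the fragment graph

Two strands pair into a sheet when at least 40% of their cross-fragment
CV angles fall inside the parallel band ([0°, 30°]) **or** inside the
antiparallel band ([150°, 180°]), and their minimum CV–CV distance is
below 6 Å.  Sheets are the connected components of this pairing relation
(transitively closed).  The band edges stand in for an unpublished
empirical angle distribution and are configurable.

Fragments become supernodes of a complete fragment graph whose edges
store min/max/mean of all cross-fragment CV angles and distances plus a
clustering weight: the inverse mean distance, multiplied by 2.0 when the
fragments share a type, which promotes the packing of sheets.

## Decomposition

Groups are found by community clustering on the fragment graph,
maximising weighted Newman modularity (fraction of intra-group edge
weight minus its degree-preserving random expectation).  Eight igraph
algorithms are selectable (fastgreedy is the default; spinglass and label
propagation take an explicit seed, default 42); an unknown name fails
loudly.  Two constraints exist: `sheets_together` collapses each sheet
into a single pre-merged node, which makes sheet splitting impossible by
construction; `homogeneous_size` repeatedly damps (×0.8) the internal
edge weights of the largest group until group sizes differ by at most one
fragment or 20 rounds pass.  Hierarchical mode cuts the agglomerative
dendrogram at every level from one group to all singletons.  The output
PDB assigns one chain identifier per group; coil residues outside every
fragment follow their nearest fragment (minimum Cα distance) so the model
stays exhaustive for rigid-group refinement.

## Fold matrix and recursive search

A structure's CV graph is laid out as a square matrix: the diagonal holds
each CV's (modulus, label), the second diagonal the consecutive-CV
(angle, distance) relations — sufficient to recognise secondary-structure
elements in linear time — and the remaining cells the cross-fragment
relations that define the fold.  Template and target matrices are
compared cell-wise: a cell matches when the angle difference is within
±15° *and* the distance difference within ±2 Å (full-credit bands,
doubled for cells involving coil CVs); a block's similarity is the
percentage of matching cells.  The bands are a design choice calibrated
only by two self-evident anchors: a template compared with itself scores
100, and scores must fall smoothly under growing perturbation.

The search assigns target fragments to template fragments depth-first.
A candidate must share the fragment type and reach the intra-fragment
(secondary-structure) threshold on its best CV window — the window is
chosen by score alone, so thresholds only ever shrink the candidate set.
Partial assignments are pruned with an optimistic bound: a branch dies
only when even 100% scores on all unassigned fragment pairs could not
lift the aggregate inter-fragment (tertiary) score to its threshold.
This bound is admissible, so the recursion provably returns exactly the
set a brute-force enumeration over all fragment tuples accepts (a
property the test suite checks against an independent enumerator).
Thresholds act on the aggregate percentage over all cells, with the
per-level bound doing the pruning; this resolves the open choice between
per-pair and aggregate thresholds in favour of the aggregate, which keeps
completeness trivially true.  Fragment order is free unless connectivity
is required (then target fragments must follow the template's N→C
order); matches confined to one chain are the default unless the
template itself spans several chains or multi-chain mode is on.

Filters: a position-wise sequence pattern (X = wildcard) over the matched
residues, an S^γ–S^γ distance window of 1.8–2.5 Å for disulfide
enforcement, and a maximum Cα r.m.s.d. to the template (default 5.0 Å)
after superposition.

Library generation runs the five steps — annotate template, annotate
database entries, extract matches, filter, superpose onto the template —
writing each surviving model as `pdbid_x_yyyy.pdb` (x = coordinate-model
index, yyyy = running four-digit id) with a common B factor of 25.0 Å².
Clustering offers complete-linkage on exhaustive pairwise r.m.s.d.
(deterministic), binning by r.m.s.d.-to-template, or a seeded random
subset.

## Superposition

Correspondences come from the fold search.  Each site is refined with a
weighted Kabsch fit (proper rotation enforced via the SVD sign
correction, so mirror images are never matched) iterated with
inverse-variance weights: after each fit the per-pair squared residual
sets the next weight, 1/(r² + 10⁻⁴ Ų), normalised to mean 1, until the
r.m.s.d. moves less than 10⁻⁶ Å or 20 iterations pass.  The reported
r.m.s.d. is the weighted one — the fit quality over the consistent core —
which never exceeds the plain unweighted fit.  For every fragment longer
than five residues up to three residues may be cut from each extremity
(keeping at least a tripeptide); all cut combinations are enumerated
(full Cartesian product up to 10⁵ combinations, then a per-fragment
greedy sweep) and the lowest-r.m.s.d. core wins, with ties resolved
towards fewer cuts.  Site finding uses Cα atoms; the final refinement
uses all four main-chain atoms (configurable).  Sites sharing no target
residue are reported separately; among overlapping candidates the lower
r.m.s.d. (ties: earlier residue range) survives.

## The synthetic generator

Fixtures are grown in internal coordinates (NeRF-style placement from
ideal bond lengths/angles) so φ/ψ are exact: helices at (−57°, −47°),
strands at (−139°, +135°) with a deterministic alternating ±20° pleat on
both angles.  The pleat emulates the flattening that sheet hydrogen
bonding imposes on real strands; without it the uniform canonical repeat
is over-twisted and its consecutive-CV angles (~57°) leave the observed
50–55° range.  Carbonyls are placed in the peptide plane (N–Cα–C–O
torsion = ψ + 180°); the "coil" element follows a fixed irregular walk
through the bridge region where both penalty scores stay balanced.
Assembled fixtures centre each element before applying its placement
transform and ship a ground-truth sidecar (labels, fragments, element
membership).

The noise model is sequence-correlated: a per-residue Gaussian
displacement field (per-coordinate std = σ, correlation length ≈ 4
residues via an L2-normalised Gaussian kernel, which preserves the
marginal variance) moves whole residues, plus 10%-of-σ independent
per-atom jitter.  This imitates the low-frequency conformational
variation a fold library samples.  Independent per-atom noise of the same
magnitude would sever peptide bonds — something no real conformer family
does — and is therefore not what the generator produces.  Carbonyl
misorientation (rotation of selected O atoms about the local C–Cα axis)
is available separately to emulate distorted helices.

What passing on fixtures does **not** show: fixtures carry no side
chains (beyond approximate S^γ for Cys), no solvent, no lattice
disorder, and their torsion tracks are idealised; annotation percentages
on real, bent, low-resolution chains depend on the penalty scales, which
were fixed from the ideal statistics rather than calibrated against a
curated protein set.

## Numerical choices and limitations

* C–N connectivity window 1.1–1.8 Å; altloc ties break to the lowest
  letter; insertion codes sort after their base number.
* Angle comparisons near 0°/180° are limited by `arccos` conditioning to
  about 10⁻³ degrees under coordinate round-trips; distances and moduli
  reproduce to 10⁻⁶ Å.
* Modularity maximisation is heuristic; on graphs of ≤ 8 nodes the tests
  bound it by exhaustive search, beyond that no optimality claim is made.
  Very small graphs (≤ 3 supernodes) often have no positive-modularity
  split, so constrained runs may legitimately return a single group.
* Problem sizes in the test-suite: fixtures of 5–24 residues per element,
  libraries of ten database entries, 100 random search targets with ≤ 6
  fragments.  These sizes make every oracle comparison exhaustive while
  keeping the whole suite fast; the algorithms themselves carry no such
  limits.
* The database filter accepts a local directory plus an optional stem
  list; no remote database access is performed anywhere in the package.
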