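# cvfold

Characteristic-vector networks for protein main-chain geometry: flexible
secondary/tertiary-structure annotation, fold decomposition, sequence-free
fold-library extraction and superposition of small discontinuous
fragments.

## Who this is for

Crystallographers and structural bioinformaticians who work with *small
local folds* — composites of a few secondary-structure elements such as
"three strands facing a helix" — rather than whole domains.  Such folds
are the search models of fragment-based molecular replacement: ubiquitous
across unrelated families, but too variable for one rigid model.  This
package annotates them flexibly, cuts structures into compact rigid
groups for rigid-group refinement, harvests every geometric occurrence of
a template fold from a directory of PDB files into a superposed library,
and relocates a small fragment onto a complete structure even when
general-purpose superposition tools fail on it.

## The core idea

For any peptide window of ≥ 3 residues the **characteristic vector** (CV)
runs from the centroid of the window's Cα atoms to the centroid of its
carbonyl O atoms:

```
CV = centroid(O_i … O_{i+w−1}) − centroid(Cα_i … Cα_{i+w−1}),  w = 3
```

Sliding this tripeptide window along the chain gives a smoothed vector
field whose statistics separate conformations: |CV| ≈ 2.2 Å with
consecutive-CV angles of 5–10° in an α-helix, |CV| ≈ 1.4 Å with 50–55°
in a β-strand.  All pairwise (angle, distance) relations live in a
complete graph; near-diagonal relations encode secondary structure,
cross-fragment relations encode the fold.  Each CV is scored against the
two ideals with a weighted penalty over modulus, neighbour angles and
Cα spacing, and labelled only when the two scores differ by more than a
tunable **strictness** — higher strictness keeps shorter, more ideal
fragments.  Fragments become supernodes of a weighted graph that drives
modularity-based community clustering (decomposition), a CV-matrix
representation drives a recursive, provably complete fold search
(library generation), and a weighted-Kabsch fit with inverse-variance
reweighting and extremity trimming superposes each hit.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Build a synthetic mixed fold (two antiparallel strands packed at sheet
distance plus one helix), make three conformers of it at σ = 0.3 Å
correlated noise, and extract the fold from them as a library:

```bash
cvfold make-fixture --kind mixed --length 10 --out fold.pdb
# ... write perturbed copies into db/ (see cvfold.fixtures.perturb) ...
cvfold generate-library --template fold.pdb --db db --out lib
```

The run reports `library: 3 models`, and the manifest `lib/summary.json`
lists per model:

```
conf0_0_0001.pdb  rmsd=0.461  ss=100%  tt=100%
conf1_0_0002.pdb  rmsd=0.318  ss=100%  tt=100%
conf2_0_0003.pdb  rmsd=0.455  ss=100%  tt=100%
```

`rmsd` is each model's Cα r.m.s.d. to the template after superposition —
well inside the 5 Å acceptance default, as expected for mild conformers
of the same fold.  `ss` and `tt` are the intra-fragment
(secondary-structure) and inter-fragment (tertiary-structure) similarity
percentages against the template matrix; 100% means every compared
(angle, distance) cell fell within the ±15°/±2 Å bands.  File names
follow `pdbid_x_yyyy.pdb`: source file stem, coordinate-model index
(non-zero only for multi-model entries) and a running model id.

The other subcommands follow the same pattern — `cvfold annotate`,
`cvfold decompose`, `cvfold superpose` — each writing its products plus a
JSON `summary.json` manifest; `--help` prints every default.

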