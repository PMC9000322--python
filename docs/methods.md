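# Methods

## The fingerprint

`csfp` implements a keyed 2D fingerprint built from two kinds of chemically
interpretable fragments:

* **ring fragments** sampled from the cores of analogue series (AS) — sets of
  compounds sharing a scaffold and differing only in substituents — and
* **substituent fragments** (R-groups) harvested from bond fragmentation.

Each bit position corresponds 1:1 to one fragment. The default layout is 250
single rings, 250 fused rings, and 500 substituents (1000 bits; rings in the
first half, substituents in the second), each category frequency-ranked with
ties broken by canonical pattern order. The design goal is a *minimalist*
representation: far fewer features per molecule than MACCS (166 keys) or
folded ECFP4 (1024 bits), while remaining competitive in similarity searching
and machine learning.

### Core extraction

Analogue series are found by systematic fragmentation of every combination of
1–5 *exocyclic bonds* — acyclic single bonds between heavy atoms (bonds to
hydrogen are never cut). A combination is admitted when it splits the
molecule into exactly one ring-containing core plus substituents carrying one
attachment point each, with core heavy atoms ≥ 2 × combined substituent heavy
atoms (the 2:1 size ratio). Cores are generalized by hydrogen-capping the
attachment sites; compounds sharing a generalized core form an AS. When one
compound yields several valid cores, all are recorded for library statistics
(a largest-core-only mode is available). Admitted cuts are exactly
invertible: rejoining core and substituents reproduces the parent, which the
test suite uses as a round-trip oracle. A configurable cap on the number of
cuttable bonds (default 25) guards against combinatorial explosion and raises
an explicit capacity error.

### Ring fragmentation and model fragments

Deleting every acyclic bond and atom from a core leaves connected components
of the ring skeleton: components spanning ≥ 2 smallest-set-of-smallest-rings
(SSSR) rings are *fused systems*, the rest single rings. Rings joined by a
single bond (biphenyl) are therefore two singles, not a fused system. Spiro
junctions count as fused by default (configurable), since the rings share an
atom after acyclic-bond deletion.

Fused systems are further decomposed into their SSSR rings. Each product
keeps the aromaticity and bond orders its atoms had in the fused context, so
its pattern still matches that ring inside larger systems. This is encoded by
emitting per-atom SMARTS primitives (element, aromatic/aliphatic flag, formal
charge) with explicit bond symbols, rather than molecule SMILES — the only
way to represent *model fragments* such as the partially aromatic five-ring
of indane, whose electronic state cannot exist in an isolated molecule. A
decomposition product is flagged as a model fragment when its retained state
(any aromatic atom or non-single bond) differs from the perception of its
bare sigma skeleton, which would be a saturated ring; decalin's cyclohexanes
are therefore not model fragments while naphthalene's aromatic six-rings are.
Rings emitted whole from non-fused systems are never flagged. Exocyclic
double-bond atoms (e.g. a ring carbonyl oxygen) are not part of ring
fragments; they remain substituent-side features.

### Substituents

Substituent fragments come from two sources whose counts are merged by
canonical pattern: the single-bond systematic cuts above ("random cut"
source) and a pluggable retrosynthetic cutter, by default single cuts at
RDKit BRICS bonds. Frequencies are counted per occurrence (a substituent
appearing twice in one compound counts twice). Hydrogen and the unsubstituted
benzene ring are excluded — benzene is only allowed as a ring fragment, which
avoids high-frequency ambiguous assignments. Substituent queries encode
per-atom H counts, so an interior CH2 of a recorded fragment never matches a
further-substituted position, while the attachment point is a heavy-atom
wildcard (ring atoms may anchor, maximizing recall of R-group-like features).

### Substructure closure

To guarantee enough bit density for meaningful Tanimoto comparison despite
the small feature count, substructure relationships *between recorded
fragments* are precomputed at assembly time: a fused system maps to the
recorded single rings among its decomposition products, and a substituent
maps to the recorded substituents strictly contained in it (computed
pairwise, then transitively closed; strict-size ordering keeps the relation
acyclic). When a fragment matches a molecule, all its closure descendants are
set as well — e.g. a detected substituent containing two recorded
substituents sets three bits. Closure from fused rings to smaller fused rings
is off by default (configurable). Bits are binary; per-bit provenance records
whether each bit was set directly or through closure.

## Similarity searching

Per trial, 100 actives are sampled from a class: 10 references, 90 potential
hits spiked into a fixed background of decoys. Every database compound is
scored by its maximum Tanimoto coefficient against the references (1-NN) or
the mean of its top-k values (5-NN, 10-NN), and the hit/decoy ranking is
summarized by AUC ROC (Mann–Whitney formulation; ties credited ½; an all-zero
fingerprint pair has Tc 0 by convention). Twenty trials are averaged;
per-trial seeds derive from the master seed. The protocol-scale background is
100,000 compounds; the packaged fixture mode uses 1,000.

## Compound classification

Per trial, a random half of the actives trains the model and the other half
are positive test instances, joined by 3× as many negatives sampled from a
background pool (disjoint train/test negative sets). Hyperparameters are
chosen by stratified 10-fold cross-validation and grid search maximizing mean
balanced accuracy, on training actives plus 3× training negatives. Grids: RF
trees ∈ {25, 50, 100, 200, 400} × min-split ∈ {2, 3, 5, 10} (20 candidates);
SVM C ∈ {0.1, 1, 10, 50, 100, 200, 1000} (7 candidates) with the Tanimoto
kernel and balanced class weights; remaining hyperparameters are scikit-learn
defaults pinned by the library version recorded in run manifests. Metrics are
computed from the confusion matrix:

* BA = (TPR + TNR) / 2
* MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0 when
  any factor vanishes
* F1 = 2TP / (2TP + FP + FN), precision = TP/(TP+FP), recall = TP/(TP+FN)

Paired fingerprint comparisons use the two-sided Wilcoxon signed-rank test;
identical pairs are reported as degenerate (p = 1) with a warning.

## Activity-record curation

The curation stage keeps records with molecular weight < 1000 Da, a direct
target annotation (confidence score 9), an exact potency (relation "="), type
Ki/IC50/Kd, potency ≤ 10 µM (all potencies normalized to nM), and none of the
flags "inactive", "not active", "inconclusive", "potential transcription
error". The potency direction is configurable. Anti-target removal (hERG,
serum albumin, ABC transporters) and assay-interference filtering are
pluggable hooks (an id blacklist and a predicate), not hardcoded chemistry.
Duplicates per (compound, target) collapse to the most potent measurement.
Standardization keeps the largest organic fragment, neutralizes charges, and
canonicalizes; canonicalization is idempotent.

## Synthetic fixtures: what they emulate and what they do not

All tests and the acceptance script run on generated data:

* **Analogue series**: 24 drug-like scaffolds (mostly fused heterocycles —
  quinoline, indole, benzothiazole, benzimidazole, benzodioxole, etc.) with
  two attachment sites, decorated with R-groups from a 22-member pool.
  R-group pairs are constrained so the scaffold stays ≥ 2× the combined
  substituent size — the defining property of a CCR-extractable series —
  making each series' shared core recoverable by construction.
* **Background decoys**: a disjoint scaffold pool (furan, thiophene,
  morpholine, benzothiazole variants, …) with its own R-group pool, emulating
  a random screening database structurally distinct from any series.
* **Fragment catalog**: a combinatorial enumeration of single rings (ring
  sizes 3–8, aromatic and saturated, ≤ 3 heteroatoms, one-double-bond
  variants), fused systems (heteroatom mutations of 12 bicyclic skeletons),
  and substituents (chain/terminal-group grammar), with Zipf-like synthetic
  frequencies. It exists so the full default 250/250/500 assembly is
  exercisable offline.

The fixtures do not emulate: the real frequency spectrum of medicinal
chemistry fragments, activity cliffs, heterogeneous ("difficult") classes
with low scaffold overlap, assay noise, or database-scale backgrounds.
Passing benchmarks therefore demonstrate protocol correctness and the
fingerprint's ability to exploit shared cores — not screening performance on
real compound collections, which depends on library composition derived from
large curated data.

## Problem sizes and numerical choices

The packaged benchmark uses one fixture class of 4 series × 30 analogues
versus 1,000 decoys: 20 search trials (mean 1-NN AUC is reported), 3 SVM and
2 RF classification trials with the full protocol grids, and a 20-trial label
-permutation null with a reduced single-point grid (the null only needs a
fixed estimator). The feature-count comparison uses 1,000 molecules (500
series compounds + 500 decoys) with the library fitted on those same
molecules, mirroring how the reference library is derived from the screened
population. Determinism: every stochastic step derives its seed from a master
seed via `numpy.random.SeedSequence`; tie-breaks are by canonical pattern
order everywhere; library JSON round-trips bit-for-bit.

## Known limitations

* Ring SMARTS do not constrain ring membership beyond connectivity, so a
  saturated ring pattern can in principle match an acyclic chain of the same
  length; in practice library rings are closed cycles, which forces the match
  to be a cycle.
* The exact retrosynthetic rule set behind the published R-group resource is
  not reproduced; BRICS rules stand in behind the same pluggable interface.
* Bridged polycycles are treated by SSSR, so envelope rings of macrocycles
  and some bridged systems are not emitted as separate fragments.
* Substituent frequency counting is per occurrence; per-compound counting
  would change rankings only for fragments repeated within one molecule.
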