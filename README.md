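# csfp — core-substituent fingerprint

`csfp` implements a chemically intuitive, *keyed* 2D molecular fingerprint
built from ring and substituent fragments, together with the benchmark
protocols used to evaluate fingerprints in similarity searching and compound
classification. It is aimed at cheminformaticians and computational medicinal
chemists who want an interpretable, low-density alternative to MACCS keys and
folded ECFP4 — every bit corresponds to one nameable fragment — or a clean
reference implementation of the k-NN search and Tanimoto-kernel SVM / random
forest evaluation protocols.

## The fingerprint

The representation follows a structural-minimalist design. From a compound
collection:

1. **Analogue-series cores.** Every combination of 1–5 exocyclic single bonds
   is cut (CCR-style fragmentation, 2:1 core:substituent heavy-atom ratio);
   compounds sharing a hydrogen-capped generalized core form an analogue
   series, and the cores are sampled as generalizable scaffolds.
2. **Ring fragments.** Deleting acyclic bonds splits each core into fused
   systems and single rings; fused systems are further decomposed into their
   SSSR rings with *retained hybridization states*, so a ring cut from a
   fused system ("model fragment") still matches inside larger ring systems.
3. **Substituents.** R-groups from the same cuts plus a retrosynthetic
   (BRICS) cutter, frequency-ranked; hydrogen and bare benzene are excluded.
4. **Assembly.** The top 250 single rings, 250 fused rings, and 500
   substituents each get one bit (1000 bits total). Substructure relations
   among recorded fragments are precomputed: a matched fused ring also sets
   its recorded decomposition rings, and a matched substituent sets the
   recorded substituents it contains ("substructure closure"), guaranteeing
   workable bit density despite few features.

Similarity is the Tanimoto coefficient Tc(A, B) = |A∧B| / |A∨B|.

## Worked example

```python
import numpy as np
from csfp import (CSFPVectorizer, MACCSVectorizer, ECFPVectorizer,
                  generate_fixture_series, generate_background,
                  compute_csfp, run_trials)

# synthetic study conditions: 4 analogue series x 30 compounds + 1000 decoys
actives = generate_fixture_series(4, 30, seed=3)
decoys = generate_background(1000, seed=4, exclude={a.smiles for a in actives})

vec = CSFPVectorizer().fit(actives + decoys)   # derives the fragment library
print("bits:", vec.n_bits_)

X = vec.transform(actives)
print("median CSFP features:", np.median(X.sum(axis=1)))
print("median MACCS features:",
      np.median(MACCSVectorizer().fit().transform(actives).sum(axis=1)))

v = compute_csfp(actives[0], vec.library_)
print(actives[0].smiles, "->", sorted(v.provenance.items())[:3])

_, mean_auc = run_trials(actives, decoys, vec.transform,
                         k=1, n_trials=20, n_sample=100, seed=9)
print(f"1-NN mean AUC: {mean_auc:.3f}")
```

prints

```
bits: 522
median CSFP features: 7.0
median MACCS features: 40.0
CC(C)N1CCN(c2ccc(C#N)cc2)CC1 -> [(0, ('[#6;a]1:[#6;a]:[#6;a]:[#6;a]:[#6;a]:[#6;a]:1', 'direct')), (11, ('[#6;A]1-[#6;A]-[#7;A]-[#6;A]-[#6;A]-[#7;A]-1', 'direct')), (22, ('*C', 'direct'))]
1-NN mean AUC: 0.959
```

The library fitted on this small synthetic collection holds 522 bits (its
catalogs are smaller than the 250/250/500 default quotas, which a full-size
catalog fills to exactly 1000). The median active compound sets 7 CSFP bits
versus 40 MACCS keys — the intended feature-count reduction — with each bit
traceable to a named fragment (here the benzene and piperazine rings and a
methyl R-group), and the 1-NN benchmark separates the analogue-series class
from the random decoys at mean AUC 0.959.

The same stages are available as a CLI:

```bash
csfp curate --in records.tsv --out curated.tsv --potency-um 10 --mw 1000
csfp cores --in compounds.smi --out cores.tsv --max-cuts 5 --ratio 2.0
csfp build-lib --in compounds.smi --out lib.json
csfp fp --lib lib.json --in mols.smi --out fps.csv
csfp search --actives class.smi --background bg.smi --lib lib.json \
     --fp csfp --k 1,5,10 --trials 20 --seed 42 --out search.tsv
csfp classify --actives class.smi --negatives pool.smi --lib lib.json \
     --fp csfp --model svm --trials 20 --seed 42 --out clf.tsv
```

Every command writes a `.manifest.json` (inputs hashed, config, seed,
version) next to its output; reruns with the same seed are byte-identical.

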