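# distsvm

Distance-indexed symbol-pair features and SVM classifiers for **protein
remote homology detection** — finding evolutionary relatives whose sequence
identity is too low for alignment-based search. The package is aimed at
computational biologists who want position-dependent, explicitly
interpretable feature spaces for family classification: unlike kernel
methods that never materialize their features, every dimension here is a
named (symbol, symbol, distance) triple whose learned weight can be read
off and plotted.

## The representation

Fix the 20-letter amino-acid alphabet Ӑ = (A, R, D, C, Q, E, H, I, G, N, L,
K, M, F, P, S, T, W, Y, V). A sequence S′ over Ӑ is mapped to the count
vector

```
F_dmax(S′) = [ D_0(S′), D_1(S′), …, D_dmax(S′) ]
```

where `D_0` holds the 20 symbol occurrence counts and, for 1 ≤ d ≤ d_max,
`D_d` holds the 400 counts of ordered pairs (t_i, t_j) occurring at
positional offset exactly d (adjacent symbols have d = 1). The dimension is
`20 + 20·20·d_max`, i.e. 60 020 at the default operating point d_max = 150.

Two input channels feed this one construction:

- **DR (sequence-based)** — S′ is the native residue string;
- **DT (profile-based)** — each position is replaced by its **Top-1-gram**,
  the most frequent amino acid of the corresponding column of the protein's
  PSI-BLAST frequency profile, so the vector carries evolutionary
  information.

Per family, a soft-margin linear SVM is trained on unit-L2-normalized
vectors of positive (within-superfamily) and negative training proteins;
test proteins are ranked by the discriminative score and evaluated with
**ROC** (probability a positive outranks a negative) and **ROC50** (area
under the ROC curve truncated at the 50th false positive). For linear
models the discriminant weights are recovered explicitly as **w = Mα**
(training matrix × label-signed dual coefficients), and the importance of
each ordered pair is the L2 norm of its per-distance weights — a 20×20
matrix whose dark spots name the discriminative residue pairs of a family.

## Worked example

Generate two synthetic families whose positives share a planted (G, G)
pair at distance 5, then run the full per-family protocol with the
profile-based (DT) features:

```bash
distsvm simulate --out-dir demo --families 2 --seed 42 \
    --pos-train 20 --neg-train 20 --pos-test 10 --neg-test 10
distsvm benchmark --data-dir demo --mode dt --dmax 10 --out demo/results.tsv
```

which prints

```
mean_roc        0.970000
mean_roc50      0.970000
```

and writes per-family rows (`fam1` ROC 0.94, `fam2` ROC 1.0, unweighted
mean 0.97): the classifier separates held-out family members from
non-members almost perfectly. The same pipeline from Python, plus the
feature-importance analysis:

```python
from distsvm import *
from distsvm.classify import TrainingSet

split = read_split_file("demo/fam1.split")
profiles = {i: read_pssm(f"demo/pssm/{i}.pssm", sequence_id=i)
            for i in split.positive_train + split.negative_train}
vecs = [dt_features(profiles[i], 10)
        for i in split.positive_train + split.negative_train]
model = train_family_classifier(
    TrainingSet.from_vectors(vecs, [1] * 20 + [-1] * 20))

importance = pair_l2_norms(discriminant_weights(model))
print(importance.top_pairs(3))
```

prints

```
[('G', 'G', 2.674904876066545), ('G', 'D', 0.5171162167511016), ('L', 'G', 0.5106884363393417)]
```

— the planted (G, G) pair dominates all 400 ordered pairs by a factor of
five, and its per-distance weight profile
(`pair_distance_profile(..., ("G", "G"))`) peaks at the planted offset
d = 5. On real families the same analysis surfaces conserved sequence
patterns (e.g. glycine-rich motifs) that drive the discrimination.

Input formats: FASTA for sequences, PSI-BLAST ASCII PSSM for profiles (the
percentage block is consumed; a plain L×20 matrix dialect is also
accepted), simple `<id> <role>` split files for family membership, and
SVM-light sparse files for feature vectors.

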