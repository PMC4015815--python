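# Methods

## The model

A protein is represented by the occurrence counts of ordered symbol pairs
at bounded positional offsets. Over the fixed alphabet Ӑ = (A, R, D, C, Q,
E, H, I, G, N, L, K, M, F, P, S, T, W, Y, V), with index 0 = A and
19 = V, the vector

```
F_dmax(S′) = [D_0, D_1, …, D_dmax],   dim = 20 + 400·d_max
```

concatenates the 20-dim composition block (d = 0) with one 400-dim block
per distance d ≥ 1, block d flattened row-major as (first symbol, second
symbol). Pairs are ordered — (a, b) and (b, a) are distinct features — and
the distance is the positional offset j − i, so adjacent symbols have
d = 1. The flat index map is frozen for file-format stability:
`unigram(a) → a`, `pair(a, b, d) → 20 + 400(d−1) + 20a + b`.

The construction is one vectorized pass per distance (O(L·d_max)); its
correctness is pinned by exact integer equality with a naive O(L²) double
loop over all ordered position pairs, in both the unit suite and the
acceptance script.

Two channels feed it. **DR** uses the native residue string. **DT** first
replaces each position by its Top-1-gram — the most frequent amino acid of
the corresponding column of the protein's frequency profile — so the
counts reflect evolutionary preferences rather than the observed residues.
Profiles are consumed as files (PSI-BLAST ASCII PSSM percentage block,
divided by 100 and row-renormalized); computing alignments or profiles is
out of scope.

## Assumptions and conventions

- **Alphabet strictly 20 symbols.** Ambiguity codes (B, Z, X, U, O, and
  other non-standard characters) are masked invalid rather than mapped to a
  21st symbol, because every dimension formula depends on |Ӑ| = 20.
  Invalid positions contribute to no count; pairs spanning them are
  dropped, not bridged. Consequence: for fully valid sequences the vector
  total is exactly L + Σ_d max(0, L−d), a conservation law the tests
  assert.
- **Tie-breaking in profiles.** Equal column frequencies resolve to the
  symbol earliest in alphabet order (stable argsort), so an all-uniform
  column encodes to A. All-zero percentage rows become uniform rows and
  are flagged. Both rules are package conventions chosen for determinism;
  no upstream convention exists to follow.
- **Counts stay raw integers** in the feature module; normalization is a
  classifier concern. This keeps the feature invariants exact.

## Classification

One binary soft-margin SVM per family (scikit-learn's libsvm backend
behind the module surface). Defaults: linear kernel on unit-L2-normalized
count vectors, C = 1.0, dual tolerance 1e-6, and minority-class weight
N_majority/N_minority to survive the heavy class imbalance of family
benchmarks. These defaults are this package's own documented choice; the
historical Gist 2.3 defaults used in early SVM homology work are
unspecified and not reproduced, so absolute scores are not comparable
across implementations — rankings and the recovery properties below are.
Training is deterministic given config and input order; permuting the
training order moves test scores by less than 1e-6 (asserted).

Scores are computed from the stored expansion f(v) = Σ αᵢ yᵢ K(xᵢ, v) + b
rather than delegated, so that the explicit weight vector **w = Mα**
(label-signed α; unsigned coefficients would destroy the identity) exactly
reproduces linear-kernel scores via dot(w, v) + b to 1e-9 — the
consistency oracle that validates the feature-analysis path. An RBF kernel
is available behind a flag; weight pull-back is linear-only.

## Evaluation

ROC is computed by a grouped-trapezoid sweep over descending score groups,
which equals the Mann–Whitney U-statistic with half credit for ties.
ROC50 truncates the same curve at the 50th false positive (linear
interpolation inside a crossing tie group) and normalizes by
n_pos · min(50, n_neg), the standard convention of the family-benchmark
literature; with ≤ 50 negatives ROC50 equals ROC identically. Family
averages are unweighted. Correctness is checked against three independent
routes: direct pair counting, a brute-force threshold-sweep curve, and
scikit-learn's AUC.

## Synthetic data

The generator emulates exactly the structure the method consumes: a family
is an over-represented ordered pair at a characteristic offset (the
skeleton of a conserved motif such as a glycine-rich repeat).

- Positives: i.i.d. background draws (uniform by default) with
  `insertions_per_sequence` planted (a, b) occurrences at the planted
  offset, sites uniform without overlap.
- Negatives: the same number of a and b symbols written at unpaired random
  positions — never forming the planted pair among themselves — so both
  classes share residue composition and the d = 0 block carries no signal.
  Pure-background negatives would leak the planted symbols' composition
  excess into the unigram block and make even d_max below the planted
  offset discriminative, defeating the point of a distance sweep; matching
  composition stress-tests the d ≥ 1 blocks specifically.
- Profiles: each column puts mass `profile_concentration` on the native
  residue and spreads the remainder randomly over the other 19. Above 0.5
  the Top-1-gram channel reproduces the sequence exactly; at 1.0 DT and DR
  vectors are identical (asserted). This is a deliberate simplification —
  it controls the only channel the method reads (per-column argmax) — and
  does not emulate realistic profile noise, correlated columns, indels, or
  phylogenetic structure.

Default family conditions, fixed up front: 30 + 30 training and 15 + 15
test sequences, lengths 80–120, planted pair (G, G) at distance 5, 6
insertions per sequence, concentration 0.9. Sizing rationale: with matched
composition the chance count of (G, G) at offset 5 is ≈ (L−5)·p_G² ≈ 2.8
with Poisson-like variance, against 6 deterministic planted pairs — a
single-feature separation of d′ ≈ 2.6, enough for the SVM to exceed ROC
0.95 with margin while leaving the d_max = 1 classifier at chance.

What passing these tests shows: the pipeline recovers a planted
pair-distance signal end-to-end and attributes it to the correct feature.
What it does not show: performance on real superfamily benchmarks, which
adds profile noise, length variation, homologous negatives and much larger
negative sets.

## Numerical and design notes

- d_max default 150: real-family performance saturates near there while
  dimension grows linearly; small toy runs use d_max ≤ 10 purely because
  their planted signal sits at distance 5.
- Vector length, block nesting (F_k is an exact prefix of F_dmax), and the
  layout bijection are property-tested (hypothesis, seeded).
- Degenerate inputs: single-symbol sequences produce a pure composition
  vector; d ≥ L blocks are zero; the all-zero vector is left unchanged by
  normalization; single-class training sets and one-class score lists are
  rejected with explicit errors.
- Model files are versioned JSON archives storing α, bias, ids, config,
  d_max and the (sparse) training matrix — self-contained for scoring and
  weight analysis.
- The acceptance script's problem sizes (5 seeds, 200 oracle sequences,
  d_max 10) are chosen to make every statistical margin wide at desk
  scale; all randomness flows from one `--seed`.

## Known limitations

- Top-n-gram pairs are restricted to n = 1; general n would multiply the
  alphabet and the dimension.
- No probability calibration; scores are ranking scores only.
- The discriminant analysis assumes the linear kernel; RBF models expose
  no feature-space weights.
- Profile quality control beyond row renormalization is out of scope.
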