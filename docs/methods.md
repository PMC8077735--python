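# Methods

This note records the model, the numerical choices, and what the synthetic
data does and does not establish.

## Problem and model

Carbonylation-site prediction is binary classification of individual K/P/R/T
residues. The pipeline is: peptide-window extraction → DR encoding →
SMOTE-KSU balancing of the training set → Rotation Forest of SVMs →
credibility scoring and thresholding. Each stage is an independent module
with a plain-array interface, so every stage can be exercised (and replaced)
in isolation.

### Window extraction

Windows are `half_width` residues either side of the candidate (default 10,
a 21-residue window). The motif signal in carbonylation logos sits within the
six positions upstream of the site, so the default covers it with margin;
it is exposed in every API and in the CLI. Terminal windows are truncated,
never padded: the DR encoding is defined for any window length, and padding
characters would either invent counts or need the same skip rule 'X' already
has. Positions are 1-based in all files; Python indexing is 0-based
internally and never appears in I/O.

Non-standard residues (B, J, O, U, Z, `*`, …) are normalized to 'X' with a
logged warning. 'X' occupies a position but is skipped by every DR count, so
ambiguous real-world sequences degrade gracefully instead of erroring.

### DR encoding

Block 0 holds the 20 single-residue counts; block d (1 ≤ d ≤ d_MAX ≤ 3) the
400 ordered-pair counts at *exact* separation d. Exact (not bounded)
separation per block is used: blocks are then disjoint counts and satisfy
the conservation identities Σblock0 = L, Σblock_d = L − d for X-free windows,
which the property tests assert under fuzzing. Counts stay raw integers —
frequencies would discard window-length information, and KSU rescales
columns later anyway.

### Balancing (SMOTE-KSU)

The common class size is M = n₁ + N with N = round(k₁n₀ − k₀n₁), k₀ = k₁ = ½.
Rounding is half-away-from-zero; banker's rounding would shift half-integer
targets down by one. The split of N into additions and removals
(additions = M − n₁ = N, removals = n₀ − M) makes the two classes exactly
equal, which is the stated goal of the resampler.

SMOTE: neighbour search is Euclidean in raw DR space (no scaling — the KSU
column normalization applies only inside KSU), k = 5 neighbours by default,
base points cycled round-robin over a shuffled minority so any quota is met
exactly, u ~ Uniform(0,1) per synthetic row. Provenance (base, neighbour, u)
is returned on request and synthetic rows are flagged in the output matrix.

KSU: k-means with k = 6, k-means++ initialization, 10 restarts, seeded.
Within each cluster, columns are divided by their column maximum (an all-zero
column stays zero; a column whose maximum is negative is divided by that
maximum as the formula states — DR features are non-negative so this arises
only for user-supplied matrices). Pair dissimilarity is the squared Euclidean
distance divided by the cluster size n; the 1/n factor is monotone within a
cluster but *does* affect the merged cross-cluster ranking, and is kept as
defined. Removals are not pre-allocated per cluster: a single globally
merged, ascending-sorted pair list (ties broken by cluster index then pair
index, for determinism) is walked, deleting one random member of each pair
whose two members both still survive. If the single pass exhausts the pair
list before the quota — possible with many tiny clusters — the remainder is
removed uniformly at random with a logged warning. Survivors keep their
original order.

### Rotation Forest

Per subclassifier: a seeded random permutation of the feature indices is cut
into K contiguous chunks (the first n mod K chunks one larger). "75% of the
samples randomly and repeatedly extracted" is implemented as a bootstrap:
⌈0.75·n⌉ draws with replacement, independently per subset. PCA loadings are
kept for components with eigenvalue > 1e-9 (`pca_tolerance`); loadings are
not eigenvalue-scaled. A subset whose bootstrap draw has no variance falls
back to an identity block, logged. The block-diagonal matrix is assembled
directly in original-feature row order, which is the re-ordered R_iᵅ.

SVM hyperparameters are not pinned by the procedure the ensemble implements,
so defaults follow common practice: RBF kernel, C = 1, `gamma="scale"`,
Platt-scaled probabilities, all exposed in `RotationForestConfig`. `max_iter`
is capped at 500 000 so that pathological (pure-noise) fits terminate;
converged fits never approach the cap. With K near the feature dimension
(subsets of 1–3 features) the per-subset PCA is still performed — that regime
is a supported operating point, guarded by the identity fallback.

Credibility is the mean positive-class probability over the L members. The
decision rule is `score ≥ threshold` (default 0.5): a sample exactly at the
threshold is called positive.

### Metrics

Sn, Sp, Acc and G-mean are computed literally from the error counts. The MCC
is the ratio form with numerator 1 − (fn/N⁺ + fp/N⁻) and denominator
√((1 + (fp−fn)/N⁺)(1 + (fn−fp)/N⁻)), algebraically identical to the textbook
four-product MCC (property-tested to 1e-12). A `strict_mcc` flag computes the
variant whose numerator is 1 − (fn+fp)/(N⁺+N⁻) — that numerator collapses to
the accuracy and the result is **not** a valid MCC; the flag exists only to
audit legacy reports that printed it. MCC is NaN (not an exception) when a
prediction column is empty, so degenerate classifiers still produce a report.

The AUC is the pairwise comparison count: ties contribute 0 by default, 0.5
under `tie_correction=True` (the Mann-Whitney convention). With continuous
SVM scores the two agree; with discrete scores the default is a downward-
biased AUC, which is why the tie-corrected form is used in tests that score
by integer motif counts.

Metric averaging across folds is the plain arithmetic mean at full precision;
4-decimal rounding is display-only.

### Cross-validation protocol

Stratified k-fold (default 10), seeded. Resampling runs **inside each
training fold** by default (`resample_mode="per_fold"`): balancing before the
split would let SMOTE interpolants of held-out points into the training set.
A `global` mode reproducing the resample-then-split protocol exists and logs
a warning. A training fold that is already balanced or positive-heavy is left
as-is (the balance plan is defined only for a negative majority). Grid cells
with K above the feature dimension are skipped with a notice rather than
failing the run. Selection is by mean MCC, tie-broken by mean AUC, then by
smaller K (cheaper model).

## Synthetic data

`synthdata.generate` draws proteins residue-wise from a background
distribution (uniform 1/20 by default, to keep tests composition-agnostic; a
proteome-like preset is included), plants annotated candidate residues at
spaced positions ≥ 7 residues from the N-terminus, and, for positive sites,
overwrites each motif position with the motif residue with probability θ.
Motif layout per residue type mirrors the observed sequence logos: K at
−6…−1, R at −5…−1, T at −3…−2, P no motif. θ = 0 is an exact null (labels
independent of sequence); θ = 1 saturates the motif.

What this emulates: positional amino-acid enrichment upstream of positive
sites under class imbalance, which is the signal the classifier assumes.
What it does not: homology/redundancy structure between proteins, realistic
secondary-structure or accessibility correlates, composition biases around
negatives, or inter-site dependence. Passing end-to-end tests therefore
demonstrates machinery correctness and signal recovery, not field performance
on curated proteome data.

`generate_feature_blobs` supplies geometry-controlled Gaussian fixtures (5
informative of `dim` coordinates, unit variance, mean shift `separation`)
for resampler and ensemble tests that should not depend on sequence encoding.

## Problem sizes used in the test suite

The end-to-end recovery check runs ten-fold CV on 600 positive / 3,000
negative 21-residue windows at d_MAX = 1 with K = 20 subsets and L = 5 — a
deliberate scale-down of the full grid (d_MAX ∈ {1,2,3}, K ∈ {300…400}, which
is a ~33-cell grid over ~27,000 windows) chosen so the whole suite runs on a
laptop-class single core; the ensemble and protocol code paths are identical
at both scales. Unit and property suites use windows of length ≤ 50 and
feature matrices of ≤ a few hundred rows.

## Known limitations

* Eq-style KSU is O(n²) in the largest cluster's size for pair ranking;
  at the published negative-class sizes (≈27,000) this is minutes and
  gigabytes — acceptable offline, but a k-d-tree or blocked ranking would be
  needed for much larger corpora.
* SVC Platt scaling adds an internal 5-fold CV per member; training cost is
  dominated by it. `probability=True` is slated for deprecation in future
  scikit-learn releases; migrating to `CalibratedClassifierCV` would change
  scores slightly.
* The independent-test protocol on cross-species data (redundancy filtering
  with CD-HIT at 40%/70%/30% identity) is out of scope; users should filter
  homology with CD-HIT before trusting cross-validation estimates on their
  own data.
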