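# Methods

## Problem setting

`dtilink` predicts drug–target interactions (DTIs) transductively: all drugs
and targets are known up front, a subset of interactions is observed in the
binary matrix Mat-int, and the task is to rank the unobserved pairs. The
working hypothesis is the standard similarity principle — drugs similar to
*d* tend to bind targets similar to *t*'s partners — implemented by fusing
each pair's embedding vectors with its nearest neighbors' similarity weights
and interaction profiles, then classifying the fused vectors.

## Knowledge-graph embedding

Entities and relations are embedded with DistMult, the bilinear-diagonal
model `s(h,r,t) = Σ_i h_i r_i t_i`. The score is symmetric in head and
tail, so the model cannot represent anti-symmetric relations; that is
acceptable here because the relations we embed (interaction, similarity,
type membership) are themselves symmetric or type-like.

Trainer choices (all seeded; a seed fully determines the result bitwise):

* **Loss**: binary cross-entropy of `sigmoid(score)`, positives against
  uniform negatives produced by corrupting head or tail (fair coin) and
  resampling up to 10 times if the corruption is itself a known triple.
* **Optimizer**: plain SGD at a fixed learning rate (default 0.05), no
  momentum or adaptive state, so runs are exactly reproducible.
* **Initialization**: uniform in ±0.5/√k from the config seed; `epochs=0`
  returns the initialization, which doubles as the untrained baseline in
  tests.
* **Dimension**: default 400 for full-scale use; tests and the synthetic
  benchmark use 8–16, which is enough to separate a handful of clusters.

Ranking evaluation scores every candidate entity on both the tail side and
the head side and averages reciprocal ranks into MRR plus Hits@{1,3,10}.
Tied scores receive the mean rank of the tied block (unbiased under random
tie order). `filtered` mode removes candidates that would re-create another
known triple; `raw` keeps them. Both modes are exposed because either
convention appears in published link-prediction tables.

## Local features

* **Drugs**: Avalon substructure fingerprints (default 512 bits) from
  SMILES via RDKit, reduced to 64 dimensions. The default reducer is a
  single-hidden-layer autoencoder (linear 64-unit code, sigmoid output,
  mean-squared error, full-batch gradient descent, seeded initialization,
  fixed epoch count); PCA with a deterministic sign convention is offered as
  a drop-in when exact linearity is preferred. The fingerprint length is a
  free parameter — 512 is a conventional middle ground between collision
  rate and width.
* **Proteins**: the 20 standard residues are grouped into non-polar
  {G,A,V,L,I,P,F,M,W}, polar-neutral {S,T,C,Y,N,Q}, acidic {D,E} and basic
  {K,R,H} (textbook polarity classes; a single editable constant). A
  width-3 window slides with step 1; each window maps to one of 4³ = 64
  group-triplets by the positional code `16·g1 + 4·g2 + g3`. Windows
  containing a non-standard residue (X, B, Z, U, O, …) are skipped rather
  than assigned to an arbitrary group. Counts are normalized to frequencies
  by default (so vectors of long and short proteins are comparable); raw
  counts remain available behind a flag. Sequences shorter than 3 give an
  all-zero vector with a logged warning instead of an exception, so one
  fragmentary record cannot abort a batch.

## Embedding providers and alignment

All feature sources return one container, an id → fixed-length-vector
table serialized as delimited text with a dimension header. A protein
language model is wired in as an optional provider (mean pooling over
residue positions by default, CLS pooling optional) that demands locally
stored model assets and the optional torch/transformers dependencies —
library code performs no network access. The seeded mock provider
(standard-normal vectors) stands in wherever an uninformative embedding is
needed, e.g. null comparisons. When drug and target tables come from
different sources at different widths, `pca_align` mean-centers and projects
onto the top principal axes, orienting each axis so its largest-magnitude
loading is positive (removes the SVD sign indeterminacy). Which side to
reduce is the caller's choice; the fusion step only requires equal widths.

## Similarity matrices

Five metrics over embedding rows: cosine; Pearson correlation across vector
coordinates; Euclidean and Manhattan distances mapped to similarities by
`s = 1/(1+d)` (monotone decreasing, bounded in (0,1], keeps the fusion
weights positive); and Jaccard, generalized to Ruzicka `Σ min / Σ max` on
non-negative real vectors, which coincides with set Jaccard on binary
fingerprints. Jaccard on vectors with negative entries raises an error
directing the user to binarize or shift — there is no canonical extension.
Degenerate vectors (zero for cosine, constant for Pearson) get similarity 0
off-diagonal, and the diagonal is forced to exactly 1 for every metric.

## Pair fusion

For a pair (d, t) with the n most similar drugs `D_near` (weights `W_d^z`
from Mat-Sim-DD, anchor always excluded, ties broken by ascending id) and
targets `T_near` likewise:

```
Vd_intg = (Σ_z W_d^z) · vec(d)          Vt_intg = (Σ_z W_t^z) · vec(t)
Vd_test = (Σ_z MatInt[d^z, t]) · vec(t) Vt_test = (Σ_z MatInt[d, t^z]) · vec(d)
pair    = [Vd_intg + Vd_test ‖ Vt_intg + Vt_test]      (length 2k)
```

The default `as-printed` mode applies the summed similarity weights to the
anchor's own vector, which is the fusion formula taken literally; it makes
each side a scalar multiple of the anchor embedding. Because related
bipartite-fusion methods instead weight the *neighbor* embeddings, a
`neighbor-vectors` mode (`Vd_intg = Σ_z W_d^z · vec(d^z)`) is selectable by
one flag; the interaction-count terms keep the cross-anchor vectors in both
modes, since both the equations and their prose description multiply those
anchors. Neither reading is asserted as uniquely correct.

Note an intentional property: `MatInt[d, t]` itself is never read when
fusing (d, t) — only neighbors' rows and columns are — but neighbors'
interaction profiles do encode the training labels, so pair-level
cross-validation of the downstream classifier measures transductive
performance, not inductive generalization to unseen entities. This mirrors
how the method is meant to be used (re-run when entities are added).

## Classifier bank and evaluation

Nine scikit-learn classifiers with fixed per-scenario defaults (scenario =
which feature source built the embeddings: `kge`, `kge-protbert`, or
`local`): random forest (100 trees, balanced class weights), decision tree,
MLP (lbfgs, hidden (5,2) for `kge`, (240,96) otherwise), k-neighbors (7 /
2), bagging over k-neighbors, gradient boosting (learning rate 1.0, depth
1 / 2), Gaussian naive Bayes, SGD logistic (max_iter 5 / 2), and extra
trees. Unstated knobs default to fixed values (tree counts 100, fixed
random states) so every member is deterministic; all are overridable.

Evaluation is stratified 5-fold cross-validation at the pair level, seeded,
with all negatives retained (no subsampling — imbalance is handled by the
per-classifier parameters). Threshold metrics use the 0.5 probability
cut; any zero denominator (precision, recall, F1, MCC) defines the metric
as 0 so reports are total. AUC/AUPR come from the ranking of predicted
probabilities (trapezoidal ROC; step-interpolated precision–recall). The
`relative_gap(a, b) = 100·(a−b)/a` statistic, rounded to two decimals,
expresses by how many percent classifier *b* trails classifier *a* on any
one metric. Novel-candidate ranking excludes known positives and breaks
probability ties by (drug id, target id).

## Synthetic benchmark

The generator emulates the *shape* of a curated DTI gold standard, not its
chemistry or network topology. Drugs and targets are assigned uniformly to
`n_clusters` latent clusters; a pair interacts with probability
`base_rate + signal·1[clusters match]` (clipped to [0,1]). Defaults —
50 drugs × 50 targets, 4 clusters, signal 0.8, base rate 0.05 — give an
interaction density near 0.24 and are the conditions under which the
recovery results below are quoted. The knowledge graph holds one
`interacts_with` triple per observed interaction, within-cluster
`similar_to` edges on both sides, and an `is_a` type triple per entity so
every id is embeddable even if isolated. SMILES are drawn from a frozen
packaged list of 77 valid structures partitioned by cluster (guaranteed
parseable without a chemistry-aware generator); protein sequences (length
120–300) are sampled with the four biochemical-group frequencies perturbed
by ±signal·0.15 per cluster, so the window-3 featurizer also carries the
cluster signal. All randomness flows from one seed through spawned child
streams, one per artifact.

What passing tests show — and do not show: recovering the planted signal
demonstrates that every stage transmits information end to end (embedding →
similarity → fusion → classifier) and that the null configuration is
calibrated near AUC 0.5; it does not demonstrate performance on real
pharmacological data, whose interaction structure is not block-constant and
whose molecular similarity is far subtler than cluster-assigned SMILES.

`end_to_end_recovery` runs the whole chain at reduced problem sizes chosen
to keep a full sweep comfortable on a single CPU: embedding dimension 16,
30 training epochs, cosine similarity, 5 neighbors, 5 folds. Under the
default conditions the random-forest member reaches mean cross-validated
AUC ≈ 0.92 over 5 seeds, falls to ≈ 0.55 with signal 0, and increases
monotonically with signal — numbers the acceptance script recomputes on
every run rather than asserting from this file.

## Numerical and degenerate-input conventions

* Similarity matrices are symmetrized (`(S+Sᵀ)/2`) and the diagonal forced
  to 1 after computation; values are validated finite.
* Ranking ties → mean rank; neighbor ties → ascending id; ranking
  probability ties → ascending (drug, target).
* Triple splits use floor(fraction·N) per split with the remainder to
  train; an empty split with a positive fraction (N ≥ 3) is an error.
* Negative sampling is filtered by default (never emits a known triple); a
  raw flag exists for speed on large graphs.
* Fingerprint reduction pads with zero columns when PCA rank runs out
  before the requested width, keeping output shapes stable.

## Known limitations

* DistMult's head–tail symmetry limits it on directed relations; no
  TransE/TransR-style alternatives are included.
* The `as-printed` fusion collapses each side to a scalar multiple of the
  anchor embedding; whether that or the `neighbor-vectors` reading is more
  informative on real data is dataset-dependent.
* The pipeline is transductive: adding a drug or target requires re-running
  embedding and fusion.
* The synthetic benchmark's SMILES are reused catalog molecules, so the
  fingerprint arm sees repeated structures within a cluster; that is
  deliberate (parseability over realism) but means fingerprint-based
  results on it overstate chemical distinguishability.
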