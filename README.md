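# dtilink

Drug–target interaction (DTI) prediction from knowledge-graph embeddings,
molecular fingerprints and protein sequence composition.

Experimentally validating which drugs bind which protein targets is slow and
expensive, so computational ranking of candidate interactions is a standard
step in drug discovery and repurposing. `dtilink` implements a transductive
pipeline that treats DTI prediction as bipartite link prediction over a
biomedical knowledge graph, packaged so every stage is a plain Python
function over text files and testable on synthetic data.

## The method

Given drugs *D = {d¹ … dⁿ}*, targets *T = {t¹ … tˡ}*, a binary interaction
matrix **Mat-int** ∈ {0,1}ⁿˣˡ and per-entity embedding vectors, the pipeline is:

1. **Embeddings.** Entities of a knowledge graph of ⟨head, relation, tail⟩
   triples are embedded with **DistMult**, the bilinear-diagonal model with
   triple score *s(h,r,t) = Σᵢ hᵢ·rᵢ·tᵢ* (symmetric in *h* and *t*), trained
   by SGD on a binary cross-entropy loss with uniform filtered negative
   sampling. Alternatives plug in behind the same table interface: local
   features (Avalon fingerprints of SMILES reduced to 64 dimensions by a
   seeded autoencoder or PCA; length-64 group-triplet composition vectors of
   protein sequences computed with a width-3 sliding window over four
   biochemical residue classes), precomputed tables, a protein language
   model, or a seeded mock. PCA alignment brings tables to a shared width.
2. **Similarities.** Drug–drug (*Mat-Sim-DD*) and target–target
   (*Mat-Sim-TT*) matrices under cosine, Pearson, Euclidean (1/(1+d)),
   Manhattan (1/(1+d)) or Jaccard (Ruzicka Σmin/Σmax) similarity.
3. **Pair fusion.** For each pair (dⁱ, tʲ), with *Dⁿᵉᵃʳ*/*Tⁿᵉᵃʳ* the n most
   similar drugs/targets:
   *Vd_intg* = (Σ_z W_d^z)·dⁱ, *Vt_intg* = (Σ_z W_t^z)·tʲ,
   *Vd_test* = (Σ_z Mat-int[d^z, tʲ])·tʲ, *Vt_test* = (Σ_z Mat-int[dⁱ, t^z])·dⁱ;
   the pair embedding is [*Vd_intg* + *Vd_test* ‖ *Vt_intg* + *Vt_test*],
   length 2k.
4. **Classification.** All n·l pairs with labels y = Mat-int form the
   dataset; a bank of nine classifiers (random forest, decision tree, MLP,
   k-neighbors, bagging, gradient boosting, Gaussian naive Bayes, SGD,
   extra trees) is evaluated by stratified cross-validation with AUPR, AUC,
   ACC, MCC, F1, precision and recall, and novel candidates are ranked by
   predicted interaction probability with known positives excluded.

A seeded synthetic benchmark with planted drug/target clusters exercises the
whole chain without any external download; see `docs/methods.md` for the
model details and design choices.

## Worked example

```python
from dtilink import BenchmarkParams, PipelineConfig, end_to_end_recovery

params = BenchmarkParams(n_drugs=50, n_targets=50, n_clusters=4,
                         signal=0.8, base_rate=0.05, seed=1)
report = end_to_end_recovery(params, PipelineConfig(classifier="rf"))
print(f"pairs scored:        {report.n_pairs}")
print(f"cross-validated AUC: {report.auc:.3f}")
print(f"top-10 precision:    {report.top_k_precision:.2f}")
```

prints

```
pairs scored:        2500
cross-validated AUC: 0.923
top-10 precision:    1.00
```

2500 is every drug × target pair; the AUC says the random-forest member
separates interacting from non-interacting pairs almost perfectly when 80%
planted cluster signal is present (with no signal it falls to ≈0.5); the
top-10 precision says all ten highest-probability novel pairs fall in
matching drug/target clusters, i.e. they are the planted (but unobserved)
positives.

The same chain is scriptable from a shell:

```bash
dtilink simulate  --out-dir run/data --seed 1
dtilink embed-kg  --out-dir run/emb --triples run/data/triples.tsv --dimension 16 --epochs 30
dtilink similarity --out-dir run/sim --embeddings run/emb/entities.tsv --metric cosine
dtilink fuse      --out-dir run/fused --interactions run/data/interactions.tsv \
                  --drug-embeddings run/emb/entities.tsv --target-embeddings run/emb/entities.tsv \
                  --sim-dd run/sim/similarity_cosine.tsv --sim-tt run/sim/similarity_cosine.tsv
dtilink evaluate  --out-dir run/eval --pairs run/fused/pairs.tsv \
                  --interactions run/data/interactions.tsv --classifier rf
dtilink rank      --out-dir run/rank --pairs run/fused/pairs.tsv \
                  --interactions run/data/interactions.tsv --top-k 10
```

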