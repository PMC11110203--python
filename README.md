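# plaquekg

Association mining between coronary-artery plaque types and clinical symptom
phenotypes on a heterogeneous clinical–molecular knowledge graph.

Coronary CT angiography distinguishes calcified, noncalcified and mixed
plaque, but the symptoms patients report — chest pain, dyspnea, fatigue,
dizziness — are mostly nonspecific. `plaquekg` is for researchers who want to
quantify which symptom phenotypes associate with which plaque type and which
genes mediate the link, by fusing three evidence layers into one graph:

* a **clinical co-occurrence network**: symptoms and plaque types are nodes;
  two items are linked when they appear in the same patient, weighted by the
  number of such patients;
* **annotation gene sets** linking each symptom and plaque to its known
  molecular targets (GMT files);
* a **protein–protein interaction network** (STRING-style scored edge list,
  retained at combined score ≥ 400).

## Method

For every (symptom *s*, plaque *t*) pair the package computes three feature
channels:

1. **Network topology** — Dijkstra shortest-path length *d(s, t)* over the
   fused graph, plus a point-to-network value *e(s)*: the Euclidean distance
   between *s*'s vector of path lengths to all plaques and the centroid of
   those vectors over all symptoms.
2. **Correlation quantization** — Apriori lift
   `supp(s ∧ t) / (supp(s) · supp(t))` over patient transactions, and a score
   distilled from a small CNN trained on per-patient symptom × plaque lift
   matrices to predict the patient's plaque labels.
3. **Biological similarity** — Wang-measure GO-style semantic similarity
   between the two gene sets, combined by best-match average.

Labels come from **random walk with restart** (`p ← (1−r)·W·p + r·p0`) seeded
at each plaque node: the top fraction *q* of symptoms by stationary score are
positives. A **k-nearest-neighbor** classifier (k = 6, stratified 10-fold
cross-validation) is evaluated in three configurations — A: all channels,
B: topology + correlation, C: similarity only — and pairs scoring ≥ 0.5
out-of-fold are retained as association rules, pooling their annotation genes
as hub-gene candidates. Those genes feed a weighted-correlation network
analysis (soft-threshold power β, |cor|^β adjacency, topological-overlap
clustering, module eigengenes, eigengene–trait Pearson correlation),
hypergeometric term enrichment (raw p < 0.05), and expression-signature ROC
validation on labeled case/control matrices.

A bundled synthetic-data generator emulates every input with planted
associations, a scale-free interactome, association-correlated annotations
and planted co-expression modules, so the whole pipeline runs and is tested
without any external download.

## Worked example

```bash
python examples/04_knn_ablation.py
```

```
KNN-A cross-validated AUC: 0.970
KNN-B cross-validated AUC: 0.972
KNN-C cross-validated AUC: 0.625
selected association rules: 16
precision vs planted truth: 1.00, recall: 1.00
```

On a simulated 2000-patient cohort with 16 planted symptom–plaque
associations, the full-channel model separates RWR-positive from negative
pairs almost perfectly (AUC 0.97), semantic similarity alone is much weaker
(0.63), and the 16 rules retained at the 0.5 score cutoff are exactly the
planted pairs. `examples/` contains one script per capability (simulation,
feature channels, RWR labeling, ablation, module detection, enrichment and
validation, full pipeline); the same stages are scriptable as
`plaquekg simulate|graph|features|label|model|modules|enrich|validate|all
--out DIR`.

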