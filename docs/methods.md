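# Methods

This note documents the models and procedures implemented in `plaquekg`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## The knowledge graph

Three node kinds (symptom, plaque, gene; namespaces kept disjoint by
internal `sym:`/`plq:`/`gene:` tags) and three undirected edge kinds:

* **co-occurrence** (symptom/plaque ↔ symptom/plaque), weight = number of
  patients containing both endpoints; a patient contributes at most one
  count per pair, and patients with no symptoms still contribute to plaque
  support counts;
* **annotation** (symptom/plaque ↔ gene) from GMT gene sets;
* **interaction** (gene ↔ gene) with an integer confidence score; edges
  below 400 are rejected at parse time (`read_ppin` reports the dropped
  count) and again at fusion time.

Shortest paths and the random walk need a positive traversal length per
edge. Nothing in the problem dictates one, so the defaults are monotone
transforms of the evidence strength, recorded in the run manifest and
overridable (`EdgeLengths`):

| edge kind | length | rationale |
|---|---|---|
| co-occurrence | `1 / ln(1 + weight)` | more shared patients ⇒ shorter |
| interaction | `1 − score/1000 + 0.001` | higher confidence ⇒ shorter; the 0.001 floor keeps lengths positive at score 1000 |
| annotation | `1.0` | uninformative prior |

A `unit` mode sets every length to 1 for sensitivity analyses, since it is
not documented practice whether clinical edge weights should influence
fusion-level distances.

## Feature channels

**Topology.** `topo_dist` is the Dijkstra length from symptom to plaque
(point-to-point). The point-to-network value `topo_euclid` embeds each
symptom as its vector of path lengths to the three plaque nodes and takes
the Euclidean distance to the centroid of all symptom vectors; it measures
how atypical a symptom's plaque-proximity profile is. Unreachable entries
are replaced by twice the maximum finite length before profiling
(configurable); a fully disconnected symptom is flagged.

**Association.** Lift treats each patient as one transaction over symptom
and plaque items; supports are fractions of all records. Lift of a pair
that never co-occurs is 0; lift involving a zero-support item is undefined
and returned as NaN (never 0, to keep "independent" and "undefined"
distinct). Per-patient association matrices hold the global symptom × plaque
lift grid with rows of absent symptoms zeroed, so all matrices share one
shape and differ only through the patient's symptom set.

**CNN correlation value.** The correlation-quantization model is a
deliberately small convolutional network over the patient matrices —
conv 3×3 (8 filters, ReLU) → conv 3×3 (16, ReLU) → global average pool →
dense → 3 sigmoid outputs — trained full-batch with Adam on binary
cross-entropy against the patient's multi-label plaque vector. It is
implemented directly on numpy (im2col convolutions, manual backprop,
float32); training is a pure function of the seed. Defaults: 200 epochs,
learning rate 0.03 (the smallest rate that saturates training accuracy on a
small-cohort overfit check within the epoch budget while remaining stable
at cohort scale), and a training subsample cap of 512 patients so full-batch
epochs stay tractable on one CPU; prediction always covers every patient.
Distilling a patient-level model into a pair-level value is underdetermined;
the implemented contrast is the mean predicted probability of plaque *t*
over patients exhibiting symptom *s* minus the mean over patients not
exhibiting it, min-max rescaled to [0, 1] over all pairs (a flat grid maps
to 0.5). The contrast-of-means choice is recorded in the manifest.

**Semantic similarity.** The Wang measure propagates a semantic
contribution down ancestor paths: S_A(A) = 1 and
S_A(t) = max over children c in the path of w(edge) · S_A(c), with
w(is_a) = 0.8 and w(part_of) = 0.6 (the measure's conventional defaults).
Term similarity is Σ(S_A + S_B) over shared ancestors divided by
SV(A) + SV(B); genes combine over their term sets and sets over their gene
pairs by best-match average. Unannotated genes are dropped with a warning;
two fully unannotated sets are an error rather than a silent 0. A
shared-ancestor-depth measure (`resnik_depth_sim`) is provided as a cheap
alternative.

## Labeling and classification

The random walk with restart uses edge affinity = 1/length, column
normalized; iteration `p ← (1−r)·W·p + r·p0` from a uniform seed
distribution, restart probability r = 0.7, L1 tolerance 1e−10, at most
10 000 sweeps (common practice; the choice of r matters little for ranking
here). Mass that reaches an isolated node is returned to the seeds so the
scores remain a probability distribution.

Per-plaque labels take the top ⌈q·S⌉ symptoms by walk score (lexicographic
tie-break). The default positive fraction is **q = 0.15, matching the
planted association density of the default study conditions**: the positive
fraction is effectively the label prior, and setting it far above the true
association rate would make the majority of positive labels false pairs by
construction, bounding the precision of any downstream selection at roughly
density/q regardless of model quality. q is configurable; on real data it
should be set near the expected association prevalence.

The KNN scorer returns the fraction of the k = 6 nearest training pairs
(Euclidean metric) labeled positive, with distance ties broken by training
row index. Channels are z-scored inside each training fold only (no
leakage). Cross-validation is stratified 10-fold with a shared seed across
the three named configurations (A = topology + association + similarity,
B = topology + association, C = similarity only) so ablations share folds.
AUC is the Mann–Whitney rank statistic with half-credit on ties, computed
on pooled out-of-fold scores. The classification unit is the
(symptom, plaque) pair — the natural unit given that the output of interest
is a set of pair rules — and the classifier interface accepts any object
with `fit`/`predict`, so externally supplied alternatives (boosted trees,
Bayesian networks) can be compared without being part of this package.

## Module analysis

The patient × gene coefficient matrix sets entry (p, g) to the sum over p's
symptoms of relevance(s, g), where relevance(s, g) is the mean out-of-fold
score of the pairs (s, ·) whose pooled annotation genes contain g. This is
one defensible reading of "model coefficients per item"; a plain
annotation-indicator weighting is available as a fallback by passing
constant scores.

Module detection follows unsigned weighted-correlation-network practice:
adjacency |cor|^β; topological overlap
TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
ℓ_ij = Σ_{u≠i,j} a_iu·a_uj; average-linkage clustering on 1 − TOM; a static
cut; clusters below `min_size` (default 5) fall into module 0 (grey);
surviving modules are relabeled by decreasing size so labels are invariant
to gene input order, and exported under the conventional color ladder
(turquoise, blue, brown, …; grey = unassigned). The static cut height
defaults to **0.98**: merge heights of TOM gene trees concentrate just
below 1 even for tight modules (a module with within-correlation ~0.6 at
β = 6 has within-module TOM near 0.05), so cuts far from 1 shred everything
into singletons; 0.98 sits where within-module merges complete and
between-module merges have not. Dynamic tree cut is out of scope.

The soft-threshold power is the smallest β in 1..20 whose signed scale-free
fit R² (log10 p(k) vs log10 k on 10 connectivity bins, slope required
negative) reaches 0.8. When no power reaches the target — typical for
strongly block-structured matrices, whose degree distribution is bimodal
rather than scale-free and whose R² curve rises slowly and monotonically in
β — the chooser does **not** take the argmax (which runs to the top of the
grid and dissolves real modules) but falls back to the published
sample-count recommendation for unsigned networks: 9 below 20 samples, 8
below 30, 7 below 40, else 6.

Module eigengenes are the first principal component of the z-scored module
columns, sign-oriented to correlate positively with the member genes on
average. Eigengene–trait association uses Pearson r with the two-sided
p-value from t = r·√((n−2)/(1−r²)), n ≥ 3 required.

## Enrichment and validation

Enrichment is the exact upper-tail hypergeometric probability P(X ≥ k)
computed by log-binomial summation; one result per term with overlap ≥ 1,
sorted by p. The default significance flag is raw p < 0.05 with no
multiple-testing correction — matching how such screens are commonly
reported — with Benjamini–Hochberg available by flag.

Group-level log fold change is not a per-sample quantity, and a ROC needs
per-sample scores; the signature score is therefore the mean z-scored
expression over the module's genes, whose sample ranking is what a
logFC-weighted score would also produce for a coherently shifted module.
AUC reuses the rank statistic; label inversion maps AUC to 1 − AUC and any
strictly monotone transform of scores leaves it unchanged.

## Synthetic data

The generator plants every signal the pipeline is supposed to detect, at
the scale of a ~1500-patient single-center registry:

* plaque labels are independent Bernoulli per type (calcified 0.45,
  noncalcified 0.35, mixed 0.25 — about 27% of patients carry no plaque,
  with calcified most common, as in such cohorts); exclusivity is
  deliberately not imposed;
* symptom s is present with probability logistic(α + β·#true partners
  present), α = −2 (baseline prevalence ~12%), β = 2; true pairs are drawn
  at density 0.15 of the symptom × plaque grid. Additivity on the logit
  scale is the simplest joint model that makes lift, walk proximity and
  semantic similarity all informative at once;
* the interactome is a preferential-attachment graph (3 stubs per new gene)
  with uniform integer scores in [400, 1000], so the confidence filter is a
  pass-through on generated data and is exercised against sub-threshold
  scores in fixtures;
* for each true pair the plaque's gene set preferentially samples the 1-hop
  interactome neighborhood of the symptom's genes (2-hop, then uniform, as
  fallbacks with a warning) — in a scale-free graph the 2-hop neighborhood
  of ten genes already covers most of the network, so wider sampling would
  erase the planted proximity signal;
* each symptom owns an ontology "theme" (a random internal term of a
  rooted is_a/part_of DAG of configured depth and branching); the symptom's
  genes and the plaque genes borrowed from its neighborhood draw 1–2 terms
  from the theme's subtree, direct interactome neighbors get light (15%)
  spillover, and every gene carries at least one background term;
* expression: genes share a module latent factor (loading √0.6, so
  within-module correlation ≈ 0.6, typical of co-expression modules, and
  clearly above between-module correlation ≈ 0); module 1 genes are shifted
  by `module_shift` (default 2 s.d.) in case samples; 100 samples (50/50).

Every generator is a pure function of (config, seed); sub-generators derive
their streams from the global seed plus fixed stage offsets, and identical
configs reproduce output files byte-for-byte. Because the OBO format
carries no gene links, gene→term annotations are written as an additional
`annotations.gmt` (term → genes) next to `ontology.obo`, and expression
labels as a `expression_labels.tsv` sidecar.

What the generator does **not** emulate: free-text EMR symptom mentions or
vocabulary normalization, realistic RNA-seq count distributions (Gaussian
suffices for the rank-based downstream statistics), correlated plaque
comorbidity, or database-realistic annotation noise. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
planted signals under the stated model, not performance on hospital data.

## Problem sizes and numerical notes

The default study sizes (2000 patients for association recovery, 300 genes,
100 expression samples, 5 replicate seeds) are chosen so a full replicate
study runs in well under a minute on a single CPU while keeping planted
signals comfortably above sampling noise. Degenerate inputs fail loudly:
zero-variance gene columns, single-class training labels, sub-threshold
interaction scores, empty universes, cyclic ontologies and non-convergent
walks all raise named errors rather than propagating NaNs. Reported
tolerances: walk convergence at L1 1e−10 (scores conserve probability to
1e−12 per sweep); oracle equivalence tests compare at 1e−8 or tighter.
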