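"""Synthetic cohort, interactome, annotation and expression generators.

The generators emulate the five input classes of the plaque–symptom
association pipeline — an EMR-style patient table, symptom and plaque gene
sets, a STRING-like protein interaction network, an OBO-lite ontology with
gene annotations, and labeled case/control expression matrices — with the
statistical structure the downstream analysis assumes:

* a planted set of true (symptom, plaque) associations that raise symptom
  probability on the logit scale when the plaque is present;
* plaque gene sets drawn from the <=2-hop interactome neighborhood of their
  true-partner symptom's genes, so true pairs sit closer in the network and
  share more ontology terms;
* planted co-expression modules sharing a latent factor, with module 1
  shifted in cases so a signature ROC has signal.

Every generator is a pure function of (config, seed); sub-generators derive
their streams from the global seed plus fixed stage offsets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .graphio import (
    PLAQUE_LABELS,
    OntologyDAG,
    PatientRecord,
    write_gmt,
    write_obo,
    write_ppin,
    write_records,
)

# fixed per-stage offsets for deriving independent streams from one seed
_STAGE_OFFSET = {"cohort": 101, "ppin": 202, "annotations": 303, "expression": 404}


def _rng(cfg: "GeneratorConfig", stage: str) -> np.random.Generator:
    return np.random.default_rng(cfg.seed + _STAGE_OFFSET[stage])


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with defaults mirroring the cohort scale
    of a ~1500-patient coronary CT angiography registry with 35 standardized
    symptoms and three plaque types."""

    n_patients: int = 1498
    n_symptoms: int = 35
    plaque_prevalence: dict = field(
        default_factory=lambda: {"calcified": 0.45, "noncalcified": 0.35, "mixed": 0.25}
    )
    base_symptom_logit: float = -2.0
    effect_size: float = 2.0
    true_pair_density: float = 0.15
    n_genes: int = 300
    genes_per_symptom: int = 10
    genes_per_plaque: int = 15
    ontology_depth: int = 4
    ontology_branching: int = 3
    n_expression_samples: int = 100
    n_planted_modules: int = 4
    module_shift: float = 2.0
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_patients": self.n_patients,
            "n_symptoms": self.n_symptoms,
            "n_genes": self.n_genes,
            "genes_per_symptom": self.genes_per_symptom,
            "genes_per_plaque": self.genes_per_plaque,
            "ontology_depth": self.ontology_depth,
            "ontology_branching": self.ontology_branching,
            "n_expression_samples": self.n_expression_samples,
            "n_planted_modules": self.n_planted_modules,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        for label, p in self.plaque_prevalence.items():
            if label not in PLAQUE_LABELS:
                raise ValueError(f"unknown plaque label {label!r}")
            if not 0.0 < p < 1.0:
                raise ValueError(f"plaque prevalence for {label} must be in (0,1), got {p}")
        if not 0.0 < self.true_pair_density < 1.0:
            raise ValueError(f"true_pair_density must be in (0,1), got {self.true_pair_density}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")

    @property
    def symptoms(self) -> list:
        return [f"S{i:02d}" for i in range(1, self.n_symptoms + 1)]

    @property
    def genes(self) -> list:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """Planted structure: true pairs, module membership and the gene sets."""

    true_pairs: set
    planted_modules: dict
    symptom_gene_sets: dict = field(default_factory=dict)
    plaque_gene_sets: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_pairs": sorted(list(p) for p in self.true_pairs),
            "planted_modules": self.planted_modules,
            "symptom_gene_sets": {k: sorted(v) for k, v in self.symptom_gene_sets.items()},
            "plaque_gene_sets": {k: sorted(v) for k, v in self.plaque_gene_sets.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_pairs={tuple(p) for p in d["true_pairs"]},
            planted_modules=d["planted_modules"],
            symptom_gene_sets={k: set(v) for k, v in d["symptom_gene_sets"].items()},
            plaque_gene_sets={k: set(v) for k, v in d["plaque_gene_sets"].items()},
        )


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(cfg: GeneratorConfig) -> tuple[list, GroundTruth]:
    """Draw the patient table and the planted (symptom, plaque) associations.

    Each plaque type is an independent Bernoulli with its prevalence (a
    patient may carry several plaque types or none).  Symptom ``s`` is then
    present with probability ``logistic(alpha + beta * #true partners present)``.
    """
    rng = _rng(cfg, "cohort")
    symptoms = cfg.symptoms
    plaques = list(PLAQUE_LABELS)

    all_pairs = [(s, t) for s in symptoms for t in plaques]
    n_true = int(round(cfg.true_pair_density * len(all_pairs)))
    idx = rng.choice(len(all_pairs), size=n_true, replace=False)
    true_pairs = {all_pairs[i] for i in idx}

    prev = np.array([cfg.plaque_prevalence.get(t, 0.0) for t in plaques])
    # beta bump per symptom: matrix [n_symptoms, n_plaques]
    bump = np.zeros((len(symptoms), len(plaques)))
    for i, s in enumerate(symptoms):
        for j, t in enumerate(plaques):
            if (s, t) in true_pairs:
                bump[i, j] = cfg.effect_size

    records = []
    for k in range(cfg.n_patients):
        present = rng.random(len(plaques)) < prev
        logits = cfg.base_symptom_logit + bump[:, present].sum(axis=1)
        has_sym = rng.random(len(symptoms)) < _logistic(logits)
        records.append(
            PatientRecord(
                patient_id=f"P{k + 1:05d}",
                symptoms=frozenset(np.array(symptoms)[has_sym]),
                plaques=frozenset(np.array(plaques)[present]),
                covariates={},
            )
        )

    truth = GroundTruth(true_pairs=true_pairs, planted_modules=planted_module_map(cfg))
    return records, truth


def planted_module_map(cfg: GeneratorConfig) -> dict:
    """Deterministic round-robin assignment of every gene to a planted module."""
    k = cfg.n_planted_modules
    return {g: 1 + i % k for i, g in enumerate(cfg.genes)}


def generate_ppin(cfg: GeneratorConfig) -> list:
    """Scale-free (preferential attachment) interactome with STRING-like scores.

    Returns sorted ``(gene1, gene2, score)`` edges; scores are uniform
    integers in [400, 1000] so the confidence filter passes everything the
    generator emits.
    """
    if cfg.n_genes < 3:
        raise ValueError("n_genes must be >= 3 for an interaction network")
    rng = _rng(cfg, "ppin")
    m = min(3, cfg.n_genes - 1)
    g = nx.barabasi_albert_graph(cfg.n_genes, m, seed=int(rng.integers(2**31)))
    genes = cfg.genes
    edges = []
    for u, v in sorted(g.edges()):
        a, b = sorted((genes[u], genes[v]))
        edges.append((a, b, int(rng.integers(400, 1001))))
    return sorted(edges)


def _neighborhood(graph: nx.Graph, seeds: set, hops: int) -> set:
    hood = set(seeds)
    frontier = set(seeds)
    for _ in range(hops):
        frontier = {n for f in frontier for n in graph.neighbors(f)} - hood
        hood |= frontier
    return hood


def _build_ontology(cfg: GeneratorConfig, rng: np.random.Generator) -> OntologyDAG:
    """Rooted DAG: a b-ary tree of the configured depth plus sparse extra
    part_of edges between sibling branches (keeps it a DAG)."""
    root = "T:root"
    terms = {root}
    parents: dict = {root: []}
    levels = [[root]]
    counter = 0
    for depth in range(1, cfg.ontology_depth + 1):
        level = []
        for parent in levels[-1]:
            for _ in range(cfg.ontology_branching):
                counter += 1
                t = f"T:{counter:04d}"
                terms.add(t)
                parents[t] = [(parent, "is_a")]
                level.append(t)
        levels.append(level)
    # occasional part_of cross-links to a random term one level up
    for level_idx in range(2, len(levels)):
        for t in levels[level_idx]:
            if rng.random() < 0.15:
                p = levels[level_idx - 1][int(rng.integers(len(levels[level_idx - 1])))]
                if (p, "is_a") not in parents[t]:
                    parents[t].append((p, "part_of"))
    return OntologyDAG(terms=terms, parents=parents, roots={root})


def generate_annotations(
    cfg: GeneratorConfig, ppin_edges: list, truth: GroundTruth
) -> tuple[dict, dict, OntologyDAG]:
    """Symptom/plaque gene sets plus an annotated ontology.

    Symptom sets are uniform draws from the interactome.  For each true pair
    (s, t), the plaque set preferentially samples the 1-hop interactome
    neighborhood of the symptom's genes (2-hop, then uniform, as fallbacks),
    which shortens graph distances for true pairs.  Each symptom owns an
    ontology "theme" (a random internal term); its genes — and the plaque
    genes borrowed from its neighborhood — are annotated from that theme's
    subtree, so true pairs also share more terms.  Updates ``truth`` in
    place with the generated sets.
    """
    rng = _rng(cfg, "annotations")
    graph = nx.Graph()
    graph.add_nodes_from(cfg.genes)
    graph.add_edges_from((a, b) for a, b, _s in ppin_edges)
    genes = np.array(cfg.genes)

    symptom_sets = {}
    for s in cfg.symptoms:
        pick = rng.choice(len(genes), size=min(cfg.genes_per_symptom, len(genes)), replace=False)
        symptom_sets[s] = set(genes[pick])

    plaque_sets: dict = {}
    borrowed_from: dict = {s: set() for s in cfg.symptoms}  # symptom -> plaque genes drawn near it
    partners = {t: sorted(s for (s, tt) in truth.true_pairs if tt == t) for t in PLAQUE_LABELS}
    for t in PLAQUE_LABELS:
        chosen: set = set()
        if partners[t]:
            n_linked = max(1, int(round(0.7 * cfg.genes_per_plaque)))
            per_symptom = max(1, n_linked // len(partners[t]))
            for s in partners[t]:
                hood = sorted(_neighborhood(graph, symptom_sets[s], hops=1))
                if len(hood) < per_symptom:
                    hood = sorted(_neighborhood(graph, symptom_sets[s], hops=2))
                if len(hood) < per_symptom:
                    warnings.warn(
                        f"neighborhood of symptom {s} too small; falling back to uniform sampling"
                    )
                    hood = sorted(genes)
                pick = rng.choice(len(hood), size=per_symptom, replace=False)
                drawn = {hood[i] for i in pick}
                chosen |= drawn
                borrowed_from[s] |= drawn
        while len(chosen) < min(cfg.genes_per_plaque, len(genes)):
            chosen.add(genes[int(rng.integers(len(genes)))])
        plaque_sets[t] = chosen

    dag = _build_ontology(cfg, rng)
    # theme-based gene annotations: each symptom owns a random internal term;
    # its genes (and plaque genes borrowed from its neighborhood) draw terms
    # from that theme's subtree, with light spillover to direct neighbors
    children = dag.children()

    def descendants(term):
        out, stack = set(), [term]
        while stack:
            for c, _rel in children[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    internal = sorted(t for t in dag.terms if children[t] and t not in dag.roots)
    annotations: dict = {g: set() for g in cfg.genes}

    def tag(g, pool, n_max=2):
        for _ in range(1 + int(rng.integers(n_max))):
            annotations[g].add(pool[int(rng.integers(len(pool)))])

    for s in cfg.symptoms:
        theme = internal[int(rng.integers(len(internal)))] if internal else next(iter(dag.roots))
        pool = sorted(descendants(theme) | {theme})
        for g in sorted(symptom_sets[s] | borrowed_from[s]):
            tag(g, pool)
        for g in sorted(_neighborhood(graph, symptom_sets[s], hops=1) - symptom_sets[s]):
            if rng.random() < 0.15:
                tag(g, pool, n_max=1)
    all_terms = sorted(dag.terms - dag.roots)
    for g in cfg.genes:  # background annotation so no gene is term-free
        if not annotations[g]:
            annotations[g].add(all_terms[int(rng.integers(len(all_terms)))])
    dag.annotations = annotations

    truth.symptom_gene_sets = symptom_sets
    truth.plaque_gene_sets = plaque_sets
    return symptom_sets, plaque_sets, dag


def generate_expression(cfg: GeneratorConfig, truth: GroundTruth):
    """Gene x sample expression with planted co-expression modules.

    Genes of a module load on a shared latent factor (within-module Pearson
    correlation ~0.6, higher than between-module); module 1 genes are shifted
    by ``module_shift`` standard deviations in case samples.

    Returns ``(matrix [n_genes, n_samples], gene_ids, sample_labels)`` with
    labels 1 = case, 0 = control (first half cases).
    """
    if cfg.n_planted_modules < 1:
        raise ValueError("n_planted_modules must be >= 1")
    rng = _rng(cfg, "expression")
    genes = cfg.genes
    n, m = len(genes), cfg.n_expression_samples
    labels = np.zeros(m, dtype=int)
    labels[: m // 2] = 1

    modules = truth.planted_modules or planted_module_map(cfg)
    module_ids = sorted(set(modules.values()))
    factors = rng.standard_normal((len(module_ids), m))
    loading = np.sqrt(0.6)
    noise_sd = np.sqrt(1.0 - 0.6)

    X = np.empty((n, m))
    for i, g in enumerate(genes):
        mod = modules[g]
        f = factors[module_ids.index(mod)]
        X[i] = loading * f + noise_sd * rng.standard_normal(m)
        if mod == module_ids[0]:
            X[i] += cfg.module_shift * labels
    return X, list(genes), labels


def write_expression(X, genes, labels, path, labels_path) -> None:
    import pandas as pd

    samples = [f"samp{j + 1:03d}" for j in range(X.shape[1])]
    pd.DataFrame(X, index=genes, columns=samples).to_csv(path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": samples, "label": labels}).to_csv(labels_path, sep="\t", index=False)


def simulate_to_dir(cfg: GeneratorConfig, outdir) -> GroundTruth:
    """Run all generators and write the full input bundle to ``outdir``.

    Files: records.tsv, ppin.tsv, symptoms.gmt, plaques.gmt, ontology.obo,
    annotations.gmt (term -> genes), expression.tsv (+ labels sidecar),
    truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_cohort(cfg)
    ppin = generate_ppin(cfg)
    symptom_sets, plaque_sets, dag = generate_annotations(cfg, ppin, truth)
    X, genes, labels = generate_expression(cfg, truth)

    write_records(records, outdir / "records.tsv")
    write_ppin(ppin, outdir / "ppin.tsv")
    write_gmt(symptom_sets, outdir / "symptoms.gmt")
    write_gmt(plaque_sets, outdir / "plaques.gmt")
    write_obo(dag, outdir / "ontology.obo")
    term_to_genes: dict = {}
    for g, terms in dag.annotations.items():
        for t in terms:
            term_to_genes.setdefault(t, set()).add(g)
    write_gmt(term_to_genes, outdir / "annotations.gmt")
    write_expression(X, genes, labels, outdir / "expression.tsv", outdir / "expression_labels.tsv")
    truth.to_json(outdir / "truth.json")
    (outdir / "config.json").write_text(json.dumps(asdict(cfg), indent=1, sort_keys=True))
    return truth
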