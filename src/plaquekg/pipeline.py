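"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages (each resumable from the previous stage's files in the run directory):

    simulate -> graph -> features -> label -> model -> modules -> enrich -> validate

A single YAML config with per-stage sections drives a run; the manifest
records the config snapshot, seeds, input checksums, per-stage counts and
library versions, so an identical re-run reproduces the exact stages
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graphio import (
    PLAQUE_LABELS,
    EdgeLengths,
    build_clinical_network,
    fuse_graph,
    read_annotations,
    read_gmt,
    read_obo,
    read_ppin,
    read_records,
    write_graph,
)
from .syndata import (
    GeneratorConfig,
    generate_annotations,
    generate_cohort,
    generate_ppin,
    simulate_to_dir,
)
from .features import build_patient_matrices, lift_table, pair_feature_table
from .cnn import cnn_pair_scores, train_cnn
from .labeling import DEFAULT_POSITIVE_FRACTION, DEFAULT_RESTART, label_pairs
from .assocmodel import ModelConfig, run_ablation, select_associations
from .netmodules import coefficient_matrix, detect_modules, module_trait, pick_soft_threshold
from .downstream import enrich, signature_roc

STAGES = ("simulate", "graph", "features", "label", "model", "modules", "enrich", "validate")


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},           # GeneratorConfig overrides
    "graph": {"min_score": 400, "unit_lengths": False},
    "features": {"cnn_epochs": 200, "cnn_lr": 0.03},
    "label": {"r": DEFAULT_RESTART, "q": DEFAULT_POSITIVE_FRACTION},
    "model": {"k_neighbors": 6, "folds": 10, "score_cutoff": 0.5},
    "modules": {"betas": list(range(1, 21)), "cut_height": 0.98, "min_size": 5},
    "enrich": {"alpha": 0.05, "correction": None},
    "validate": {},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    loaded = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
    for src in (loaded, overrides or {}):
        for key, val in src.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if cfg["model"]["folds"] < 2:
        raise ConfigError("model.folds must be >= 2")
    if cfg["model"]["k_neighbors"] < 1:
        raise ConfigError("model.k_neighbors must be >= 1")
    if not 0 < cfg["label"]["q"] < 1:
        raise ConfigError("label.q must be in (0, 1)")
    if not 0 < cfg["label"]["r"] <= 1:
        raise ConfigError("label.r must be in (0, 1]")
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config sections {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(outdir: Path, name: str, stage: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(f"missing {name}; re-run stage '{stage}' first")
    return p


class PipelineRun:
    """Stateful pipeline over a run directory; each stage writes its files."""

    def __init__(self, outdir, config: dict | None = None):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = config or load_config()
        self.manifest = {
            "config": self.config,
            "seed": self.config["seed"],
            "versions": {"plaquekg": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__, "networkx": nx.__version__},
            "stages": {},
            "checksums": {},
        }

    # -- stages -------------------------------------------------------------

    def simulate(self):
        gen_cfg = GeneratorConfig(**{"seed": self.config["seed"], **self.config["simulate"]})
        truth = simulate_to_dir(gen_cfg, self.outdir)
        self._log("simulate", n_true_pairs=len(truth.true_pairs),
                  n_patients=gen_cfg.n_patients, n_genes=gen_cfg.n_genes)
        return truth

    def graph(self):
        records = read_records(_require(self.outdir, "records.tsv", "simulate"))
        symptom_sets = read_gmt(_require(self.outdir, "symptoms.gmt", "simulate"))
        plaque_sets = read_gmt(_require(self.outdir, "plaques.gmt", "simulate"))
        ppin, dropped = read_ppin(_require(self.outdir, "ppin.tsv", "simulate"),
                                  min_score=self.config["graph"]["min_score"])
        clinical = build_clinical_network(records)
        lengths = EdgeLengths(unit=self.config["graph"]["unit_lengths"])
        kg = fuse_graph(clinical, symptom_sets, plaque_sets, ppin, lengths)
        write_graph(clinical, self.outdir / "clinical_network.tsv")
        write_graph(kg, self.outdir / "knowledge_graph.tsv")
        self._log("graph", clinical_nodes=clinical.number_of_nodes(),
                  clinical_edges=clinical.number_of_edges(),
                  kg_nodes=kg.number_of_nodes(), kg_edges=kg.number_of_edges(),
                  ppin_edges_dropped=dropped)
        return kg, clinical, records, symptom_sets, plaque_sets

    def features(self):
        kg, _clinical, records, symptom_sets, plaque_sets = self.graph()
        dag = read_obo(_require(self.outdir, "ontology.obo", "simulate"))
        dag.annotations = read_annotations(_require(self.outdir, "annotations.gmt", "simulate"))
        symptoms = sorted(symptom_sets)
        plaques = list(PLAQUE_LABELS)
        lifts = lift_table(records, symptoms, plaques)
        matrices = build_patient_matrices(records, lifts)
        plaque_y = np.array([[t in r.plaques for t in plaques] for r in records], dtype=float)
        model = train_cnn(matrices, plaque_y,
                          epochs=self.config["features"]["cnn_epochs"],
                          lr=self.config["features"]["cnn_lr"],
                          seed=self.config["seed"])
        cnn_scores = cnn_pair_scores(model, matrices, records, symptoms, plaques)
        rows = pair_feature_table(kg, records, symptoms, plaques,
                                  symptom_sets, plaque_sets, dag, cnn_scores)
        rows.to_csv(self.outdir / "features.tsv", sep="\t", index=False)
        self._log("features", n_pairs=len(rows))
        return rows, kg, records, symptom_sets, plaque_sets

    def label(self):
        rows, kg, records, symptom_sets, plaque_sets = self.features()
        labels = label_pairs(kg, list(PLAQUE_LABELS), symptoms=sorted(symptom_sets),
                             r=self.config["label"]["r"], q=self.config["label"]["q"])
        rows["label"] = [labels[(r.symptom, r.plaque)] for r in rows.itertuples()]
        rows.to_csv(self.outdir / "labeled_features.tsv", sep="\t", index=False)
        self._log("label", n_positive=int(rows["label"].sum()), n_pairs=len(rows))
        return rows, records, symptom_sets, plaque_sets

    def model(self):
        rows, records, symptom_sets, plaque_sets = self.label()
        cfg = ModelConfig(k_neighbors=self.config["model"]["k_neighbors"],
                          folds=self.config["model"]["folds"], seed=self.config["seed"])
        reports = run_ablation(rows, cfg)
        pairs, genes = select_associations(reports["A"], self.config["model"]["score_cutoff"],
                                           symptom_sets, plaque_sets)
        out = {
            "auc": {name: rep.mean_auc for name, rep in reports.items()},
            "fold_aucs": {name: rep.fold_aucs for name, rep in reports.items()},
            "roc": {name: {"fpr": rep.roc_fpr.tolist(), "tpr": rep.roc_tpr.tolist()}
                    for name, rep in reports.items()},
            "selected_pairs": sorted(list(p) for p in pairs),
            "selected_genes": sorted(genes),
            "n_symptoms_selected": len({s for s, _ in pairs}),
        }
        (self.outdir / "model_report.json").write_text(json.dumps(out, indent=1))
        reports["A"].pair_scores.to_csv(self.outdir / "pair_scores.tsv", sep="\t", index=False)
        self._log("model", n_rules=len(pairs), n_hub_genes=len(genes),
                  auc_a=out["auc"]["A"], auc_b=out["auc"]["B"], auc_c=out["auc"]["C"])
        return reports, pairs, genes, rows, records, symptom_sets, plaque_sets

    def modules(self):
        reports, pairs, genes, rows, records, symptom_sets, plaque_sets = self.model()
        gene_list = sorted(genes) if genes else sorted({g for s in symptom_sets.values() for g in s})
        m, traits = coefficient_matrix(records, reports["A"].pair_scores,
                                       symptom_sets, plaque_sets, gene_list)
        keep = m.columns[m.std(axis=0) > 0]
        m = m[keep]
        sft = pick_soft_threshold(m, self.config["modules"]["betas"])
        assignment = detect_modules(m, sft.beta,
                                    cut_height=self.config["modules"]["cut_height"],
                                    min_size=self.config["modules"]["min_size"])
        module_trait(assignment, traits)
        m.to_csv(self.outdir / "coefficient_matrix.tsv", sep="\t")
        out = {
            "beta": assignment.beta,
            "modules": {str(mid): assignment.module_genes(mid) for mid in assignment.modules},
            "colors": {str(mid): assignment.color_of(mid) for mid in assignment.modules},
            "grey": assignment.module_genes(0),
            "trait_correlation": assignment.trait_correlation.to_dict() if assignment.trait_correlation is not None else {},
            "trait_pvalues": assignment.trait_pvalues.to_dict() if assignment.trait_pvalues is not None else {},
        }
        (self.outdir / "modules.json").write_text(json.dumps(out, indent=1))
        self._log("modules", beta=assignment.beta, n_modules=len(assignment.modules),
                  n_grey=len(assignment.module_genes(0)))
        return assignment, genes

    def enrich(self):
        assignment, _genes = self.modules()
        annotation = {t: set(g) for t, g in read_gmt(_require(self.outdir, "annotations.gmt", "simulate")).items()}
        universe = set().union(*annotation.values())
        results = {}
        for mid in assignment.modules:
            query = set(assignment.module_genes(mid)) & universe
            if not query:
                results[mid] = []
                continue
            results[mid] = enrich(query, annotation, universe,
                                  alpha=self.config["enrich"]["alpha"],
                                  correction=self.config["enrich"]["correction"])
        rows = [
            {"module": mid, "term": r.term, "overlap": r.k, "term_size": r.K,
             "query_size": r.n, "universe": r.N, "p": r.p, "significant": r.significant}
            for mid, rs in results.items() for r in rs
        ]
        pd.DataFrame(rows).to_csv(self.outdir / "enrichment.tsv", sep="\t", index=False)
        self._log("enrich", n_significant=sum(r["significant"] for r in rows), n_tests=len(rows))
        return results, assignment

    def validate(self):
        _results, assignment = self.enrich()
        expr = pd.read_csv(_require(self.outdir, "expression.tsv", "simulate"),
                           sep="\t", index_col="gene")
        labels = pd.read_csv(_require(self.outdir, "expression_labels.tsv", "simulate"),
                             sep="\t")["label"].to_numpy()
        rocs = {}
        for mid in assignment.modules:
            gene_set = set(assignment.module_genes(mid)) & set(expr.index)
            if not gene_set:
                continue
            roc = signature_roc(expr, labels, gene_set)
            rocs[mid] = {"auc": roc.auc, "n_genes": len(gene_set),
                         "color": assignment.color_of(mid)}
        (self.outdir / "validation.json").write_text(json.dumps(rocs, indent=1))
        self._log("validate", **{f"auc_module_{mid}": v["auc"] for mid, v in rocs.items()})
        return rocs

    # -- orchestration ------------------------------------------------------

    def run_all(self) -> dict:
        self.simulate()
        rocs = self.validate()  # validate pulls the whole chain
        self._finalize()
        return self.manifest

    def run_stage(self, stage: str):
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
        result = getattr(self, stage)()
        self._finalize()
        return result

    def _log(self, stage: str, **counts) -> None:
        self.manifest["stages"][stage] = counts

    def _finalize(self) -> None:
        for p in sorted(self.outdir.glob("*.tsv")) + sorted(self.outdir.glob("*.gmt")):
            self.manifest["checksums"][p.name] = _sha256(p)
        (self.outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))


def run_pipeline(outdir, config: dict | None = None) -> dict:
    """Run every stage on a fresh simulated dataset; returns the manifest."""
    return PipelineRun(outdir, config).run_all()


def run_association_study(
    gen_cfg: GeneratorConfig,
    q: float = DEFAULT_POSITIVE_FRACTION,
    folds: int = 10,
    k_neighbors: int = 6,
    cnn_epochs: int = 200,
    score_cutoff: float = 0.5,
) -> dict:
    """In-memory simulate -> features -> labels -> KNN ablation -> selection.

    Returns the ablation reports, the selected pairs/genes, the planted
    ground truth and the precision/recall of the selection against it.
    Convenient for studies that do not need the file-based stage outputs.
    """
    records, truth = generate_cohort(gen_cfg)
    ppin = generate_ppin(gen_cfg)
    symptom_sets, plaque_sets, dag = generate_annotations(gen_cfg, ppin, truth)
    clinical = build_clinical_network(records)
    kg = fuse_graph(clinical, symptom_sets, plaque_sets, ppin)
    symptoms = sorted(symptom_sets)
    plaques = list(PLAQUE_LABELS)
    lifts = lift_table(records, symptoms, plaques)
    matrices = build_patient_matrices(records, lifts)
    plaque_y = np.array([[t in r.plaques for t in plaques] for r in records], dtype=float)
    model = train_cnn(matrices, plaque_y, epochs=cnn_epochs, seed=gen_cfg.seed)
    cnn_scores = cnn_pair_scores(model, matrices, records, symptoms, plaques)
    rows = pair_feature_table(kg, records, symptoms, plaques,
                              symptom_sets, plaque_sets, dag, cnn_scores)
    labels = label_pairs(kg, plaques, symptoms=symptoms, q=q)
    rows["label"] = [labels[(r.symptom, r.plaque)] for r in rows.itertuples()]
    reports = run_ablation(rows, ModelConfig(k_neighbors=k_neighbors, folds=folds,
                                             seed=gen_cfg.seed))
    pairs, genes = select_associations(reports["A"], score_cutoff, symptom_sets, plaque_sets)
    tp = pairs & truth.true_pairs
    return {
        "reports": reports,
        "rows": rows,
        "selected_pairs": pairs,
        "selected_genes": genes,
        "truth": truth,
        "records": records,
        "clinical_network": clinical,
        "precision": len(tp) / len(pairs) if pairs else 0.0,
        "recall": len(tp) / len(truth.true_pairs) if truth.true_pairs else 0.0,
    }
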