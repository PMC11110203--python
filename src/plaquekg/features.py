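"""Per-pair feature channels: network topology, association lift, semantic similarity.

For every (symptom, plaque) pair the pipeline computes

* ``topo_dist`` — Dijkstra shortest-path length between the symptom and the
  plaque in the fused knowledge graph (point-to-point topology value);
* ``topo_euclid`` — Euclidean distance between the symptom's vector of
  shortest-path lengths to all plaques and the centroid of those vectors
  over all symptoms (point-to-network value);
* ``lift`` — Apriori-style lift of the pair over the patient transactions;
* ``cnn_score`` — a correlation value distilled from a CNN trained on
  per-patient lift matrices (see :mod:`plaquekg.cnn`);
* ``semsim`` — Wang-measure best-match-average similarity of the two gene
  sets' ontology annotations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphio import OntologyDAG, PatientRecord, plq, sym

WANG_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


# ---------------------------------------------------------------------------
# Network topology channel
# ---------------------------------------------------------------------------

def shortest_paths(kg: nx.Graph, source: str) -> dict:
    """Single-source Dijkstra over the ``length`` edge attribute.

    Unreachable nodes map to ``math.inf``.
    """
    if source not in kg:
        raise KeyError(f"unknown source node {source!r}")
    dist = nx.single_source_dijkstra_path_length(kg, source, weight="length")
    return {n: dist.get(n, math.inf) for n in kg.nodes}


def symptom_profiles(kg: nx.Graph, symptoms: Sequence[str], plaque_ids: Sequence[str]):
    """Shortest-path profile of every symptom to every plaque node.

    Infinite distances are replaced by twice the maximum finite length over
    the whole profile table (configurable downstream); returns
    ``(profiles [S, P], raw distances [S, P])``.
    """
    if not plaque_ids:
        raise ValueError("plaque_ids must be non-empty")
    raw = np.empty((len(symptoms), len(plaque_ids)))
    for j, t in enumerate(plaque_ids):
        dist = shortest_paths(kg, plq(t))
        for i, s in enumerate(symptoms):
            raw[i, j] = dist.get(sym(s), math.inf)
    finite = raw[np.isfinite(raw)]
    cap = 2.0 * finite.max() if finite.size else 1.0
    profiles = np.where(np.isfinite(raw), raw, cap)
    return profiles, raw


def topo_features(
    kg: nx.Graph, symptom: str, plaque_ids: Sequence[str], symptoms: Sequence[str] | None = None
) -> tuple[dict, float]:
    """Topology channel for one symptom.

    Returns ``(per-plaque shortest-path lengths, point-to-network value)``
    where the latter is the Euclidean distance between this symptom's
    profile and the centroid of all symptoms' profiles.
    """
    symptoms = list(symptoms) if symptoms is not None else sorted(
        {n.split(":", 1)[1] for n, d in kg.nodes(data=True) if d.get("kind") == "symptom"}
    )
    profiles, raw = symptom_profiles(kg, symptoms, plaque_ids)
    i = symptoms.index(symptom)
    if not np.isfinite(raw[i]).any():
        warnings.warn(f"symptom {symptom} disconnected from all plaques")
    centroid = profiles.mean(axis=0)
    euclid = float(np.linalg.norm(profiles[i] - centroid))
    dists = {t: float(profiles[i, j]) for j, t in enumerate(plaque_ids)}
    return dists, euclid


def topo_feature_table(kg: nx.Graph, symptoms: Sequence[str], plaque_ids: Sequence[str]) -> pd.DataFrame:
    """Topology channel for all (symptom, plaque) pairs at once."""
    profiles, _raw = symptom_profiles(kg, symptoms, plaque_ids)
    centroid = profiles.mean(axis=0)
    euclid = np.linalg.norm(profiles - centroid, axis=1)
    rows = []
    for i, s in enumerate(symptoms):
        for j, t in enumerate(plaque_ids):
            rows.append({"symptom": s, "plaque": t, "topo_dist": profiles[i, j], "topo_euclid": euclid[i]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Association-rule channel
# ---------------------------------------------------------------------------

def _items(record: PatientRecord) -> set:
    return set(record.symptoms) | set(record.plaques)


def association_stats(records: Sequence[PatientRecord], item_a: str, item_b: str) -> dict:
    """Support, confidence and lift of the pair over patient transactions.

    Supports are fractions of all records; a patient is one transaction.
    Lift of a zero-support item is undefined and reported as NaN.
    """
    n = len(records)
    if n == 0:
        raise ValueError("empty record list")
    na = sum(1 for r in records if item_a in _items(r))
    nb = sum(1 for r in records if item_b in _items(r))
    nab = sum(1 for r in records if item_a in _items(r) and item_b in _items(r))
    supp_a, supp_b, supp_ab = na / n, nb / n, nab / n
    if na == 0 or nb == 0:
        return {"support_a": supp_a, "support_b": supp_b, "support_ab": supp_ab,
                "confidence": math.nan, "lift": math.nan}
    return {
        "support_a": supp_a,
        "support_b": supp_b,
        "support_ab": supp_ab,
        "confidence": supp_ab / supp_a,
        "lift": supp_ab / (supp_a * supp_b),
    }


def lift(records: Sequence[PatientRecord], item_a: str, item_b: str) -> float:
    return association_stats(records, item_a, item_b)["lift"]


def lift_table(records: Sequence[PatientRecord], symptoms: Sequence[str], plaques: Sequence[str]) -> pd.DataFrame:
    """Symptom x plaque grid of lift values (NaN-free: undefined lifts -> 0)."""
    counts_items = [list(_items(r)) for r in records]
    n = len(records)
    tbl = np.zeros((len(symptoms), len(plaques)))
    count = {x: 0 for x in list(symptoms) + list(plaques)}
    pair = np.zeros_like(tbl)
    for items in counts_items:
        present_s = [i for i, s in enumerate(symptoms) if s in items]
        present_p = [j for j, t in enumerate(plaques) if t in items]
        for i in present_s:
            count[symptoms[i]] += 1
        for j in present_p:
            count[plaques[j]] += 1
        for i in present_s:
            for j in present_p:
                pair[i, j] += 1
    for i, s in enumerate(symptoms):
        for j, t in enumerate(plaques):
            if count[s] and count[t]:
                tbl[i, j] = (pair[i, j] / n) / ((count[s] / n) * (count[t] / n))
    return pd.DataFrame(tbl, index=list(symptoms), columns=list(plaques))


@dataclass
class AssociationMatrix:
    """One patient's symptom x plaque lift grid, zeroed on absent symptoms."""

    patient_id: str
    matrix: np.ndarray  # [n_symptoms, n_plaques]


def build_patient_matrices(
    records: Sequence[PatientRecord], lifts: pd.DataFrame
) -> list[AssociationMatrix]:
    """Per-patient association matrices over the full symptom x plaque grid.

    Rows of symptoms the patient does not exhibit are identically zero; the
    grid dimensions are fixed across patients.
    """
    base = lifts.to_numpy(dtype=float)
    out = []
    for r in records:
        mask = np.array([s in r.symptoms for s in lifts.index], dtype=float)
        out.append(AssociationMatrix(r.patient_id, base * mask[:, None]))
    return out


# ---------------------------------------------------------------------------
# Semantic-similarity channel (Wang measure, best-match average)
# ---------------------------------------------------------------------------

def wang_svalues(term: str, dag: OntologyDAG, weights: Mapping[str, float] = WANG_EDGE_WEIGHTS) -> dict:
    """Semantic contribution S_term(t) of every ancestor t of ``term``.

    S of the term itself is 1; walking upward, each ancestor receives the
    maximum over its children-in-path of (edge weight x child's S value).
    """
    if term not in dag.terms:
        raise KeyError(f"unknown term {term!r}")
    s = {term: 1.0}
    # relax upward until stable; DAG is small so repeated sweeps are fine
    changed = True
    while changed:
        changed = False
        for child in list(s):
            for parent, rel in dag.parents.get(child, []):
                cand = weights.get(rel, 0.0) * s[child]
                if cand > s.get(parent, 0.0) + 1e-15:
                    s[parent] = cand
                    changed = True
    return s


def term_similarity(t1: str, t2: str, dag: OntologyDAG) -> float:
    """Wang similarity of two ontology terms."""
    s1 = wang_svalues(t1, dag)
    s2 = wang_svalues(t2, dag)
    shared = set(s1) & set(s2)
    denom = sum(s1.values()) + sum(s2.values())
    if denom == 0:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / denom


def _bma(sim: np.ndarray) -> float:
    """Best-match average of a similarity matrix."""
    if sim.size == 0:
        return 0.0
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (sim.shape[0] + sim.shape[1]))


class SemanticSimilarity:
    """Wang-measure set similarity with term- and gene-level caching."""

    def __init__(self, dag: OntologyDAG, weights: Mapping[str, float] = WANG_EDGE_WEIGHTS):
        self.dag = dag
        self.weights = dict(weights)
        self._svalues: dict = {}
        self._term_sim: dict = {}
        self._gene_sim: dict = {}

    def _sv(self, term: str) -> dict:
        if term not in self._svalues:
            self._svalues[term] = wang_svalues(term, self.dag, self.weights)
        return self._svalues[term]

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key not in self._term_sim:
            s1, s2 = self._sv(t1), self._sv(t2)
            shared = set(s1) & set(s2)
            denom = sum(s1.values()) + sum(s2.values())
            self._term_sim[key] = sum(s1[t] + s2[t] for t in shared) / denom if denom else 0.0
        return self._term_sim[key]

    def gene_sim(self, g1: str, g2: str) -> float:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        if key not in self._gene_sim:
            ts1 = sorted(self.dag.annotations.get(g1, ()))
            ts2 = sorted(self.dag.annotations.get(g2, ()))
            mat = np.array([[self.term_sim(a, b) for b in ts2] for a in ts1]).reshape(len(ts1), len(ts2))
            self._gene_sim[key] = _bma(mat)
        return self._gene_sim[key]

    def set_sim(self, set_a, set_b) -> float:
        """Best-match-average similarity between two gene sets in [0, 1]."""
        if not set_a or not set_b:
            raise ValueError("gene sets must be non-empty")
        ann = self.dag.annotations
        a = sorted(g for g in set_a if ann.get(g))
        b = sorted(g for g in set_b if ann.get(g))
        if len(a) < len(set_a) or len(b) < len(set_b):
            warnings.warn("dropping unannotated genes from semantic similarity")
        if not a or not b:
            raise ValueError("both gene sets are fully unannotated; similarity undefined")
        mat = np.array([[self.gene_sim(x, y) for y in b] for x in a])
        return _bma(mat)


def semsim(set_a, set_b, dag: OntologyDAG) -> float:
    """Wang best-match-average similarity of two gene sets (convenience form)."""
    return SemanticSimilarity(dag).set_sim(set_a, set_b)


def resnik_depth_sim(t1: str, t2: str, dag: OntologyDAG) -> float:
    """Alternative term measure: shared-ancestor depth, normalized by max depth.

    Depth of a term is the longest upward path to a root; similarity is the
    deepest common ancestor's depth over the deeper of the two terms' depths.
    """
    def depth(t):
        best = 0
        stack = [(t, 0)]
        while stack:
            node, d = stack.pop()
            ps = dag.parents.get(node, [])
            if not ps:
                best = max(best, d)
            for p, _ in ps:
                stack.append((p, d + 1))
        return best

    common = (dag.ancestors(t1) | {t1}) & (dag.ancestors(t2) | {t2})
    if not common:
        return 0.0
    dmax = max(depth(t1), depth(t2))
    if dmax == 0:
        return 1.0
    return max(depth(c) for c in common) / dmax


# ---------------------------------------------------------------------------
# Assembled feature rows
# ---------------------------------------------------------------------------

def pair_feature_table(
    kg: nx.Graph,
    records: Sequence[PatientRecord],
    symptoms: Sequence[str],
    plaques: Sequence[str],
    symptom_sets: Mapping,
    plaque_sets: Mapping,
    dag: OntologyDAG,
    cnn_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (symptom, plaque) pair with all feature channels.

    ``cnn_scores`` (same index/columns layout as the lift table) is merged
    if provided; otherwise the column is filled with 0.5 (uninformative).
    """
    topo = topo_feature_table(kg, symptoms, plaques).set_index(["symptom", "plaque"])
    lifts = lift_table(records, symptoms, plaques)
    simmer = SemanticSimilarity(dag)
    rows = []
    for s, t in itertools.product(symptoms, plaques):
        sim = simmer.set_sim(symptom_sets[s], plaque_sets[t])
        cnn = float(cnn_scores.loc[s, t]) if cnn_scores is not None else 0.5
        rows.append(
            {
                "symptom": s,
                "plaque": t,
                "topo_dist": float(topo.loc[(s, t), "topo_dist"]),
                "topo_euclid": float(topo.loc[(s, t), "topo_euclid"]),
                "lift": float(lifts.loc[s, t]),
                "cnn_score": cnn,
                "semsim": sim,
            }
        )
    return pd.DataFrame(rows)
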