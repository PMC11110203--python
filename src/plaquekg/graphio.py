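"""Readers, writers and graph construction for the clinical-molecular knowledge graph.

The package models three node kinds — clinical symptoms, coronary plaque
types (calcified / noncalcified / mixed) and genes — and three edge kinds:

* ``cooccurrence``: symptom/plaque pairs observed in the same patient,
  weighted by the number of patients sharing both;
* ``annotation``: symptom→gene and plaque→gene links from curated gene sets;
* ``interaction``: STRING-style protein–protein edges with a combined
  confidence score, retained at score >= 400.

Node identifiers from the three namespaces are kept disjoint by tagging them
internally (``sym:``, ``plq:``, ``gene:``) so a gene symbol can never collide
with a symptom name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

PLAQUE_LABELS = ("calcified", "noncalcified", "mixed")

SYM_PREFIX = "sym:"
PLQ_PREFIX = "plq:"
GENE_PREFIX = "gene:"


def sym(name: str) -> str:
    """Tag a symptom identifier with its namespace prefix."""
    return name if name.startswith(SYM_PREFIX) else SYM_PREFIX + name


def plq(name: str) -> str:
    return name if name.startswith(PLQ_PREFIX) else PLQ_PREFIX + name


def gene(name: str) -> str:
    return name if name.startswith(GENE_PREFIX) else GENE_PREFIX + name


def strip_ns(node: str) -> str:
    """Remove the namespace tag from an internal node id."""
    for p in (SYM_PREFIX, PLQ_PREFIX, GENE_PREFIX):
        if node.startswith(p):
            return node[len(p):]
    return node


class FormatError(ValueError):
    """A file violated the expected format (with line context where known)."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: symptom set, plaque labels and optional lab covariates."""

    patient_id: str
    symptoms: frozenset
    plaques: frozenset
    covariates: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        bad = self.plaques - set(PLAQUE_LABELS)
        if bad:
            raise ValueError(f"unknown plaque labels {sorted(bad)} for patient {self.patient_id}")


@dataclass
class EdgeLengths:
    """Traversal lengths per edge kind used by shortest paths and RWR.

    More co-occurrence means a shorter clinical edge; higher interaction
    confidence means a shorter molecular edge.  A small floor keeps all
    lengths strictly positive.  ``unit`` mode ignores weights entirely.
    """

    annotation: float = 1.0
    interaction_floor: float = 0.001
    unit: bool = False

    def cooccurrence(self, weight: float) -> float:
        if self.unit:
            return 1.0
        return 1.0 / math.log(1.0 + weight)

    def interaction(self, score: float) -> float:
        if self.unit:
            return 1.0
        return 1.0 - score / 1000.0 + self.interaction_floor


# ---------------------------------------------------------------------------
# Patient record TSV
# ---------------------------------------------------------------------------

def read_records(path) -> list[PatientRecord]:
    """Read a patient-record TSV.

    Expected header: ``patient_id<TAB>symptoms<TAB>plaques[<TAB>covariate...]``
    with semicolon-separated symptom and plaque fields.  Empty symptom or
    plaque fields yield empty sets; unknown plaque labels are rejected with
    the offending line number.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["patient_id", "symptoms", "plaques"]:
            raise FormatError(f"{path}: bad header {header[:3]!r}")
        cov_names = header[3:]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            pid, sym_field, plq_field = fields[0], fields[1], fields[2]
            symptoms = frozenset(s for s in sym_field.split(";") if s)
            plaques_raw = [p for p in plq_field.split(";") if p]
            bad = [p for p in plaques_raw if p not in PLAQUE_LABELS]
            if bad:
                raise FormatError(f"{path}:{lineno}: unknown plaque label(s) {bad}")
            try:
                covs = {n: float(v) for n, v in zip(cov_names, fields[3:])}
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric covariate: {exc}") from None
            records.append(PatientRecord(pid, symptoms, frozenset(plaques_raw), covs))
    return records


def write_records(records: Sequence[PatientRecord], path) -> None:
    path = Path(path)
    cov_names = sorted({n for r in records for n in r.covariates})
    with path.open("w") as fh:
        fh.write("\t".join(["patient_id", "symptoms", "plaques"] + cov_names) + "\n")
        for r in records:
            row = [
                r.patient_id,
                ";".join(sorted(r.symptoms)),
                ";".join(sorted(r.plaques)),
            ] + [repr(float(r.covariates.get(n, 0.0))) for n in cov_names]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GMT / PPIN / OBO
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT file into ``{set_id: set of gene ids}`` (description dropped)."""
    sets = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs id, description and >=1 gene")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with Path(path).open("w") as fh:
        for sid in sorted(sets):
            desc = (descriptions or {}).get(sid, "na")
            fh.write("\t".join([sid, desc] + sorted(sets[sid])) + "\n")


def read_ppin(path, min_score: int = 400) -> tuple[list, int]:
    """Read a STRING-like 3-column TSV (gene1, gene2, combined_score).

    Edges with score below ``min_score`` are dropped; returns
    ``(edges, n_dropped)`` where each edge is ``(gene1, gene2, score)``.
    """
    edges = []
    dropped = 0
    with Path(path).open() as fh:
        first = fh.readline().rstrip("\n")
        lines = []
        if first:
            f = first.split("\t")
            if f[0] not in ("gene1", "protein1"):  # headerless file: keep first row
                lines.append((1, first))
        lines.extend(enumerate(fh, start=2))
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(f)}")
            try:
                score = int(f[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer score {f[2]!r}") from None
            if score < min_score:
                dropped += 1
            else:
                edges.append((f[0], f[1], score))
    return edges, dropped


def write_ppin(edges: Sequence[tuple], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene1\tgene2\tcombined_score\n")
        for g1, g2, score in sorted(edges):
            fh.write(f"{g1}\t{g2}\t{score}\n")


@dataclass
class OntologyDAG:
    """Rooted acyclic term graph with typed parent edges and gene annotations.

    ``parents[t]`` lists ``(parent_term, relation)`` pairs with relation in
    {"is_a", "part_of"}.  ``annotations`` maps gene id -> set of term ids.
    """

    terms: set
    parents: dict
    roots: set
    annotations: dict = field(default_factory=dict)

    def children(self) -> dict:
        ch: dict = {t: [] for t in self.terms}
        for t, ps in self.parents.items():
            for p, rel in ps:
                ch[p].append((t, rel))
        return ch

    def ancestors(self, term: str) -> set:
        """All proper ancestors following is_a/part_of edges upward."""
        seen = set()
        stack = [term]
        while stack:
            for p, _rel in self.parents.get(stack.pop(), []):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen


def read_obo(path) -> OntologyDAG:
    """Parse an OBO-lite file (id/name/is_a/relationship: part_of) via obonet."""
    graph = obonet.read_obo(str(path))
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError(f"{path}: ontology contains a cycle")
    terms = set(graph.nodes)
    parents: dict = {t: [] for t in terms}
    for child, parent, rel in graph.edges(keys=True):
        if rel in ("is_a", "part_of"):
            parents[child].append((parent, rel))
    roots = {t for t in terms if not parents[t]}
    return OntologyDAG(terms=terms, parents=parents, roots=roots)


def write_obo(dag: OntologyDAG, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-annotation-dag\n")
        for t in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            for p, rel in sorted(dag.parents.get(t, [])):
                if rel == "is_a":
                    fh.write(f"is_a: {p}\n")
                else:
                    fh.write(f"relationship: part_of {p}\n")


def read_annotations(path) -> dict:
    """Read gene->term annotations from a GMT of term -> gene ids."""
    term_sets = read_gmt(path)
    annotations: dict = {}
    for term, genes in term_sets.items():
        for g in genes:
            annotations.setdefault(g, set()).add(term)
    return annotations


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def build_clinical_network(records: Sequence[PatientRecord]) -> nx.Graph:
    """Co-occurrence network over symptoms and plaque types.

    Two clinical items are linked if they appear in the same patient; the
    edge weight is the number of patients in which the pair co-occurs (each
    patient contributes at most one count per pair).
    """
    if not records:
        raise ValueError("empty record list")
    g = nx.Graph(kind="clinical")
    for r in records:
        items = sorted({sym(s) for s in r.symptoms} | {plq(p) for p in r.plaques})
        for node in items:
            if node not in g:
                g.add_node(node, kind="symptom" if node.startswith(SYM_PREFIX) else "plaque")
        for i, u in enumerate(items):
            for v in items[i + 1:]:
                if g.has_edge(u, v):
                    g[u][v]["weight"] += 1
                else:
                    g.add_edge(u, v, weight=1, kind="cooccurrence")
    return g


def fuse_graph(
    clinical: nx.Graph,
    symptom_sets: Mapping[str, Iterable[str]],
    plaque_sets: Mapping[str, Iterable[str]],
    ppin_edges: Sequence[tuple],
    lengths: EdgeLengths | None = None,
) -> nx.Graph:
    """Merge the clinical network, annotation gene sets and the PPIN.

    Every edge carries a ``length`` attribute (see :class:`EdgeLengths`)
    used by shortest-path and random-walk computations.  A fusion report
    (counts, isolated-annotation warnings) is stored in ``graph.graph``.
    """
    lengths = lengths or EdgeLengths()
    kg = nx.Graph()
    report = {"added_isolated_genes": [], "symptoms_without_genes": []}

    for node, data in clinical.nodes(data=True):
        kg.add_node(node, kind=data.get("kind", "symptom"))
    for u, v, data in clinical.edges(data=True):
        w = data["weight"]
        kg.add_edge(u, v, kind="cooccurrence", weight=w, length=lengths.cooccurrence(w))

    ppin_nodes = set()
    for g1, g2, score in ppin_edges:
        ppin_nodes.add(g1)
        ppin_nodes.add(g2)
    for g in sorted(ppin_nodes):
        kg.add_node(gene(g), kind="gene")
    for g1, g2, score in ppin_edges:
        if score < 400:
            raise ValueError(f"interaction edge {g1}-{g2} below confidence threshold (score={score})")
        kg.add_edge(gene(g1), gene(g2), kind="interaction", score=score, length=lengths.interaction(score))

    def add_annotations(sets: Mapping, prefix_fn):
        for set_id in sorted(sets):
            node = prefix_fn(set_id)
            if node not in kg:
                kg.add_node(node, kind="symptom" if prefix_fn is sym else "plaque")
            for g in sorted(sets[set_id]):
                gnode = gene(g)
                if gnode not in kg:
                    kg.add_node(gnode, kind="gene")
                    report["added_isolated_genes"].append(g)
                kg.add_edge(node, gnode, kind="annotation", length=lengths.annotation)

    add_annotations(symptom_sets, sym)
    add_annotations(plaque_sets, plq)

    for node, data in kg.nodes(data=True):
        if data["kind"] == "symptom" and strip_ns(node) not in symptom_sets:
            report["symptoms_without_genes"].append(strip_ns(node))
    report["n_nodes"] = kg.number_of_nodes()
    report["n_edges"] = kg.number_of_edges()
    report["connected"] = nx.is_connected(kg) if kg.number_of_nodes() else False
    kg.graph["fusion_report"] = report
    return kg


def write_graph(kg: nx.Graph, path) -> None:
    """Export a graph as an edge-list TSV with kind / weight / score / length."""
    with Path(path).open("w") as fh:
        fh.write("node1\tnode2\tkind\tweight\tscore\tlength\n")
        for u, v, data in sorted(kg.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data.get('kind','')}\t{data.get('weight','')}"
                f"\t{data.get('score','')}\t{data.get('length','')}\n"
            )
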