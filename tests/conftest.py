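import numpy as np
import networkx as nx
import pytest

from plaquekg.graphio import OntologyDAG, PatientRecord
from plaquekg.syndata import GeneratorConfig, generate_annotations, generate_cohort, generate_ppin


@pytest.fixture(scope="session")
def small_cfg():
    """Compact but structured study: planted pairs, 300 patients, 60 genes."""
    return GeneratorConfig(
        n_patients=300, n_symptoms=12, n_genes=60, genes_per_symptom=5,
        genes_per_plaque=8, ontology_depth=3, ontology_branching=2,
        n_expression_samples=60, n_planted_modules=3, seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Cohort + interactome + annotations for the compact study."""
    records, truth = generate_cohort(small_cfg)
    ppin = generate_ppin(small_cfg)
    symptom_sets, plaque_sets, dag = generate_annotations(small_cfg, ppin, truth)
    return {
        "cfg": small_cfg, "records": records, "truth": truth, "ppin": ppin,
        "symptom_sets": symptom_sets, "plaque_sets": plaque_sets, "dag": dag,
    }


@pytest.fixture
def toy_records():
    """Three patients used for hand-counted co-occurrence and lift checks."""
    return [
        PatientRecord("p1", frozenset({"s1", "s2"}), frozenset({"calcified"})),
        PatientRecord("p2", frozenset({"s1"}), frozenset({"calcified"})),
        PatientRecord("p3", frozenset({"s2"}), frozenset()),
    ]


@pytest.fixture
def root_child_dag():
    """Minimal ontology: root A with one is_a child B (Wang weight 0.8)."""
    return OntologyDAG(
        terms={"A", "B"},
        parents={"A": [], "B": [("A", "is_a")]},
        roots={"A"},
        annotations={"g1": {"A"}, "g2": {"B"}},
    )


@pytest.fixture
def chain_graph():
    """a - b - c with unit traversal lengths."""
    g = nx.Graph()
    g.add_edge("a", "b", length=1.0)
    g.add_edge("b", "c", length=1.0)
    return g


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyDAG:
    """Random rooted DAG for oracle-equivalence tests (shared helper)."""
    terms = [f"T{i}" for i in range(n_terms)]
    parents = {terms[0]: []}
    for i in range(1, n_terms):
        n_par = 1 + (rng.random() < 0.3)
        choices = rng.choice(i, size=min(n_par, i), replace=False)
        parents[terms[i]] = [
            (terms[int(j)], "is_a" if rng.random() < 0.7 else "part_of") for j in choices
        ]
    return OntologyDAG(terms=set(terms), parents=parents, roots={terms[0]})
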