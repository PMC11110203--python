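"""Random walk with restart over the knowledge graph, and pair labeling.

Edge affinities are the reciprocals of traversal lengths; the walk matrix is
column-stochastic (each node distributes its mass to neighbors in proportion
to affinity).  Iterating

    p <- (1 - r) W p + r p0

from a uniform seed distribution p0 converges to a stationary score that
ranks every node's proximity to the seeds.  Scores of the symptom nodes,
seeded at each plaque in turn, provide the "judgment" used to binarize
(symptom, plaque) pairs into training labels: the top fraction q of symptoms
per plaque are positives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .graphio import plq, sym

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000
DEFAULT_POSITIVE_FRACTION = 0.15


class ConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float):
        super().__init__(f"RWR did not converge in {iterations} iterations (residual {residual:.3e})")
        self.iterations = iterations
        self.residual = residual


@dataclass
class RWRResult:
    restart_prob: float
    seeds: frozenset
    scores: dict
    iterations: int
    residual: float
    converged: bool


def _transition_matrix(kg: nx.Graph, nodes: list) -> sp.csc_matrix:
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, data in kg.edges(data=True):
        length = data.get("length", 1.0)
        if length <= 0:
            raise ValueError(f"non-positive traversal length on edge {u}-{v}")
        a = 1.0 / length
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
        vals += [a, a]
    w = sp.csc_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    colsum = np.asarray(w.sum(axis=0)).ravel()
    colsum[colsum == 0] = 1.0  # isolated nodes keep zero columns harmless
    return w @ sp.diags(1.0 / colsum)


def rwr(
    kg: nx.Graph,
    seeds: Sequence[str],
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RWRResult:
    """Random walk with restart from ``seeds``; returns stationary scores.

    Scores are a probability distribution over nodes (sum 1); isolated seed
    mass simply stays put.  Raises :class:`ConvergenceError` if the L1
    residual does not drop below ``tol`` within ``max_iter`` sweeps.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    missing = [s for s in seeds if s not in kg]
    if missing:
        raise KeyError(f"seed nodes not in graph: {missing}")
    nodes = list(kg.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    for s in seeds:
        p0[index[s]] = 1.0 / len(seeds)
    if r == 1.0:
        return RWRResult(r, frozenset(seeds), dict(zip(nodes, p0)), 0, 0.0, True)
    w = _transition_matrix(kg, nodes)
    # isolated nodes (zero column) would leak mass; redirect their mass to restart
    deg = np.asarray((w != 0).sum(axis=0)).ravel()
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_new = (1.0 - r) * (w @ p) + r * p0
        # mass parked on zero-degree nodes has nowhere to walk: return it to seeds
        lost = 1.0 - p_new.sum()
        if lost > 1e-15:
            p_new += lost * p0
        residual = float(np.abs(p_new - p).sum())
        p = p_new
        if residual < tol:
            return RWRResult(r, frozenset(seeds), dict(zip(nodes, p)), it, residual, True)
    raise ConvergenceError(max_iter, residual)


def label_pairs(
    kg: nx.Graph,
    plaque_ids: Sequence[str],
    symptoms: Sequence[str] | None = None,
    r: float = DEFAULT_RESTART,
    q: float = DEFAULT_POSITIVE_FRACTION,
) -> dict:
    """Binary labels for every (symptom, plaque) pair from per-plaque RWR.

    For each plaque the walk is seeded at that plaque node; symptoms are
    ranked by stationary score (ties broken lexicographically) and the top
    ``ceil(q * S)`` become positives.  A plaque with no walkable path to any
    symptom yields all-zero labels and a warning.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"positive fraction q must be in (0, 1), got {q}")
    if symptoms is None:
        symptoms = sorted(
            n.split(":", 1)[1] for n, d in kg.nodes(data=True) if d.get("kind") == "symptom"
        )
    symptoms = list(symptoms)
    n_pos = math.ceil(q * len(symptoms))
    labels = {}
    for t in plaque_ids:
        res = rwr(kg, [plq(t)], r=r)
        scored = sorted(((-res.scores.get(sym(s), 0.0), s) for s in symptoms))
        if all(-neg == 0.0 for neg, _ in scored):
            warnings.warn(f"plaque {t} is disconnected from all symptoms; labeling all pairs 0")
            for s in symptoms:
                labels[(s, t)] = 0
            continue
        positive = {s for _, s in scored[:n_pos]}
        for s in symptoms:
            labels[(s, t)] = 1 if s in positive else 0
    return labels
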