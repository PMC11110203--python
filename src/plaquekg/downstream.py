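"""Hypergeometric gene-set enrichment and expression-signature ROC validation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .assocmodel import rank_auc


@dataclass
class EnrichmentResult:
    term: str
    k: int          # overlap
    K: int          # term size
    n: int          # query size
    N: int          # universe size
    p: float        # upper-tail hypergeometric probability
    significant: bool


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray
    labels: np.ndarray


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), via exact log-binomial sums.

    N genes in the universe, K in the term, n drawn (the query), k observed
    in the overlap.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    logs = _log_binom(K, j) + _log_binom(N - K, n - j) - _log_binom(N, n)
    return float(min(1.0, np.exp(logs).sum()))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrich(
    query: set,
    annotation: Mapping[str, set],
    universe: set,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``query`` against each term.

    One result per term with overlap >= 1, sorted by p.  Significance is a
    raw p < alpha flag by default; pass ``correction='bh'`` for
    Benjamini-Hochberg-adjusted flags.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    results = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe
        k = len(query & term_genes)
        if k == 0 or not term_genes:
            continue
        p = hypergeom_p(k, len(term_genes), len(query), len(universe))
        results.append(EnrichmentResult(term, k, len(term_genes), len(query), len(universe), p, p < alpha))
    results.sort(key=lambda r: (r.p, r.term))
    if correction == "bh" and results:
        adj = benjamini_hochberg([r.p for r in results])
        for r, q in zip(results, adj):
            r.significant = q < alpha
    return results


def signature_roc(expr: pd.DataFrame, labels: Sequence[int], gene_set: set) -> RocCurve:
    """ROC of a gene-set signature on a gene x sample expression matrix.

    The per-sample signature score is the mean z-scored expression over the
    gene set (a per-sample analog of group-level fold change); the ROC/AUC
    use the rank statistic with half-credit on ties.
    """
    labels = np.asarray(labels, dtype=int)
    genes = [g for g in sorted(gene_set) if g in expr.index]
    if not genes:
        missing = sorted(gene_set)[:5]
        raise ValueError(f"no signature genes found in the expression matrix (e.g. {missing})")
    if len(np.unique(labels)) < 2:
        raise ValueError("both case and control labels must be present")
    x = expr.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    scores = z.mean(axis=0)
    auc = rank_auc(scores, labels)
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc, scores=scores, labels=labels)
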