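"""Weighted-correlation network modules on a patient x gene coefficient matrix.

The pipeline's co-expression-style step: raise absolute Pearson correlations
between gene columns to a soft-threshold power chosen for scale-free
connectivity, convert the adjacency to topological-overlap similarity,
cluster genes by average linkage on 1 - TOM with a static cut, summarize
each module by its eigengene (first principal component) and correlate
eigengenes with clinical traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

# WGCNA's conventional color ladder; grey is the unassigned bucket.
MODULE_COLORS = ["turquoise", "blue", "brown", "yellow", "green", "red", "black",
                 "pink", "magenta", "purple"]
DEFAULT_BETAS = tuple(range(1, 21))
DEFAULT_CUT_HEIGHT = 0.98
DEFAULT_MIN_SIZE = 5


@dataclass
class SoftThresholdResult:
    beta: int
    r_squared: dict       # beta -> signed scale-free fit R^2
    slopes: dict
    mean_connectivity: dict


@dataclass
class ModuleAssignment:
    """Gene -> module partition with eigengenes; module 0 is unassigned (grey)."""

    labels: dict                      # gene -> int module id (0 = grey)
    beta: int
    eigengenes: pd.DataFrame          # patients x modules ("ME1", ...)
    trait_correlation: pd.DataFrame | None = None
    trait_pvalues: pd.DataFrame | None = None
    _colors: dict = field(default_factory=dict)

    def module_genes(self, module: int) -> list:
        return sorted(g for g, m in self.labels.items() if m == module)

    @property
    def modules(self) -> list:
        return sorted({m for m in self.labels.values() if m != 0})

    def color_of(self, module: int) -> str:
        if module == 0:
            return "grey"
        return MODULE_COLORS[(module - 1) % len(MODULE_COLORS)]


def coefficient_matrix(
    records: Sequence,
    pair_scores: pd.DataFrame,
    symptom_sets: Mapping,
    plaque_sets: Mapping,
    genes: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient x gene matrix of model-derived gene relevances, plus traits.

    relevance(s, g) = mean predicted score of pairs (s, .) whose pooled
    annotation genes contain g (0 when g never appears with s); a patient's
    entry for g sums relevance over the symptoms they exhibit.  The trait
    table carries plaque indicator flags and any numeric covariates.
    """
    genes = list(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    symptoms = sorted(pair_scores["symptom"].unique())
    relevance = {s: np.zeros(len(genes)) for s in symptoms}
    counts = {s: np.zeros(len(genes)) for s in symptoms}
    for r in pair_scores.itertuples():
        pooled = set(symptom_sets.get(r.symptom, ())) | set(plaque_sets.get(r.plaque, ()))
        for g in pooled:
            if g in gene_idx:
                relevance[r.symptom][gene_idx[g]] += r.score
                counts[r.symptom][gene_idx[g]] += 1
    for s in symptoms:
        nz = counts[s] > 0
        relevance[s][nz] /= counts[s][nz]

    rows, trait_rows, index = [], [], []
    from .graphio import PLAQUE_LABELS

    for rec in records:
        v = np.zeros(len(genes))
        for s in rec.symptoms:
            if s in relevance:
                v += relevance[s]
        rows.append(v)
        traits = {f"plaque_{t}": float(t in rec.plaques) for t in PLAQUE_LABELS}
        traits.update(rec.covariates)
        trait_rows.append(traits)
        index.append(rec.patient_id)
    m = pd.DataFrame(rows, index=index, columns=genes)
    traits = pd.DataFrame(trait_rows, index=index).fillna(0.0)
    return m, traits


def _column_correlations(m: np.ndarray) -> np.ndarray:
    sd = m.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance columns at indices {dead.tolist()[:10]}")
    return np.corrcoef(m, rowvar=False)


def adjacency(m: pd.DataFrame | np.ndarray, beta: int) -> np.ndarray:
    """Unsigned soft adjacency |cor|^beta; symmetric, unit diagonal."""
    x = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows (patients/samples)")
    a = np.abs(_column_correlations(x)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of log10 p(k) vs log10 k on binned connectivity."""
    k = k[k > 0]
    if k.size < 2 or k.min() == k.max():
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - pred) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (-np.sign(slope) * r2 if slope != 0 else 0.0), float(slope)


def _fallback_power(n_samples: int) -> int:
    """Recommended unsigned-network power by sample count (standard
    weighted-correlation-network practice) when no power reaches the
    scale-free fit target: <20 samples -> 9, <30 -> 8, <40 -> 7, else 6."""
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


def pick_soft_threshold(
    m: pd.DataFrame | np.ndarray,
    betas: Sequence[int] = DEFAULT_BETAS,
    r2_target: float = 0.8,
) -> SoftThresholdResult:
    """Smallest power with signed scale-free fit R^2 >= target.

    The signed criterion requires a decreasing log-log degree fit (slope < 0);
    the default candidate grid is 1..20.  When no candidate reaches the
    target — common for strongly block-structured matrices, whose degree
    distribution is bimodal rather than scale-free — the chooser falls back
    to the sample-size-based recommended power (see :func:`_fallback_power`)
    clipped to the candidate grid, since chasing the argmax of a slowly
    rising R^2 curve inflates the power and dissolves genuine modules.
    """
    if not len(betas):
        raise ValueError("candidate beta list is empty")
    x = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    cor = np.abs(_column_correlations(x))
    np.fill_diagonal(cor, 0.0)
    r2s, slopes, meank = {}, {}, {}
    chosen = None
    for b in betas:
        a = cor ** b
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        r2s[b], slopes[b], meank[b] = r2, slope, float(k.mean())
        if chosen is None and r2 >= r2_target:
            chosen = b
    if chosen is None:
        fb = _fallback_power(x.shape[0])
        chosen = min(betas, key=lambda b: abs(b - fb))
    return SoftThresholdResult(int(chosen), r2s, slopes, meank)


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap: shared-neighbor strength normalized by
    the smaller connectivity; symmetric, unit diagonal, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=1) - 1.0  # exclude the self term
    l = a @ a - 2.0 * a      # sum over u != i,j of a_iu a_uj (diag of a is 1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def _eigengene(sub: np.ndarray) -> np.ndarray:
    """First principal component of z-scored columns, sign-oriented so its
    mean correlation with the member genes is positive."""
    z = (sub - sub.mean(axis=0)) / np.where(sub.std(axis=0) > 0, sub.std(axis=0), 1.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eg = u[:, 0]
    cors = np.array([np.corrcoef(eg, z[:, j])[0, 1] for j in range(z.shape[1])])
    if np.nanmean(cors) < 0:
        eg = -eg
    return eg


def detect_modules(
    m: pd.DataFrame,
    beta: int,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_size: int = DEFAULT_MIN_SIZE,
) -> ModuleAssignment:
    """TOM-based average-linkage clustering with a static cut.

    Clusters smaller than ``min_size`` fall into module 0 (grey); surviving
    modules are relabeled 1, 2, ... by decreasing size, then by the
    lexicographically smallest member for ties, so labels are invariant to
    gene input order.
    """
    genes = list(m.columns)
    a = adjacency(m, beta)
    tom = tom_similarity(a)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = sch.linkage(squareform(diss, checks=False), method="average")
    raw = sch.fcluster(link, t=cut_height, criterion="distance")

    clusters: dict = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(c, []).append(g)
    keep = [sorted(gs) for gs in clusters.values() if len(gs) >= min_size]
    keep.sort(key=lambda gs: (-len(gs), gs[0]))
    labels = {g: 0 for g in genes}
    for mid, gs in enumerate(keep, start=1):
        for g in gs:
            labels[g] = mid

    x = m.to_numpy(dtype=float)
    gene_idx = {g: i for i, g in enumerate(genes)}
    egs = {}
    for mid, gs in enumerate(keep, start=1):
        sub = x[:, [gene_idx[g] for g in gs]]
        egs[f"ME{mid}"] = _eigengene(sub)
    eigengenes = pd.DataFrame(egs, index=m.index)
    return ModuleAssignment(labels=labels, beta=beta, eigengenes=eigengenes)


def module_trait(assignment: ModuleAssignment, traits: pd.DataFrame) -> ModuleAssignment:
    """Pearson correlation of each eigengene with each numeric trait.

    p-values are two-sided from t = r sqrt((n-2)/(1-r^2)); requires n >= 3.
    Fills the assignment's trait tables in place and returns it.
    """
    n = len(traits)
    if n < 3:
        raise ValueError("need at least 3 patients for trait correlation")
    rmat = pd.DataFrame(index=assignment.eigengenes.columns, columns=traits.columns, dtype=float)
    pmat = rmat.copy()
    for me in assignment.eigengenes.columns:
        for tr in traits.columns:
            x = assignment.eigengenes[me].to_numpy()
            y = traits[tr].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                rmat.loc[me, tr], pmat.loc[me, tr] = 0.0, 1.0
                continue
            r, p = pearsonr(x, y)
            rmat.loc[me, tr], pmat.loc[me, tr] = float(r), float(p)
    assignment.trait_correlation = rmat
    assignment.trait_pvalues = pmat
    return assignment
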