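"""KNN association model over (symptom, plaque) pair features, with ablations.

The classification unit is the (symptom, plaque) pair.  Three named
configurations mirror the feature ablation of interest:

* ``A`` — all channels: topology (shortest path + point-to-network), the
  association channel (lift + CNN correlation value) and semantic similarity;
* ``B`` — topology + association only;
* ``C`` — semantic similarity only.

Scores are the fraction of the k = 6 nearest training pairs (Euclidean
metric on per-fold z-scored channels) that are positive; evaluation is
stratified 10-fold cross-validation with a rank-statistic AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

CHANNEL_COLUMNS = {
    "topo": ["topo_dist", "topo_euclid"],
    "assoc": ["lift", "cnn_score"],
    "semsim": ["semsim"],
}
NAMED_CONFIGS = {"A": ("topo", "assoc", "semsim"), "B": ("topo", "assoc"), "C": ("semsim",)}


@dataclass
class ModelConfig:
    k_neighbors: int = 6
    folds: int = 10
    channels: tuple = ("topo", "assoc", "semsim")
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.channels:
            raise ValueError("channels must be non-empty")
        unknown = set(self.channels) - set(CHANNEL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")

    @property
    def columns(self) -> list:
        return [c for ch in self.channels for c in CHANNEL_COLUMNS[ch]]

    @classmethod
    def named(cls, name: str, **kw) -> "ModelConfig":
        return cls(channels=NAMED_CONFIGS[name], **kw)


@dataclass
class EvalReport:
    fold_aucs: list
    mean_auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    pair_scores: pd.DataFrame  # columns symptom, plaque, score, label
    config: ModelConfig = field(repr=False, default=None)

    @property
    def predicted_positive_pairs(self) -> set:
        df = self.pair_scores
        return {(r.symptom, r.plaque) for r in df.itertuples() if r.score >= 0.5}


class KNNModel:
    """k-nearest-neighbor scorer; ties in distance break by training-row index."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg

    def fit(self, x: np.ndarray, y: np.ndarray) -> "KNNModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(x) < self.cfg.k_neighbors:
            raise ValueError(f"need at least k={self.cfg.k_neighbors} training rows, got {len(x)}")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        if self.cfg.standardize:
            self._mu = x.mean(axis=0)
            sd = x.std(axis=0)
            self._sd = np.where(sd > 0, sd, 1.0)
        else:
            self._mu, self._sd = 0.0, 1.0
        self._x = (x - self._mu) / self._sd
        self._y = y
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Score in [0, 1]: fraction of the k nearest training rows labeled 1."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xq = (x - self._mu) / self._sd
        d = np.linalg.norm(xq[:, None, :] - self._x[None, :, :], axis=2)
        order = np.argsort(d, axis=1, kind="stable")[:, : self.cfg.k_neighbors]
        return self._y[order].mean(axis=1)


def knn_fit(rows: pd.DataFrame, cfg: ModelConfig) -> KNNModel:
    return KNNModel(cfg).fit(rows[cfg.columns].to_numpy(), rows["label"].to_numpy())


def knn_predict(model: KNNModel, rows: pd.DataFrame) -> np.ndarray:
    return model.predict(rows[model.cfg.columns].to_numpy())


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank statistic; distance ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cross_validate(rows: pd.DataFrame, cfg: ModelConfig) -> EvalReport:
    """Stratified k-fold CV; out-of-fold scores pooled for the ROC and AUC."""
    y = rows["label"].to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < cfg.folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {cfg.folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    oof = np.full(len(rows), np.nan)
    fold_aucs = []
    x_all = rows[cfg.columns].to_numpy(dtype=float)
    for train_idx, test_idx in skf.split(x_all, y):
        model = KNNModel(cfg).fit(x_all[train_idx], y[train_idx])
        scores = model.predict(x_all[test_idx])
        oof[test_idx] = scores
        if len(np.unique(y[test_idx])) == 2:
            fold_aucs.append(rank_auc(scores, y[test_idx]))
    mean_auc = rank_auc(oof, y)
    fpr, tpr, thr = roc_curve(y, oof)
    pair_scores = rows[["symptom", "plaque"]].copy() if {"symptom", "plaque"} <= set(rows.columns) else pd.DataFrame(index=rows.index)
    pair_scores["score"] = oof
    pair_scores["label"] = y
    return EvalReport(fold_aucs, mean_auc, fpr, tpr, thr, pair_scores, cfg)


def run_ablation(rows: pd.DataFrame, base_cfg: ModelConfig | None = None) -> dict:
    """Evaluate the three named configurations on identical folds."""
    base_cfg = base_cfg or ModelConfig()
    out = {}
    for name, channels in NAMED_CONFIGS.items():
        cfg = ModelConfig(
            k_neighbors=base_cfg.k_neighbors,
            folds=base_cfg.folds,
            channels=channels,
            standardize=base_cfg.standardize,
            seed=base_cfg.seed,
        )
        out[name] = cross_validate(rows, cfg)
    return out


def select_associations(
    report: EvalReport,
    score_cutoff: float = 0.5,
    symptom_sets: Mapping | None = None,
    plaque_sets: Mapping | None = None,
) -> tuple[set, set]:
    """Retain pairs with out-of-fold score >= cutoff; collect their genes.

    The gene set is the union of the annotation genes of every retained
    symptom and plaque (empty when no gene sets are supplied).
    """
    pairs = {
        (r.symptom, r.plaque)
        for r in report.pair_scores.itertuples()
        if r.score >= score_cutoff
    }
    genes: set = set()
    for s, t in pairs:
        genes |= set((symptom_sets or {}).get(s, ()))
        genes |= set((plaque_sets or {}).get(t, ()))
    return pairs, genes
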