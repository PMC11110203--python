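"""Compact convolutional network over per-patient association matrices.

Each patient is represented by a symptom x plaque grid of lift values with
rows of absent symptoms zeroed.  Because symptoms aggregate locally with
specific plaques, small receptive fields capture the informative structure;
the network is deliberately tiny:

    input 1 x S x P -> conv 3x3 (8 filters, ReLU) -> conv 3x3 (16, ReLU)
    -> global average pool -> dense -> P sigmoid outputs

trained full-batch with Adam on binary cross-entropy against the patient's
multi-label plaque vector.  Implemented directly on numpy (im2col
convolutions with manual backprop, float32 internally); training is
deterministic given the seed.

The distilled pair-level score contrasts the model's predicted plaque
probability between patients who do and do not exhibit a symptom, min-max
rescaled to [0, 1] across all pairs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .graphio import PatientRecord
from .features import AssociationMatrix

_DT = np.float32


def _im2col(x: np.ndarray, kh: int = 3, kw: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*kh*kw) patches with zero 'same' padding."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh * kw, h * w), dtype=x.dtype)
    idx = 0
    for di in range(kh):
        for dj in range(kw):
            cols[:, :, idx, :] = xp[:, :, di:di + h, dj:dj + w].reshape(n, c, -1)
            idx += 1
    return cols.reshape(n, c * kh * kw, h * w).transpose(0, 2, 1)


def _col2im(cols: np.ndarray, shape, kh: int = 3, kw: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    cols = cols.transpose(0, 2, 1).reshape(n, c, kh * kw, h * w)
    idx = 0
    for di in range(kh):
        for dj in range(kw):
            xp[:, :, di:di + h, dj:dj + w] += cols[:, :, idx, :].reshape(n, c, h, w)
            idx += 1
    return xp[:, :, ph:ph + h, pw:pw + w]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


class CorrelationCNN:
    """Two-layer CNN mapping a patient matrix to per-plaque probabilities."""

    def __init__(self, n_symptoms: int, n_plaques: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.shape = (n_symptoms, n_plaques)

        def he(*s):
            fan_in = int(np.prod(s[1:])) if len(s) > 2 else s[0]
            return (rng.standard_normal(s) * np.sqrt(2.0 / fan_in)).astype(_DT)

        self.params = {
            "W1": he(8, 1, 3, 3), "b1": np.zeros(8, dtype=_DT),
            "W2": he(16, 8, 3, 3), "b2": np.zeros(16, dtype=_DT),
            "W3": he(16, n_plaques), "b3": np.zeros(n_plaques, dtype=_DT),
        }
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()}
        self._t = 0

    def zero_head(self) -> None:
        """Zero the dense head so every output probability is sigmoid(0) = 0.5."""
        self.params["W3"][:] = 0.0
        self.params["b3"][:] = 0.0

    def _forward(self, x: np.ndarray, c1: np.ndarray | None = None, keep: bool = False):
        p = self.params
        n = x.shape[0]
        h, w = self.shape
        hw = h * w
        if c1 is None:
            c1 = _im2col(x)                                    # (N, HW, 9)
        z1 = (c1.reshape(-1, 9) @ p["W1"].reshape(8, -1).T + p["b1"]).reshape(n, hw, 8)
        a1 = np.maximum(z1, 0.0)
        x1 = a1.transpose(0, 2, 1).reshape(n, 8, h, w)
        c2 = _im2col(x1)                                       # (N, HW, 72)
        z2 = (c2.reshape(-1, 72) @ p["W2"].reshape(16, -1).T + p["b2"]).reshape(n, hw, 16)
        a2 = np.maximum(z2, 0.0)
        gap = a2.mean(axis=1)                                  # (N, 16)
        logits = gap @ p["W3"] + p["b3"]
        probs = _sigmoid(logits)
        if keep:
            self._cache = (c1, z1, c2, z2, gap, probs)
        return probs

    def predict(self, matrices: np.ndarray) -> np.ndarray:
        """Per-plaque probabilities for a stack of matrices (N, S, P)."""
        x = np.asarray(matrices, dtype=_DT)[:, None, :, :]
        return self._forward(x).astype(float)

    def _backward(self, y: np.ndarray) -> dict:
        p = self.params
        c1, z1, c2, z2, gap, probs = self._cache
        n = y.shape[0]
        h, w = self.shape
        hw = h * w
        dlogits = (probs - y) / n                                # BCE + sigmoid
        grads = {"W3": gap.T @ dlogits, "b3": dlogits.sum(axis=0)}
        dgap = dlogits @ p["W3"].T                               # (N, 16)
        dz2 = np.repeat(dgap[:, None, :], hw, axis=1) / hw
        dz2 *= z2 > 0
        dz2f = dz2.reshape(-1, 16)
        c2f = c2.reshape(-1, 72)
        grads["W2"] = (dz2f.T @ c2f).reshape(p["W2"].shape)
        grads["b2"] = dz2f.sum(axis=0)
        dc2 = (dz2f @ p["W2"].reshape(16, -1)).reshape(n, hw, 72)
        dx1 = _col2im(dc2, (n, 8, h, w))
        dz1 = dx1.reshape(n, 8, hw).transpose(0, 2, 1) * (z1 > 0)
        dz1f = dz1.reshape(-1, 8)
        grads["W1"] = (dz1f.T @ c1.reshape(-1, 9)).reshape(p["W1"].shape)
        grads["b1"] = dz1f.sum(axis=0)
        return grads

    def fit(self, matrices: np.ndarray, labels: np.ndarray, epochs: int = 200, lr: float = 0.03):
        """Full-batch Adam on binary cross-entropy; returns the loss history."""
        x = np.asarray(matrices, dtype=_DT)[:, None, :, :]
        y = np.asarray(labels, dtype=_DT)
        if y.ndim != 2 or y.shape[1] != self.shape[1]:
            raise ValueError(f"labels must be (n, {self.shape[1]})")
        for j in range(y.shape[1]):
            if y[:, j].min() == y[:, j].max():
                raise ValueError(f"plaque class {j} is single-valued (all {y[0, j]:g}); cannot train")
        losses = []
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1 = _im2col(x)  # input patches do not change across epochs
        for _ in range(epochs):
            probs = self._forward(x, c1=c1, keep=True)
            p_c = np.clip(probs, 1e-7, 1 - 1e-7)
            losses.append(float(-(y * np.log(p_c) + (1 - y) * np.log(1 - p_c)).mean()))
            grads = self._backward(y)
            self._t += 1
            for k, g in grads.items():
                m, v = self._adam[k]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._adam[k] = (m, v)
                mhat = m / (1 - b1 ** self._t)
                vhat = v / (1 - b2 ** self._t)
                self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(_DT)
        return losses

    def multilabel_accuracy(self, matrices: np.ndarray, labels: np.ndarray) -> float:
        """Fraction of (patient, plaque) entries classified correctly at 0.5."""
        probs = self.predict(matrices)
        return float(((probs > 0.5) == (np.asarray(labels) > 0.5)).mean())


def train_cnn(
    matrices: Sequence[AssociationMatrix],
    plaque_labels: np.ndarray,
    epochs: int = 200,
    lr: float = 0.03,
    seed: int = 0,
    max_train: int | None = 512,
) -> CorrelationCNN:
    """Train the correlation CNN on per-patient matrices and plaque labels.

    Cohorts larger than ``max_train`` are subsampled (seed-derived, without
    replacement) for the gradient steps; the fitted model still scores every
    patient at prediction time.  Pass ``max_train=None`` to train on all.
    """
    stack = np.stack([m.matrix for m in matrices])
    y = np.asarray(plaque_labels, dtype=float)
    if max_train is not None and len(stack) > max_train:
        rng = np.random.default_rng(seed + 17)
        pick = rng.choice(len(stack), size=max_train, replace=False)
        stack, y = stack[pick], y[pick]
    model = CorrelationCNN(stack.shape[1], stack.shape[2], seed=seed)
    model.fit(stack, y, epochs=epochs, lr=lr)
    return model


def cnn_pair_scores(
    model: CorrelationCNN,
    matrices: Sequence[AssociationMatrix],
    records: Sequence[PatientRecord],
    symptoms: Sequence[str],
    plaques: Sequence[str],
) -> pd.DataFrame:
    """Distill patient-level predictions into a [0, 1] score per pair.

    Raw value for (s, t): mean predicted probability of plaque t over the
    patients exhibiting s, minus the mean over patients not exhibiting s;
    the raw grid is then min-max rescaled to [0, 1] over all pairs (a flat
    grid maps to 0.5 everywhere).
    """
    stack = np.stack([m.matrix for m in matrices])
    probs = model.predict(stack)  # (n_patients, n_plaques)
    raw = np.zeros((len(symptoms), len(plaques)))
    has = np.array([[s in r.symptoms for s in symptoms] for r in records])  # (n, S)
    for i, s in enumerate(symptoms):
        mask = has[:, i]
        if mask.any() and (~mask).any():
            raw[i] = probs[mask].mean(axis=0) - probs[~mask].mean(axis=0)
    lo, hi = raw.min(), raw.max()
    scaled = np.full_like(raw, 0.5) if hi - lo < 1e-12 else (raw - lo) / (hi - lo)
    return pd.DataFrame(scaled, index=list(symptoms), columns=list(plaques))
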