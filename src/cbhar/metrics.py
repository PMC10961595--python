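"""Evaluation metrics and the explanation-faithfulness protocol.

Classification is scored with a row-normalized confusion matrix and the
unweighted (macro) mean of per-class F1 scores. Concept prediction is
scored two ways: *concept accuracy*, the fraction of windows whose decoded
sequence matches the label sequence exactly, and the mean Levenshtein edit
distance (insertions, deletions, substitutions — deliberately without the
transposition operation used by the counterfactual proximity metric).

Faithfulness probes three properties of the decoded explanations:
P1 — windows receiving the same explanation receive the same prediction;
P2 — under small Gaussian perturbation, explanations are unchanged
wherever predictions are unchanged; P3 — destroying the temporal structure
(segment shuffling) changes predictions and explanations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "macro_f1",
    "levenshtein",
    "normalized_confusion",
    "EvalReport",
    "evaluate",
    "FaithfulnessReport",
    "faithfulness_check",
    "shuffle_segments",
]


def macro_f1(y_true: Sequence, y_pred: Sequence) -> float:
    """Unweighted mean over classes of F1 = 2PR/(P+R); classes absent from
    both truth and prediction do not contribute."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if not y_true:
        raise ValueError("empty input")
    scores = []
    for cls in sorted(set(y_true) | set(y_pred), key=str):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        scores.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return float(np.mean(scores))


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Classic edit distance (insert / delete / substitute, unit costs)."""
    a, b = tuple(a), tuple(b)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def normalized_confusion(y_true: Sequence, y_pred: Sequence, labels: Sequence) -> np.ndarray:
    """Row-normalized confusion matrix over `labels`; each non-empty row
    sums to 1, empty rows are zero."""
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    sums = mat.sum(axis=1, keepdims=True)
    return np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)


@dataclass
class EvalReport:
    labels: list
    confusion: list                  # row-normalized, L x L
    per_class: dict                  # label -> {precision, recall, f1}
    macro_f1: float
    concept_accuracy: float          # exact-sequence-match fraction
    mean_edit_distance: float
    n: int

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj) -> "EvalReport":
        if isinstance(obj, str):
            obj = json.loads(obj)
        return cls(**obj)


def evaluate(model, store, windows: Sequence) -> EvalReport:
    """Score a trained recognizer on labeled windows. Concept metrics use
    beam decoding of the bottleneck output; `store` is accepted for
    interface symmetry with the explanation pipeline and is not needed for
    the scores themselves."""
    if not windows:
        raise ValueError("no windows to evaluate")
    cfg = model.config
    for w in windows:
        if w.label not in cfg.classes or any(c not in cfg.concepts for c in w.concepts):
            raise ValueError(f"window labels do not match the model's alphabet/classes")
    pred_idx, matrices = model.predict_batch(windows)
    y_true = [w.label for w in windows]
    y_pred = [cfg.classes[i] for i in pred_idx]
    decoded = [model.decode_concepts(m) for m in matrices]

    per_class = {}
    for cls in cfg.classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = {"precision": prec, "recall": rec, "f1": f1}

    dists = [levenshtein(d, w.concepts) for d, w in zip(decoded, windows)]
    exact = [d == tuple(w.concepts) for d, w in zip(decoded, windows)]
    return EvalReport(
        labels=list(cfg.classes),
        confusion=normalized_confusion(y_true, y_pred, cfg.classes).tolist(),
        per_class=per_class,
        macro_f1=macro_f1(y_true, y_pred),
        concept_accuracy=float(np.mean(exact)),
        mean_edit_distance=float(np.mean(dists)),
        n=len(windows),
    )


def shuffle_segments(values: np.ndarray, n_segments: int, rng) -> np.ndarray:
    """Split a window into `n_segments` contiguous chunks along time and
    permute them (guaranteed non-identity when more than one distinct order
    exists); with one segment this is a no-op."""
    if n_segments <= 1:
        return values.copy()
    parts = np.array_split(values, n_segments, axis=1)
    order = rng.permutation(n_segments)
    while n_segments > 1 and np.array_equal(order, np.arange(n_segments)):
        order = rng.permutation(n_segments)
    return np.concatenate([parts[i] for i in order], axis=1)


@dataclass
class FaithfulnessReport:
    p1_consistency: float            # fraction of explanation groups with one prediction
    n_explanation_groups: int
    p2_stability: float              # explanation unchanged | prediction unchanged
    n_prediction_unchanged: int
    p3_prediction_changed: float     # fraction of shuffled windows with changed prediction
    p3_explanation_changed: float
    noise_fraction: float
    n_shuffle_segments: int
    n: int

    def to_json(self) -> dict:
        return asdict(self)


def faithfulness_check(model, store, windows: Sequence, noise_fraction: float = 0.05,
                       n_shuffle_segments: int = 4, seed: int = 0) -> FaithfulnessReport:
    """Run the three-part perturbation protocol on a test set.

    Noise perturbation adds zero-mean Gaussian noise with per-channel
    standard deviation `noise_fraction` times that channel's standard
    deviation within the window. The explanation content compared here is
    the decoded concept sequence (the counterfactual is a deterministic
    function of it and the predicted class).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if n_shuffle_segments < 2:
        raise ValueError("n_shuffle_segments must be >= 2")
    if not windows:
        raise ValueError("no windows given")
    from .synthetic import SensorWindow  # local import to avoid cycles at import time

    rng = np.random.default_rng(seed)
    pred_idx, matrices = model.predict_batch(windows)
    decoded = [model.decode_concepts(m) for m in matrices]

    groups: dict = {}
    for seq, p in zip(decoded, pred_idx):
        groups.setdefault(seq, set()).add(p)
    p1 = float(np.mean([len(v) == 1 for v in groups.values()]))

    def perturbed_copy(w, noisy_values):
        return SensorWindow(values=noisy_values, label=w.label, concepts=w.concepts)

    if noise_fraction == 0:
        noisy = [perturbed_copy(w, w.values.copy()) for w in windows]
    else:
        noisy = []
        for w in windows:
            sd = w.values.std(axis=1, keepdims=True) * noise_fraction
            noisy.append(perturbed_copy(w, w.values + rng.normal(0, 1, w.values.shape) * sd))
    n_pred, n_mat = model.predict_batch(noisy)
    n_dec = [model.decode_concepts(m) for m in n_mat]
    same_pred = [p == q for p, q in zip(pred_idx, n_pred)]
    kept = [d == e for d, e, s in zip(decoded, n_dec, same_pred) if s]
    p2 = float(np.mean(kept)) if kept else 1.0

    shuffled = [perturbed_copy(w, shuffle_segments(w.values, n_shuffle_segments, rng))
                for w in windows]
    s_pred, s_mat = model.predict_batch(shuffled)
    s_dec = [model.decode_concepts(m) for m in s_mat]
    p3_pred = float(np.mean([p != q for p, q in zip(pred_idx, s_pred)]))
    p3_expl = float(np.mean([d != e for d, e in zip(decoded, s_dec)]))

    return FaithfulnessReport(
        p1_consistency=p1,
        n_explanation_groups=len(groups),
        p2_stability=p2,
        n_prediction_unchanged=int(sum(same_pred)),
        p3_prediction_changed=p3_pred,
        p3_explanation_changed=p3_expl,
        noise_fraction=noise_fraction,
        n_shuffle_segments=n_shuffle_segments,
        n=len(windows),
    )
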