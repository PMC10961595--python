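"""Explanations: decoded concept sequences and nearest-instance
counterfactuals.

A prediction is explained twice over: by the beam-decoded concept sequence
behind it, and by a *counterfactual* — the training-derived concept
sequence closest under Damerau-Levenshtein distance whose (model-assigned)
class differs from the prediction. Because counterfactuals are literal
training-set decodings, they are plausible by construction; because the
store records the model's own predicted classes, they are faithful to the
model's decision boundary rather than to the annotation.

The distance used here is the restricted (optimal string alignment)
Damerau-Levenshtein: single-concept insertions, deletions, substitutions,
and transpositions of two adjacent concepts, with no substring edited
twice.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "dl_distance",
    "ConceptStore",
    "build_store",
    "counterfactual",
    "explain",
    "Explanation",
    "concept_spans",
]


def dl_distance(a: Sequence, b: Sequence) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance:
    minimum insertions/deletions/substitutions of a single element or
    transpositions of two adjacent elements. Symmetric; 0 iff equal."""
    a, b = tuple(a), tuple(b)
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=int)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i, j] = min(d[i, j], d[i - 2, j - 2] + 1)
    return int(d[la, lb])


@dataclass
class ConceptStore:
    """Decoded (concept sequence, predicted class) pairs harvested once from
    the training set; the search pool for counterfactuals."""

    entries: list                    # [(tuple sequence, class label)]
    alphabet: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.entries = [(tuple(s), c) for s, c in self.entries]
        for seq, _ in self.entries:
            for concept in seq:
                if concept not in self.alphabet:
                    raise ValueError(f"store sequence uses unknown concept {concept!r}")

    def __len__(self):
        return len(self.entries)

    def to_json(self) -> dict:
        return {
            "entries": [{"sequence": list(s), "class": c} for s, c in self.entries],
            "alphabet": list(self.alphabet),
            "provenance": self.provenance,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ConceptStore":
        return cls(entries=[(tuple(e["sequence"]), e["class"]) for e in obj["entries"]],
                   alphabet=tuple(obj["alphabet"]),
                   provenance=obj.get("provenance", {}))

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path) -> "ConceptStore":
        return cls.from_json(json.loads(Path(path).read_text()))


def build_store(model, windows: Sequence, provenance: dict = None) -> ConceptStore:
    """Beam-decode every training window and record it with the model's
    *predicted* class (not the annotation)."""
    if not windows:
        raise ValueError("cannot build a concept store from an empty training set")
    pred_idx, matrices = model.predict_batch(windows)
    entries = [(model.decode_concepts(m), model.config.classes[i])
               for m, i in zip(matrices, pred_idx)]
    return ConceptStore(entries=entries, alphabet=tuple(model.config.concepts),
                        provenance=provenance or {})


@dataclass
class Explanation:
    """Decoded sequence plus nearest different-class counterfactual. When no
    different-class entry exists, `counterfactual` is None and `available`
    is False (an explicit result, not an error)."""

    sequence: tuple
    predicted_class: str
    counterfactual: tuple = None
    counterfactual_class: str = None
    distance: int = None
    spans: list = field(default_factory=list)  # [(concept, start, end)) in input samples
    available: bool = True

    def to_json(self) -> dict:
        d = asdict(self)
        d["sequence"] = list(self.sequence)
        d["counterfactual"] = list(self.counterfactual) if self.counterfactual else None
        d["spans"] = [[c, int(s), int(e)] for c, s, e in self.spans]
        return d

    @classmethod
    def from_json(cls, obj) -> "Explanation":
        if isinstance(obj, str):
            obj = json.loads(obj)
        return cls(
            sequence=tuple(obj["sequence"]),
            predicted_class=obj["predicted_class"],
            counterfactual=tuple(obj["counterfactual"]) if obj.get("counterfactual") else None,
            counterfactual_class=obj.get("counterfactual_class"),
            distance=obj.get("distance"),
            spans=[(c, s, e) for c, s, e in obj.get("spans", [])],
            available=obj.get("available", True),
        )


def counterfactual(store: ConceptStore, c_test: Sequence, predicted_class: str) -> Explanation:
    """Nearest different-class store entry under Damerau-Levenshtein
    distance. Distance-0 cross-class collisions (the identical sequence
    stored under another class) are rejected — they would contradict
    explanation-prediction consistency — and logged. Ties are broken toward
    the sequence most frequent in the store, then lexicographically."""
    if len(store) == 0:
        raise ValueError("concept store is empty")
    c_test = tuple(c_test)
    freq = Counter(seq for seq, _ in store.entries)
    best = None  # (distance, -frequency, sequence, class)
    for seq, cls in store.entries:
        if cls == predicted_class:
            continue
        d = dl_distance(c_test, seq)
        if d == 0:
            logger.warning(
                "faithfulness: sequence %s stored under %r but predicted %r for the query",
                seq, cls, predicted_class)
            continue
        key = (d, -freq[seq], seq)
        if best is None or key < best[0]:
            best = (key, seq, cls)
    if best is None:
        return Explanation(sequence=c_test, predicted_class=predicted_class,
                           available=False)
    (d, _, _), seq, cls = best
    return Explanation(sequence=c_test, predicted_class=predicted_class,
                       counterfactual=seq, counterfactual_class=cls, distance=d)


def concept_spans(matrix: np.ndarray, concepts: tuple, upsample: int) -> list:
    """Argmax runs of the concept matrix mapped back to the input timebase:
    [(concept, start_sample, end_sample)), blanks omitted."""
    path = np.argmax(matrix, axis=1)
    blank = len(concepts)
    spans, start = [], 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            if path[start] != blank:
                spans.append((concepts[path[start]], start * upsample, t * upsample))
            start = t
    return spans


def explain(model, store: ConceptStore, values) -> Explanation:
    """Full pipeline for one window: classify, beam-decode the concept
    sequence, attach per-concept alignment spans and the nearest
    different-class counterfactual."""
    label, _, matrix = model.predict(values)
    seq = model.decode_concepts(matrix)
    result = counterfactual(store, seq, label)
    upsample = model.config.fusion_stride * model.config.mix_stride
    result.spans = concept_spans(matrix, tuple(model.config.concepts), upsample)
    return result
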