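"""Synthetic benchmark generator for complex-activity recognition.

Real complex-activity corpora in this domain are built by concatenating
short sensor segments of *simple activities* (concepts) in a predefined
order per complex-activity class, keeping only the ordered concept-sequence
label — no start/end timestamps. This module emulates that construction so
the whole pipeline can be exercised offline: each concept is a parametric
band-limited waveform prototype (a per-channel sinusoid, standing in for an
accelerometer motif), rendered with a random duration and additive Gaussian
channel noise, optionally interleaved with low-amplitude filler motion that
carries no label (the stretches the blank token must absorb).

The canonical fixture is a 5-class, 6-concept nursing-activity grammar
(vitals, blood collection, blood glucose, oral care, patient cleaning,
drips), with 16 admissible concept sequences across the classes.

Coordinates are 0-based half-open sample intervals. The training-facing
view of a window is (values, class label, concept sequence); ground-truth
segment boundaries are retained in memory for diagnostics only and are
never serialized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GrammarError",
    "DatasetError",
    "ConceptGrammar",
    "ConceptPrototype",
    "SensorWindow",
    "make_nurse_like_grammar",
    "default_prototypes",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

MANIFEST_NAME = "manifest.json"
ARRAYS_NAME = "arrays.npz"


class GrammarError(ValueError):
    """Invalid grammar specification."""


class DatasetError(ValueError):
    """Malformed or inconsistent on-disk dataset."""


@dataclass(frozen=True)
class ConceptGrammar:
    """Class -> admissible concept sequences, over a fixed concept alphabet.

    Every sequence has length >= 2 (a complex activity is a pattern of at
    least two concept instances), and no sequence may appear under two
    classes — otherwise those classes would be indistinguishable from the
    sequence label alone.
    """

    concepts: tuple
    classes: tuple
    sequences: Mapping[str, tuple]

    def __post_init__(self):
        if len(set(self.concepts)) != len(self.concepts):
            raise GrammarError("duplicate concept identifiers")
        if len(set(self.classes)) != len(self.classes):
            raise GrammarError("duplicate class identifiers")
        if set(self.sequences) != set(self.classes):
            raise GrammarError("sequence map must cover exactly the declared classes")
        seen = {}
        for cls in self.classes:
            seqs = self.sequences[cls]
            if not seqs:
                raise GrammarError(f"class {cls!r} has no sequences")
            for seq in seqs:
                if len(seq) < 2:
                    raise GrammarError(
                        f"sequence {seq!r} of class {cls!r} has length < 2")
                for c in seq:
                    if c not in self.concepts:
                        raise GrammarError(
                            f"sequence of class {cls!r} uses unknown concept {c!r}")
                key = tuple(seq)
                if key in seen and seen[key] != cls:
                    raise GrammarError(
                        f"sequence {seq!r} appears under both {seen[key]!r} and {cls!r}")
                seen[key] = cls

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def concept_index(self, concept: str) -> int:
        return self.concepts.index(concept)

    def class_index(self, cls: str) -> int:
        return self.classes.index(cls)

    def encode(self, seq: Sequence[str]) -> tuple:
        return tuple(self.concept_index(c) for c in seq)

    def decode(self, idx_seq: Sequence[int]) -> tuple:
        return tuple(self.concepts[i] for i in idx_seq)

    def to_json(self) -> dict:
        return {
            "concepts": list(self.concepts),
            "classes": list(self.classes),
            "sequences": {cls: [list(s) for s in self.sequences[cls]]
                          for cls in self.classes},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ConceptGrammar":
        return cls(
            concepts=tuple(obj["concepts"]),
            classes=tuple(obj["classes"]),
            sequences={k: tuple(tuple(s) for s in v)
                       for k, v in obj["sequences"].items()},
        )


@dataclass(frozen=True)
class ConceptPrototype:
    """Parametric waveform for one concept: per-channel sinusoid parameters
    plus a duration range in samples (half-open draws are inclusive of both
    endpoints)."""

    concept: str
    frequencies: tuple   # cycles per sample, one per channel
    amplitudes: tuple
    offsets: tuple
    phases: tuple
    duration_range: tuple  # (min, max) samples, min >= 1

    def __post_init__(self):
        lo, hi = self.duration_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad duration range {self.duration_range} for {self.concept!r}")
        n = len(self.frequencies)
        if not (len(self.amplitudes) == len(self.offsets) == len(self.phases) == n):
            raise ValueError("per-channel parameter tuples must have equal length")

    @property
    def n_channels(self) -> int:
        return len(self.frequencies)

    def render(self, duration: int) -> np.ndarray:
        """Noise-free realization, shape [channels, duration]."""
        t = np.arange(duration)
        rows = [a * np.sin(2 * math.pi * f * t + ph) + off
                for f, a, off, ph in zip(self.frequencies, self.amplitudes,
                                         self.offsets, self.phases)]
        return np.stack(rows)


@dataclass
class SensorWindow:
    """One multivariate sample: values [S, T], its complex-activity label and
    its weak (order-only) concept-sequence label. `boundaries` holds the
    generator's hidden segment log [(concept, start, end)) — diagnostics
    only, never exported."""

    values: np.ndarray
    label: str
    concepts: tuple
    boundaries: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("window values must be 2-D [channels, samples]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")
        if len(self.concepts) < 2:
            raise ValueError("concept sequence must have length >= 2")
        T = self.values.shape[1]
        prev_end = 0
        for _, start, end in self.boundaries:
            if not (0 <= start < end <= T) or start < prev_end:
                raise ValueError("boundaries must be sorted, non-overlapping, within [0, T)")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def make_nurse_like_grammar() -> ConceptGrammar:
    """The canonical 5-class, 6-concept nursing-activity grammar (16
    admissible sequences)."""
    V, B, G, O, C, D = ("vitals", "blood_collection", "blood_glucose",
                        "oral_care", "clean", "drips")
    sequences = {
        "Physiological Measurement": (
            (V, B, G),
            (B, V, G),
        ),
        "Patient Cleaning": (
            (V, O, C),
            (O, V, C),
            (O, G, C),
            (G, O, C),
        ),
        "Unsanitary Operations": (
            (C, G, V),
            (C, O, V),
            (V, C, O),
            (O, C, G),
        ),
        "Safe IV/Drips Procedure": (
            (V, B, D, V),
            (V, D, V),
            (V, D, B, V),
        ),
        "Unsafe IV/Drips Procedure": (
            (V, B, D),
            (B, D, V),
            (D, B, V),
        ),
    }
    return ConceptGrammar(
        concepts=(V, B, G, O, C, D),
        classes=tuple(sequences),
        sequences=sequences,
    )


def default_prototypes(grammar: ConceptGrammar, n_channels: int = 3,
                       duration_range: tuple = (120, 240)) -> dict:
    """Deterministic prototype bank: concept i gets a distinct base frequency
    (spread below the Nyquist of a 4 Hz-equivalent stream), with per-channel
    amplitude and phase variation so channels are correlated but not
    identical. `duration_range` defaults to 30-60 s at 4 Hz."""
    protos = {}
    M = grammar.n_concepts
    for i, concept in enumerate(grammar.concepts):
        base_f = 0.05 + 0.28 * i / max(M - 1, 1)  # cycles/sample in [0.05, 0.33]
        freqs, amps, offs, phases = [], [], [], []
        for c in range(n_channels):
            freqs.append(base_f * (1.0 + 0.05 * c))
            amps.append(1.0 + 0.25 * ((i + c) % 3))
            offs.append(0.1 * ((i + 2 * c) % 3 - 1))
            phases.append(0.5 * math.pi * c)
        protos[concept] = ConceptPrototype(
            concept=concept,
            frequencies=tuple(freqs),
            amplitudes=tuple(amps),
            offsets=tuple(offs),
            phases=tuple(phases),
            duration_range=tuple(duration_range),
        )
    return protos


def generate_dataset(grammar: ConceptGrammar, prototypes: Mapping[str, ConceptPrototype],
                     n_per_class: int, noise_sd: float = 0.25,
                     filler_prob: float = 0.5, seed: int = 0,
                     filler_range: tuple = (0, 40),
                     filler_sd: float = 0.15) -> list:
    """Draw `n_per_class` windows per class: pick a sequence uniformly from
    the class's set, render each concept at a uniformly drawn duration with
    additive Gaussian channel noise, and with probability `filler_prob`
    insert an unlabeled low-amplitude filler segment between consecutive
    concepts. Deterministic given `seed`."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    missing = [c for c in grammar.concepts if c not in prototypes]
    if missing:
        raise GrammarError(f"no prototype for concepts: {missing}")
    n_ch = {p.n_channels for p in prototypes.values()}
    if len(n_ch) != 1:
        raise GrammarError("all prototypes must agree on channel count")
    S = n_ch.pop()

    rng = np.random.default_rng(seed)
    windows = []
    for cls in grammar.classes:
        seqs = grammar.sequences[cls]
        for _ in range(n_per_class):
            seq = seqs[rng.integers(len(seqs))]
            segments, boundaries, pos = [], [], 0
            for j, concept in enumerate(seq):
                if j > 0 and filler_prob > 0 and rng.random() < filler_prob:
                    flen = int(rng.integers(filler_range[0], filler_range[1] + 1))
                    if flen > 0:
                        seg = rng.normal(0.0, filler_sd, size=(S, flen))
                        segments.append(seg)
                        pos += flen
                proto = prototypes[concept]
                lo, hi = proto.duration_range
                dur = int(rng.integers(lo, hi + 1))
                seg = proto.render(dur)
                if noise_sd > 0:
                    seg = seg + rng.normal(0.0, noise_sd, size=seg.shape)
                segments.append(seg)
                boundaries.append((concept, pos, pos + dur))
                pos += dur
            values = np.concatenate(segments, axis=1)
            windows.append(SensorWindow(values=values, label=cls,
                                        concepts=tuple(seq), boundaries=boundaries))
    return windows


def write_dataset(windows: Sequence[SensorWindow], directory, *,
                  grammar: ConceptGrammar = None, params: dict = None,
                  fmt: str = "npz") -> Path:
    """Persist windows as a JSON manifest plus a consolidated .npz container
    (or per-window CSV files with channels as columns, fmt="csv"). Only the
    training-facing view is written: values, class label, concept sequence.
    Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("npz", "csv"):
        raise ValueError(f"unknown dataset format {fmt!r}")
    entries = []
    arrays = {}
    for i, w in enumerate(windows):
        key = f"w{i:05d}"
        entries.append({
            "id": key,
            "class": w.label,
            "concepts": list(w.concepts),
            "channels": int(w.n_channels),
            "length": int(w.n_samples),
        })
        if fmt == "npz":
            arrays[key] = w.values
        else:
            np.savetxt(directory / f"{key}.csv", w.values.T, delimiter=",")
    manifest = {
        "format": fmt,
        "grammar": grammar.to_json() if grammar is not None else None,
        "generator": params or {},
        "windows": entries,
    }
    if fmt == "npz":
        np.savez(directory / ARRAYS_NAME, **arrays)
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(directory) -> tuple:
    """Load (windows, grammar, params) written by `write_dataset`.

    Raises DatasetError on a malformed manifest, a missing array, or a
    concept-sequence label referencing a concept outside the grammar."""
    directory = Path(directory)
    path = directory / MANIFEST_NAME
    if not path.exists():
        raise DatasetError(f"no {MANIFEST_NAME} in {directory} (empty dataset?)")
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetError(f"malformed manifest: {exc}") from exc
    for field_name in ("format", "windows"):
        if field_name not in manifest:
            raise DatasetError(f"manifest missing field {field_name!r}")
    grammar = (ConceptGrammar.from_json(manifest["grammar"])
               if manifest.get("grammar") else None)
    fmt = manifest["format"]
    npz = None
    if fmt == "npz":
        arr_path = directory / ARRAYS_NAME
        if not arr_path.exists():
            raise DatasetError(f"missing array container {ARRAYS_NAME}")
        npz = np.load(arr_path)
    windows = []
    for entry in manifest["windows"]:
        key = entry["id"]
        if grammar is not None:
            for c in entry["concepts"]:
                if c not in grammar.concepts:
                    raise DatasetError(f"window {key}: unknown concept {c!r}")
            if entry["class"] not in grammar.classes:
                raise DatasetError(f"window {key}: unknown class {entry['class']!r}")
        if fmt == "npz":
            if key not in npz:
                raise DatasetError(f"window {key}: array missing from container")
            values = npz[key]
        else:
            csv_path = directory / f"{key}.csv"
            if not csv_path.exists():
                raise DatasetError(f"window {key}: missing file {csv_path.name}")
            values = np.loadtxt(csv_path, delimiter=",").T
        if values.shape != (entry["channels"], entry["length"]):
            raise DatasetError(f"window {key}: shape mismatch with manifest")
        windows.append(SensorWindow(values=values, label=entry["class"],
                                    concepts=tuple(entry["concepts"])))
    return windows, grammar, manifest.get("generator", {})
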