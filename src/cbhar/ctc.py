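"""Alignment machinery for the temporal concept bottleneck.

A concept matrix assigns, at every output timestep, a probability
distribution over the M task concepts plus a blank token that stands for
semantically meaningless stretches of signal. An *alignment* is a length-T
path over concepts-plus-blank; collapsing an alignment (merge immediate
repeats, then drop blanks) yields a concept sequence. The CTC likelihood of
a target sequence is the total probability of all alignments that collapse
to it; the loss is its negative log, computed here by the standard
blank-augmented forward recursion in log space so it can be differentiated
for training. Decoding goes the other way: prefix beam search merges
alignments sharing a collapsed prefix (that merging is the
marginalization) and returns the most probable concept sequences.

Concepts are integer indices ``0..M-1``; index ``M`` (the last matrix
column) is reserved for the blank.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import (
    NEG_INF,
    Tensor,
    concat,
    gather_last,
    logsumexp,
    stack,
    where,
)

__all__ = [
    "collapse",
    "enumerate_alignments",
    "min_path_length",
    "ctc_loss",
    "ctc_loss_batch",
    "DecodeResult",
    "beam_decode",
]


def collapse(path: Sequence[int], blank: int) -> tuple:
    """Collapse an alignment: merge consecutive identical non-blank symbols,
    then delete blanks. A blank between two identical concepts keeps them as
    two occurrences."""
    out = []
    prev = None
    for sym in path:
        s = int(sym)
        if s < 0 or s > blank:
            raise ValueError(f"unknown symbol {s} for alphabet of size {blank} + blank")
        if s != prev:
            if s != blank:
                out.append(s)
            prev = s
    return tuple(out)


def enumerate_alignments(target: Sequence[int], n_steps: int, n_concepts: int):
    """Oracle: the exact set of length-`n_steps` paths over concepts+blank
    whose collapse equals `target`. Exponential in `n_steps`; for tests only."""
    blank = n_concepts
    tgt = tuple(int(c) for c in target)
    result = set()
    for path in itertools.product(range(n_concepts + 1), repeat=n_steps):
        if collapse(path, blank) == tgt:
            result.add(path)
    return result


def min_path_length(target: Sequence[int]) -> int:
    """Shortest alignment able to produce `target`: one step per concept plus
    a mandatory separating blank between adjacent repeats."""
    tgt = list(target)
    repeats = sum(1 for a, b in zip(tgt, tgt[1:]) if a == b)
    return len(tgt) + repeats


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("concept matrix must be 2-D [T, M+1]")
    if np.any(matrix < -1e-9) or np.any(matrix > 1 + 1e-9):
        raise ValueError("concept matrix entries must lie in [0, 1]")
    rows = matrix.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-6):
        raise ValueError("concept matrix rows must each sum to 1")
    return matrix


def ctc_loss_batch(log_probs: Tensor, targets: list, input_lens: np.ndarray) -> Tensor:
    """Negative log-likelihood of each target under its concept matrix.

    `log_probs` is a [B, T, M+1] tensor of per-timestep log-distributions
    (blank last); `targets` a list of B non-empty integer sequences;
    `input_lens` the valid timestep count per sample (rows at or beyond it
    are padding and are ignored). Returns a [B] tensor, differentiable with
    respect to `log_probs`.
    """
    B, T, V = log_probs.shape
    blank = V - 1
    lens = [len(t) for t in targets]
    if min(lens) < 1:
        raise ValueError("CTC target must be non-empty")
    kmax = max(lens)
    S = 2 * kmax + 1
    z = np.full((B, S), blank, dtype=np.intp)
    for b, tgt in enumerate(targets):
        if any(int(c) < 0 or int(c) >= blank for c in tgt):
            raise ValueError("CTC target symbol outside concept alphabet (blank not allowed)")
        z[b, 1:2 * len(tgt):2] = np.asarray(tgt, dtype=np.intp)
    # states reachable by a skip from s-2: non-blank and different from z[s-2]
    allow2 = np.zeros((B, S), dtype=bool)
    allow2[:, 2:] = (z[:, 2:] != blank) & (z[:, 2:] != z[:, :-2])

    input_lens = np.asarray(input_lens, dtype=np.intp)
    neg_col = Tensor(np.full((B, 1), NEG_INF))
    neg_col2 = Tensor(np.full((B, 2), NEG_INF))
    init = np.full((1, S), NEG_INF)
    init[0, :2] = 0.0

    lp0 = gather_last(log_probs[:, 0, :], z)
    alpha = lp0 + Tensor(init)
    for t in range(1, T):
        lp_t = gather_last(log_probs[:, t, :], z)
        a1 = concat([neg_col, alpha[:, :-1]], axis=1)
        a2 = concat([neg_col2, alpha[:, :-2]], axis=1)
        a2 = where(allow2, a2, Tensor(np.full((B, S), NEG_INF)))
        new = logsumexp(stack([alpha, a1, a2], axis=0), axis=0) + lp_t
        active = (t < input_lens)[:, None]
        alpha = where(np.broadcast_to(active, (B, S)), new, alpha)

    fin_idx = np.stack([2 * np.asarray(lens) - 1, 2 * np.asarray(lens)], axis=1)
    fin = gather_last(alpha, fin_idx)
    return -logsumexp(fin, axis=1)


def ctc_loss(matrix: np.ndarray, target: Sequence[int]) -> float:
    """-log p(target | matrix) for a single [T, M+1] concept matrix.

    Returns +inf when no alignment exists (target too long for T). An empty
    target is scored as the all-blank path. Raises if the target contains
    the blank index or symbols outside the alphabet.
    """
    matrix = _validate_matrix(matrix)
    T, V = matrix.shape
    blank = V - 1
    tgt = [int(c) for c in target]
    if any(c == blank for c in tgt):
        raise ValueError("CTC target must not contain the blank token")
    if any(c < 0 or c >= blank for c in tgt):
        raise ValueError("CTC target symbol outside concept alphabet")
    if len(tgt) == 0:
        with np.errstate(divide="ignore"):
            lp = np.log(matrix[:, blank])
        total = float(lp.sum())
        return math.inf if not np.isfinite(total) else -total
    if min_path_length(tgt) > T:
        return math.inf
    with np.errstate(divide="ignore"):
        logp = np.log(np.maximum(matrix, 0.0))
    logp = np.maximum(logp, NEG_INF)
    out = ctc_loss_batch(Tensor(logp[None]), [tgt], np.array([T]))
    val = float(out.data[0])
    return math.inf if val > -NEG_INF / 2 else val


@dataclass
class DecodeResult:
    """Ranked output of prefix beam search over a concept matrix."""

    sequence: tuple
    probability: float
    beam: list = field(default_factory=list)  # [(sequence, probability)] descending

    def to_json(self) -> dict:
        return {
            "sequence": list(self.sequence),
            "probability": self.probability,
            "beam": [{"sequence": list(s), "probability": p} for s, p in self.beam],
        }


def _rank_key(item):
    seq, p = item
    return (-p, len(seq), seq)


def beam_decode(matrix: np.ndarray, beam_width: int = 25) -> DecodeResult:
    """Prefix beam search: the returned probability of a sequence is its
    alignment-marginal, obtained by merging all paths whose collapsed prefix
    coincides. With `beam_width` at least (M+1)^T this is exact. Ties are
    broken toward higher probability, then shorter sequence, then
    lexicographic concept order."""
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    matrix = _validate_matrix(matrix)
    T, V = matrix.shape
    blank = V - 1
    # prefix -> [p ending in blank, p ending in non-blank]
    beams = {(): [1.0, 0.0]}
    for t in range(T):
        probs = matrix[t]
        new: dict = {}

        def acc(prefix, pb, pnb):
            cur = new.get(prefix)
            if cur is None:
                new[prefix] = [pb, pnb]
            else:
                cur[0] += pb
                cur[1] += pnb

        for prefix, (pb, pnb) in beams.items():
            total = pb + pnb
            acc(prefix, total * probs[blank], 0.0)
            if prefix:
                acc(prefix, 0.0, pnb * probs[prefix[-1]])
            for c in range(blank):
                p = probs[c]
                if p == 0.0:
                    continue
                if prefix and c == prefix[-1]:
                    acc(prefix + (c,), 0.0, pb * p)  # repeat needs a blank first
                else:
                    acc(prefix + (c,), 0.0, total * p)
        ranked = sorted(((seq, v[0] + v[1]) for seq, v in new.items()), key=_rank_key)
        beams = {seq: new[seq] for seq, _ in ranked[:beam_width]}

    final = sorted(((seq, v[0] + v[1]) for seq, v in beams.items()), key=_rank_key)
    best, best_p = final[0]
    return DecodeResult(sequence=best, probability=float(best_p),
                        beam=[(s, float(p)) for s, p in final])
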