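"""Alignment semantics: collapse, exact loss, enumeration oracle, decoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cbhar as cb
from cbhar.autodiff import Tensor
from cbhar.ctc import ctc_loss_batch

from conftest import marginalize_exhaustively, random_concept_matrix


class TestCollapse:
    @pytest.mark.parametrize("path,expected", [
        ([2, 0, 0, 2, 1], (0, 1)),   # merge repeats, drop blanks
        ([0, 2, 0], (0, 0)),          # blank separates a repeat
        ([2, 2, 2], ()),              # all-blank path is the empty sequence
        ([], ()),
        ([1, 1, 1], (1,)),
    ])
    def test_rule(self, path, expected):
        assert cb.collapse(path, blank=2) == expected

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            cb.collapse([0, 5], blank=2)

    @given(st.lists(st.integers(0, 3), max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent_on_repeat_free_outputs(self, path):
        """Outputs contain no blanks; re-collapsing only merges the adjacent
        duplicates that a separating blank legitimately left behind, so on
        repeat-free outputs collapse is idempotent."""
        seq = cb.collapse(path, blank=3)
        assert 3 not in seq
        merged = tuple(s for i, s in enumerate(seq) if i == 0 or s != seq[i - 1])
        assert cb.collapse(seq, blank=3) == merged
        if all(a != b for a, b in zip(seq, seq[1:])):
            assert cb.collapse(seq, blank=3) == seq


class TestEnumerate:
    def test_two_symbol_target_in_three_steps(self):
        paths = cb.enumerate_alignments([0, 1], 3, 2)
        assert paths == {(0, 0, 1), (0, 1, 1), (0, 1, 2), (0, 2, 1), (2, 0, 1)}

    def test_repeat_needs_separating_blank(self):
        assert cb.enumerate_alignments([0, 0], 2, 1) == set()
        assert cb.enumerate_alignments([0, 0], 3, 1) == {(0, 1, 0)}

    def test_single_step(self):
        assert cb.enumerate_alignments([0], 1, 1) == {(0,)}


class TestCtcLoss:
    def test_uniform_matrix_worked_case(self):
        """Uniform rows over {A, B, blank} at T=3 for target [A, B]: five
        alignments, each with probability 3^-3."""
        mat = np.full((3, 3), 1.0 / 3.0)
        assert cb.ctc_loss(mat, [0, 1]) == pytest.approx(-math.log(5 / 27), abs=1e-12)

    def test_certain_path_gives_zero_loss(self):
        assert cb.ctc_loss(np.array([[1.0, 0.0]]), [0]) == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_target(self):
        assert cb.ctc_loss(np.full((1, 3), 1 / 3), [0, 1]) == math.inf
        assert cb.ctc_loss(np.full((2, 2), 1 / 2), [0, 0]) == math.inf

    def test_blank_in_target_rejected(self):
        with pytest.raises(ValueError):
            cb.ctc_loss(np.full((3, 3), 1 / 3), [0, 2])

    def test_bad_matrix_rejected(self):
        with pytest.raises(ValueError):
            cb.ctc_loss(np.ones((3, 3)), [0])

    def test_empty_target_scores_all_blank_path(self):
        mat = np.array([[0.3, 0.7], [0.4, 0.6]])
        assert cb.ctc_loss(mat, []) == pytest.approx(-math.log(0.7 * 0.6))

    def test_oracle_equivalence_random(self):
        """exp(-loss) equals the enumerated alignment-probability sum."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            T = int(rng.integers(1, 7))
            M = int(rng.integers(1, 4))
            mat = random_concept_matrix(rng, T, M)
            k = int(rng.integers(1, 4))
            target = [int(c) for c in rng.integers(0, M, size=k)]
            paths = cb.enumerate_alignments(target, T, M)
            expected = sum(math.prod(mat[t, s] for t, s in enumerate(p)) for p in paths)
            loss = cb.ctc_loss(mat, target)
            if expected == 0.0:
                assert loss == math.inf
            else:
                assert math.exp(-loss) == pytest.approx(expected, abs=1e-8)

    def test_normalization_over_all_sequences(self):
        """Marginal probabilities of all collapsed sequences sum to one."""
        rng = np.random.default_rng(3)
        mat = random_concept_matrix(rng, 5, 2)
        marg = marginalize_exhaustively(mat)
        assert sum(marg.values()) == pytest.approx(1.0, abs=1e-9)
        for seq, p in marg.items():
            if seq:
                assert math.exp(-cb.ctc_loss(mat, list(seq))) == pytest.approx(p, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        from cbhar.autodiff import log_softmax
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(1, 4, 3))
        target = [0, 1]

        def loss_of(lg):
            z = lg - np.log(np.exp(lg).sum(-1, keepdims=True))
            return float(ctc_loss_batch(Tensor(z), [target], np.array([4])).data[0])

        t = Tensor(logits, requires_grad=True)
        out = ctc_loss_batch(log_softmax(t, axis=-1), [target], np.array([4]))
        out.backward(np.ones(1))
        eps = 1e-6
        for i in np.ndindex(logits.shape):
            lg = logits.copy(); lg[i] += eps
            up = loss_of(lg)
            lg = logits.copy(); lg[i] -= eps
            down = loss_of(lg)
            assert t.grad[i] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestBeamDecode:
    def test_certain_concept(self):
        mat = np.zeros((4, 3)); mat[:, 1] = 1.0
        res = cb.beam_decode(mat, 5)
        assert res.sequence == (1,) and res.probability == pytest.approx(1.0)

    def test_marginalization_beats_greedy(self):
        """Per-step argmax is blank-blank, but [A] accumulates 0.64 of the
        path mass against 0.36 for the empty sequence."""
        mat = np.array([[0.4, 0.6], [0.4, 0.6]])
        res = cb.beam_decode(mat, 4)
        assert res.sequence == (0,)
        assert res.probability == pytest.approx(0.64, abs=1e-12)
        assert dict(res.beam)[()] == pytest.approx(0.36, abs=1e-12)

    def test_oracle_equivalence_exhaustive_width(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            T = int(rng.integers(1, 6))
            M = int(rng.integers(1, 4))
            mat = random_concept_matrix(rng, T, M)
            res = cb.beam_decode(mat, (M + 1) ** T)
            marg = marginalize_exhaustively(mat)
            best = min(marg.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
            assert res.sequence == best[0]
            assert res.probability == pytest.approx(best[1], abs=1e-10)

    def test_widening_beam_never_hurts(self):
        rng = np.random.default_rng(9)
        mat = random_concept_matrix(rng, 6, 3)
        probs = [cb.beam_decode(mat, w).probability for w in (1, 2, 4, 8, 64, 4096)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_beam_sorted_and_bounded(self):
        rng = np.random.default_rng(11)
        mat = random_concept_matrix(rng, 5, 2)
        res = cb.beam_decode(mat, 6)
        ps = [p for _, p in res.beam]
        assert ps == sorted(ps, reverse=True)
        assert len(res.beam) <= 6
        assert res.beam[0][0] == res.sequence
        assert all(0 < p <= 1 for p in ps)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            cb.beam_decode(np.full((2, 2), 0.5), 0)
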