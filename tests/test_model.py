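"""Network wiring, shapes, determinism, and the joint training loop."""

import numpy as np
import pytest

import cbhar as cb
from cbhar.model import ModelConfig, _reverse_idx


def tiny_config(grammar, **kw):
    defaults = dict(concepts=grammar.concepts, classes=grammar.classes,
                    seed=0, epochs=2, batch_size=8)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestForward:
    def test_output_timebase_quarters_input(self, grammar):
        cfg = tiny_config(grammar)
        model = cb.build_model(cfg)
        x = np.zeros((2, 3, 1024))
        out = model.forward(x, np.array([1024, 1000]))
        assert out.concept_log_probs.shape == (2, 256, 7)
        assert out.class_log_probs.shape == (2, 5)
        assert list(out.out_lens) == [256, 250]
        assert cfg.out_len(1024) == 256

    def test_distributions_normalized_and_finite_on_zero_input(self, grammar):
        model = cb.build_model(tiny_config(grammar))
        out = model.forward(np.zeros((1, 3, 128)), np.array([128]))
        cm = out.concept_matrix(0)
        assert np.all(np.isfinite(cm))
        np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(out.class_probs(0).sum(), 1.0, atol=1e-6)

    def test_seeded_build_is_deterministic(self, grammar, small_dataset):
        a = cb.build_model(tiny_config(grammar))
        b = cb.build_model(tiny_config(grammar))
        a.fit_normalizer(small_dataset)
        b.fit_normalizer(small_dataset)
        xa = a.forward_windows(small_dataset[:3])
        xb = b.forward_windows(small_dataset[:3])
        np.testing.assert_array_equal(xa.concept_log_probs.data,
                                      xb.concept_log_probs.data)
        np.testing.assert_array_equal(xa.class_log_probs.data,
                                      xb.class_log_probs.data)

    def test_identical_windows_in_batch_get_identical_outputs(self, grammar, small_dataset):
        model = cb.build_model(tiny_config(grammar))
        model.fit_normalizer(small_dataset)
        w = small_dataset[0]
        out = model.forward_windows([w, w])
        np.testing.assert_allclose(out.concept_log_probs.data[0],
                                   out.concept_log_probs.data[1], atol=1e-12)

    def test_channel_permutation_wiring(self, grammar, small_dataset):
        """Permuting input channels together with the per-sensor conv stems
        (and the matching blocks of the cross-sensor kernel) leaves the
        output unchanged — each sensor has its own stem."""
        cfg = tiny_config(grammar)
        model = cb.build_model(cfg)
        model.fit_normalizer(small_dataset)
        perm = [2, 0, 1]
        permuted = cb.build_model(cfg)
        permuted.norm_mean = model.norm_mean[perm]
        permuted.norm_sd = model.norm_sd[perm]
        f1 = cfg.fusion_filters
        blocks = []
        for new_s, old_s in enumerate(perm):
            permuted.params[f"fuse_w{new_s}"].data = model.params[f"fuse_w{old_s}"].data
            permuted.params[f"fuse_b{new_s}"].data = model.params[f"fuse_b{old_s}"].data
            blocks.append(model.params["mix_w"].data[:, old_s * f1:(old_s + 1) * f1, :])
        permuted.params["mix_w"].data = np.concatenate(blocks, axis=1)
        for key in ("mix_b", "lstm_f_wx", "lstm_f_wh", "lstm_f_b", "lstm_b_wx",
                    "lstm_b_wh", "lstm_b_b", "bott_w", "bott_b", "clf_w", "clf_b",
                    "out_w", "out_b"):
            permuted.params[key].data = model.params[key].data
        w = small_dataset[0]
        base = model.forward_windows([w])
        pw = cb.SensorWindow(values=w.values[perm], label=w.label, concepts=w.concepts)
        swapped = permuted.forward_windows([pw])
        np.testing.assert_allclose(base.concept_log_probs.data,
                                   swapped.concept_log_probs.data, atol=1e-10)

    def test_too_short_input_reports_minimum(self, grammar):
        model = cb.build_model(tiny_config(grammar))
        with pytest.raises(ValueError, match=str(model.config.min_input_length)):
            model.forward(np.zeros((1, 3, 8)), np.array([8]))

    def test_channel_mismatch_rejected(self, grammar, small_dataset):
        model = cb.build_model(tiny_config(grammar, n_channels=4))
        with pytest.raises(ValueError):
            model.batchify(small_dataset[:1])

    def test_reverse_index_reverses_only_valid_prefix(self):
        idx = _reverse_idx(np.array([3, 5]), 5)
        np.testing.assert_array_equal(idx[0], [2, 1, 0, 3, 4])
        np.testing.assert_array_equal(idx[1], [4, 3, 2, 1, 0])


class TestConfig:
    def test_invalid_beta(self, grammar):
        with pytest.raises(ValueError):
            tiny_config(grammar, beta=1.5)

    def test_round_trip(self, grammar):
        cfg = tiny_config(grammar, beta=0.25)
        assert ModelConfig.from_json(cfg.to_json()) == cfg


@pytest.fixture(scope="module")
def short_run(grammar, prototypes):
    ds = cb.generate_dataset(grammar, prototypes, n_per_class=4, seed=3)
    cfg = tiny_config(grammar, epochs=2)
    model = cb.build_model(cfg)
    history = cb.train(model, ds, ds[:8])
    return model, history, ds


class TestTraining:
    def test_history_shape_and_loss_identity(self, short_run):
        _, history, _ = short_run
        assert len(history.total) == 2
        for tot, ly, lc in zip(history.total, history.class_loss,
                               history.concept_loss):
            assert tot == pytest.approx(0.5 * ly + 0.5 * lc, abs=1e-6)
        assert history.best_epoch >= 0
        assert all(0 <= f <= 1 for f in history.val_macro_f1)

    def test_loss_identity_respects_beta(self, grammar, prototypes):
        ds = cb.generate_dataset(grammar, prototypes, n_per_class=2, seed=4)
        cfg = tiny_config(grammar, epochs=1, beta=0.3)
        model = cb.build_model(cfg)
        history = cb.train(model, ds, ds[:5])
        assert history.total[0] == pytest.approx(
            0.3 * history.class_loss[0] + 0.7 * history.concept_loss[0], abs=1e-6)

    def test_save_load_round_trip(self, short_run, tmp_path):
        model, _, ds = short_run
        model.save(tmp_path / "ckpt")
        clone = cb.Model.load(tmp_path / "ckpt")
        a = model.forward_windows(ds[:2])
        b = clone.forward_windows(ds[:2])
        np.testing.assert_array_equal(a.class_log_probs.data, b.class_log_probs.data)

    def test_predict_is_argmax_of_probs(self, short_run):
        model, _, ds = short_run
        label, probs, matrix = model.predict(ds[0].values)
        assert label == model.config.classes[int(np.argmax(probs))]
        assert matrix.shape == (model.config.out_len(ds[0].n_samples), 7)

    def test_infeasible_target_reported_with_window_id(self, grammar):
        cfg = tiny_config(grammar)
        model = cb.build_model(cfg)
        seq = tuple(grammar.concepts[i % 2] for i in range(9))
        w = cb.SensorWindow(values=np.zeros((3, 32)), label=grammar.classes[0],
                            concepts=seq)
        with pytest.raises(ValueError, match="window 0"):
            cb.train(model, [w], [w])

    def test_unknown_label_rejected(self, grammar, small_dataset):
        cfg = ModelConfig(concepts=grammar.concepts, classes=("only",), seed=0)
        model = cb.build_model(cfg)
        with pytest.raises(ValueError):
            cb.train(model, small_dataset[:2], small_dataset[:2])


class TestIdealMatrix:
    def test_one_hot_rows_follow_segment_log(self, grammar, small_dataset):
        cfg = tiny_config(grammar)
        w = small_dataset[0]
        mat = cb.ideal_concept_matrix(w, cfg)
        assert mat.shape == (cfg.out_len(w.n_samples), 7)
        np.testing.assert_array_equal(mat.sum(axis=1), 1.0)
        idx = {c: i for i, c in enumerate(cfg.concepts)}
        for concept, start, end in w.boundaries:
            center_step = (start + end) // 2 // 4
            assert mat[center_step, idx[concept]] == 1.0

    def test_requires_segment_log(self, grammar):
        cfg = tiny_config(grammar)
        w = cb.SensorWindow(values=np.zeros((3, 64)), label=grammar.classes[0],
                            concepts=(grammar.concepts[0], grammar.concepts[1]))
        with pytest.raises(ValueError):
            cb.ideal_concept_matrix(w, cfg)
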