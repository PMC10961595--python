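"""The recognizer: sensor fusion, temporal concept bottleneck, classifier.

Architecture (all sizes configurable, defaults below):

* sensor fusion — one 1-D conv per sensor channel (64 filters, kernel 16,
  stride 2, ReLU), feature maps concatenated across sensors, then one
  cross-sensor 1-D conv (128 filters, kernel 16, stride 2, ReLU). Two
  stride-2 stages give an output timebase T' = ceil(ceil(T/2)/2).
* temporal concept bottleneck — a bi-directional LSTM (128 units per
  direction) over the fused features, a time-distributed dense layer to
  M+1 outputs and a softmax: row t is a probability distribution over the
  M concepts plus the blank token. Trained with the CTC loss against the
  order-only concept-sequence label.
* classifier — consumes ONLY the M+1 softmax channels (nothing upstream):
  one causal temporal convolution (64 filters, kernel 8, stride 1), ReLU,
  masked global average pooling over valid timesteps, dense softmax over
  the L complex-activity classes. Trained with categorical cross-entropy.

The joint objective is L = beta * L_class + (1 - beta) * L_concept with
beta = 0.5 by default, optimized end-to-end with Adam. Per-channel z-score
normalization is fitted on the training set and stored with the model.
Everything is seeded and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .ctc import beam_decode, ctc_loss_batch, min_path_length
from .metrics import levenshtein, macro_f1
from .synthetic import SensorWindow

__all__ = [
    "ModelConfig",
    "ForwardOutput",
    "TrainHistory",
    "Model",
    "build_model",
    "train",
    "ideal_concept_matrix",
    "ConceptClassifier",
]


@dataclass
class ModelConfig:
    concepts: tuple          # M concept identifiers, in bottleneck output order
    classes: tuple           # L class identifiers, in classifier output order
    n_channels: int = 3      # S
    fusion_filters: int = 64
    fusion_kernel: int = 16
    fusion_stride: int = 2
    mix_filters: int = 128
    mix_kernel: int = 16
    mix_stride: int = 2
    lstm_units: int = 128
    clf_filters: int = 64
    clf_kernel: int = 8
    clf_stride: int = 1
    clf_dilation: int = 4
    beta: float = 0.5        # weight of the class loss in the joint objective
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    patience: int = 10
    grad_clip: float = 5.0
    beam_width: int = 25
    seed: int = 0

    def __post_init__(self):
        self.concepts = tuple(self.concepts)
        self.classes = tuple(self.classes)
        if not self.concepts or not self.classes:
            raise ValueError("concepts and classes must be non-empty")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        for name in ("n_channels", "fusion_filters", "mix_filters", "lstm_units",
                     "clf_filters", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def min_input_length(self) -> int:
        """Smallest T for which every kernel fits its stage's input."""
        t = self.fusion_kernel
        t = max(t, (self.mix_kernel - 1) * self.fusion_stride + 1)
        t = max(t, (self.clf_kernel - 1) * self.fusion_stride * self.mix_stride + 1)
        return t

    def out_len(self, T: int) -> int:
        """Bottleneck timebase T' for an input of T samples."""
        t1 = -(-T // self.fusion_stride)
        return -(-t1 // self.mix_stride)

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "ModelConfig":
        obj = dict(obj)
        obj["concepts"] = tuple(obj["concepts"])
        obj["classes"] = tuple(obj["classes"])
        return cls(**obj)


@dataclass
class ForwardOutput:
    """Concept matrices (softmax rows over M concepts + blank) and class
    probability vectors for one batch; `out_lens[b]` rows of sample b's
    matrix are valid."""

    concept_log_probs: Tensor   # [B, T', M+1]
    class_log_probs: Tensor     # [B, L]
    out_lens: np.ndarray        # [B]

    def concept_matrix(self, b: int = 0) -> np.ndarray:
        return np.exp(self.concept_log_probs.data[b, :self.out_lens[b]])

    def class_probs(self, b: int = 0) -> np.ndarray:
        return np.exp(self.class_log_probs.data[b])


@dataclass
class TrainHistory:
    total: list = field(default_factory=list)
    class_loss: list = field(default_factory=list)
    concept_loss: list = field(default_factory=list)
    val_macro_f1: list = field(default_factory=list)
    val_edit_distance: list = field(default_factory=list)
    best_epoch: int = -1

    def to_json(self) -> dict:
        return asdict(self)


def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:  # conv [F, C, K]
        fan_in = shape[1] * shape[2]
        fan_out = shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Model:
    """Callable recognizer; see module docstring for the architecture."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        S, M, L = config.n_channels, config.n_concepts, config.n_classes
        H = config.lstm_units
        p = {}
        for s in range(S):
            p[f"fuse_w{s}"] = _glorot(rng, (config.fusion_filters, 1, config.fusion_kernel))
            p[f"fuse_b{s}"] = np.zeros(config.fusion_filters)
        p["mix_w"] = _glorot(rng, (config.mix_filters, S * config.fusion_filters,
                                   config.mix_kernel))
        p["mix_b"] = np.zeros(config.mix_filters)
        for d in ("f", "b"):
            p[f"lstm_{d}_wx"] = _glorot(rng, (config.mix_filters, 4 * H))
            p[f"lstm_{d}_wh"] = _glorot(rng, (H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H:2 * H] = 1.0  # forget-gate bias
            p[f"lstm_{d}_b"] = bias
        p["bott_w"] = _glorot(rng, (2 * H, M + 1))
        p["bott_b"] = np.zeros(M + 1)
        p["clf_w"] = _glorot(rng, (config.clf_filters, M + 1, config.clf_kernel))
        p["clf_b"] = np.zeros(config.clf_filters)
        p["out_w"] = _glorot(rng, (config.clf_filters, L))
        p["out_b"] = np.zeros(L)
        self.params = {k: Tensor(v, requires_grad=True) for k, v in p.items()}
        self.norm_mean = np.zeros(S)
        self.norm_sd = np.ones(S)

    # -- persistence ----------------------------------------------------------
    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(self.config.to_json(), indent=1))
        arrays = {k: t.data for k, t in self.params.items()}
        arrays["_norm_mean"] = self.norm_mean
        arrays["_norm_sd"] = self.norm_sd
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "Model":
        directory = Path(directory)
        config = ModelConfig.from_json(json.loads((directory / "config.json").read_text()))
        model = cls(config)
        npz = np.load(directory / "weights.npz")
        for k in model.params:
            model.params[k].data = npz[k]
        model.norm_mean = npz["_norm_mean"]
        model.norm_sd = npz["_norm_sd"]
        return model

    def state_copy(self) -> dict:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, state: dict):
        for k, v in state.items():
            self.params[k].data = v.copy()

    # -- normalization --------------------------------------------------------
    def fit_normalizer(self, windows: Sequence[SensorWindow]):
        flat = np.concatenate([w.values for w in windows], axis=1)
        self.norm_mean = flat.mean(axis=1)
        sd = flat.std(axis=1)
        self.norm_sd = np.where(sd > 1e-12, sd, 1.0)

    def batchify(self, windows: Sequence[SensorWindow]):
        """Normalize and right-pad to the batch max length; padding stays
        exactly zero (post-normalization) so it is inert under convolution."""
        S = self.config.n_channels
        lens = np.array([w.n_samples for w in windows])
        if lens.min() < self.config.min_input_length:
            raise ValueError(
                f"window of length {lens.min()} shorter than the minimum input "
                f"length {self.config.min_input_length} for this architecture")
        Tmax = int(lens.max())
        x = np.zeros((len(windows), S, Tmax))
        for i, w in enumerate(windows):
            if w.n_channels != S:
                raise ValueError(f"expected {S} channels, got {w.n_channels}")
            x[i, :, :w.n_samples] = ((w.values - self.norm_mean[:, None])
                                     / self.norm_sd[:, None])
        return x, lens

    # -- forward --------------------------------------------------------------
    def forward(self, x: np.ndarray, lengths: np.ndarray) -> ForwardOutput:
        """x: normalized padded batch [B, S, T]; lengths: valid samples per
        window. Returns log-domain concept matrices and class distributions."""
        cfg = self.config
        B, S, T = x.shape
        if S != cfg.n_channels:
            raise ValueError(f"expected {cfg.n_channels} channels, got {S}")
        if T < cfg.min_input_length:
            raise ValueError(f"input length {T} < minimum {cfg.min_input_length}")
        xt = Tensor(x)
        p = self.params

        feats = [ad.conv1d(xt[:, s:s + 1, :], p[f"fuse_w{s}"], p[f"fuse_b{s}"],
                           stride=cfg.fusion_stride, padding="same").relu()
                 for s in range(S)]
        fused = ad.concat(feats, axis=1)                       # [B, S*f1, T1]
        mixed = ad.conv1d(fused, p["mix_w"], p["mix_b"],
                          stride=cfg.mix_stride, padding="same").relu()  # [B, f2, T2]
        seq = mixed.transpose(0, 2, 1)                         # [B, T2, f2]
        T2 = seq.shape[1]
        out_lens = np.array([cfg.out_len(int(t)) for t in lengths])

        h_fwd = self._lstm(seq, "f")
        rev = _reverse_idx(out_lens, T2)
        h_bwd = ad.gather_time(self._lstm(ad.gather_time(seq, rev), "b"), rev)
        h = ad.concat([h_fwd, h_bwd], axis=2)                  # [B, T2, 2H]

        logits = h @ p["bott_w"] + p["bott_b"]
        concept_lp = ad.log_softmax(logits, axis=-1)           # [B, T2, M+1]

        probs = concept_lp.exp().transpose(0, 2, 1)            # [B, M+1, T2]
        mask = (np.arange(T2)[None, None, :] < out_lens[:, None, None]).astype(float)
        class_lp = self._classifier(probs, mask)
        return ForwardOutput(concept_lp, class_lp, out_lens)

    def _classifier(self, probs: Tensor, mask: np.ndarray) -> Tensor:
        """Classifier head over a batch of concept matrices [B, M+1, T2].

        One dilated causal convolution (the dilation widens the receptive
        field enough to span adjacent concept emissions, which CTC tends to
        place as brief spikes separated by blanks), then masked global
        average pooling over valid timesteps and a dense softmax."""
        cfg = self.config
        p = self.params
        z = ad.conv1d(probs, p["clf_w"], p["clf_b"], stride=cfg.clf_stride,
                      dilation=cfg.clf_dilation, padding="causal").relu()
        w = Tensor(mask)
        denom = (w.sum(axis=2)).reciprocal()                     # [B, 1]
        pooled = (z * w).sum(axis=2) * denom
        return ad.log_softmax(pooled @ p["out_w"] + p["out_b"], axis=-1)

    def _lstm(self, seq: Tensor, direction: str) -> Tensor:
        p = self.params
        H = self.config.lstm_units
        B, T2, _ = seq.shape
        xp = seq @ p[f"lstm_{direction}_wx"] + p[f"lstm_{direction}_b"]  # [B, T2, 4H]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        wh = p[f"lstm_{direction}_wh"]
        outs = []
        for t in range(T2):
            z = xp[:, t, :] + h @ wh
            i = z[:, :H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return ad.stack(outs, axis=1)  # [B, T2, H]

    # -- inference ------------------------------------------------------------
    def forward_windows(self, windows: Sequence[SensorWindow]) -> ForwardOutput:
        x, lens = self.batchify(windows)
        return self.forward(x, lens)

    def predict(self, values: np.ndarray):
        """Single window -> (class label, class probabilities, concept matrix).
        Argmax classification; ties broken toward the lowest class index."""
        w = _as_window(values, self.config)
        out = self.forward_windows([w])
        probs = out.class_probs(0)
        idx = int(np.argmax(probs))  # numpy argmax takes the first maximum
        return self.config.classes[idx], probs, out.concept_matrix(0)

    def predict_batch(self, windows: Sequence[SensorWindow], batch_size: int = 64):
        """Class indices and concept matrices for many windows."""
        labels, matrices = [], []
        for lo in range(0, len(windows), batch_size):
            out = self.forward_windows(windows[lo:lo + batch_size])
            cls = np.argmax(out.class_log_probs.data, axis=1)
            labels.extend(int(i) for i in cls)
            matrices.extend(out.concept_matrix(b) for b in range(len(out.out_lens)))
        return labels, matrices

    def decode_concepts(self, matrix: np.ndarray, beam_width: int = None) -> tuple:
        """Beam-decode a concept matrix to concept identifiers."""
        width = beam_width or self.config.beam_width
        res = beam_decode(matrix, width)
        return tuple(self.config.concepts[i] for i in res.sequence)

    def classify_from_concept_matrix(self, matrix: np.ndarray) -> np.ndarray:
        """Run only the classifier head on an externally supplied concept
        matrix [T', M+1]; used to probe bottleneck sufficiency."""
        probs = Tensor(np.asarray(matrix, dtype=np.float64).T[None])  # [1, M+1, T']
        mask = np.ones((1, 1, probs.shape[2]))
        lp = self._classifier(probs, mask)
        return np.exp(lp.data[0])


def _reverse_idx(out_lens: np.ndarray, T2: int) -> np.ndarray:
    """Per-sample index map that reverses the valid prefix and leaves the
    padded tail in place."""
    base = np.tile(np.arange(T2), (len(out_lens), 1))
    rev = out_lens[:, None] - 1 - base
    return np.where(base < out_lens[:, None], rev, base)


def _as_window(values, config: ModelConfig) -> SensorWindow:
    if isinstance(values, SensorWindow):
        return values
    values = np.asarray(values, dtype=np.float64)
    return SensorWindow(values=values, label=config.classes[0],
                        concepts=(config.concepts[0],) * 2)


def build_model(config: ModelConfig) -> Model:
    """Construct a seeded, untrained recognizer."""
    return Model(config)


def train(model: Model, train_windows: Sequence[SensorWindow],
          val_windows: Sequence[SensorWindow], config: ModelConfig = None,
          verbose: bool = False) -> TrainHistory:
    """Joint end-to-end training: minimizes
    beta * cross_entropy(class) + (1 - beta) * CTC(concepts) with Adam.
    Checkpoints the best epoch by validation macro-F1 (restored on return)
    and stops early after `patience` epochs without improvement."""
    cfg = config or model.config
    concept_idx = {c: i for i, c in enumerate(cfg.concepts)}
    class_idx = {c: i for i, c in enumerate(cfg.classes)}

    targets, labels = [], []
    for i, w in enumerate(train_windows):
        try:
            targets.append([concept_idx[c] for c in w.concepts])
            labels.append(class_idx[w.label])
        except KeyError as exc:
            raise ValueError(f"window {i}: label {exc} not in model config") from exc
        needed = min_path_length(targets[-1])
        avail = cfg.out_len(w.n_samples)
        if needed > avail:
            raise ValueError(
                f"window {i}: CTC target needs {needed} output steps "
                f"but only {avail} are available")

    model.fit_normalizer(train_windows)
    opt = ad.Adam(model.params.values(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainHistory()
    best_f1, best_state, stale = -1.0, None, 0
    n = len(train_windows)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_tot = ep_ly = ep_lc = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            batch = [train_windows[i] for i in idx]
            x, lens = model.batchify(batch)
            out = model.forward(x, lens)
            y = np.array([labels[i] for i in idx])
            ce = -ad.gather_last(out.class_log_probs, y[:, None]).mean()
            ctc = ctc_loss_batch(out.concept_log_probs,
                                 [targets[i] for i in idx], out.out_lens).mean()
            loss = cfg.beta * ce + (1.0 - cfg.beta) * ctc
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}: "
                    f"class={float(ce.data):.4g} concept={float(ctc.data):.4g}")
            opt.zero_grad()
            loss.backward()
            ad.clip_global_norm(opt.params, cfg.grad_clip)
            opt.step()
            ep_tot += float(loss.data)
            ep_ly += float(ce.data)
            ep_lc += float(ctc.data)
            n_batches += 1

        history.total.append(ep_tot / n_batches)
        history.class_loss.append(ep_ly / n_batches)
        history.concept_loss.append(ep_lc / n_batches)

        val_f1, val_ed = _validate(model, val_windows, cfg)
        history.val_macro_f1.append(val_f1)
        history.val_edit_distance.append(val_ed)
        if verbose:
            print(f"epoch {epoch}: loss={history.total[-1]:.4f} "
                  f"(class {history.class_loss[-1]:.4f} / concept {history.concept_loss[-1]:.4f}) "
                  f"val_f1={val_f1:.4f} val_edit={val_ed:.3f}")
        if val_f1 > best_f1:
            best_f1, best_state, stale = val_f1, model.state_copy(), 0
            history.best_epoch = epoch
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    if best_state is not None:
        model.load_state(best_state)
    return history


def _validate(model: Model, windows: Sequence[SensorWindow], cfg: ModelConfig,
              decode_limit: int = 64):
    """Per-epoch monitoring: macro-F1 over the full validation set (the
    checkpoint criterion) and mean edit distance over a fixed-size decoding
    subsample (beam decoding dominates monitoring cost; final evaluation
    always decodes everything)."""
    pred_idx, matrices = model.predict_batch(windows)
    true_idx = [cfg.classes.index(w.label) for w in windows]
    f1 = macro_f1(true_idx, pred_idx)
    sub = windows[:decode_limit]
    dists = [levenshtein(model.decode_concepts(m), w.concepts)
             for m, w in zip(matrices[:decode_limit], sub)]
    return f1, float(np.mean(dists))


class ConceptClassifier:
    """A standalone classifier head with the same architecture as the
    model's classifier module, fit directly on concept matrices. Used to
    probe bottleneck sufficiency: if a head trained on ideal matrices from
    the generator's segment log matches the end-to-end model, the concept
    representation carries all class signal."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        M, L = config.n_concepts, config.n_classes
        self.params = {
            "clf_w": Tensor(_glorot(rng, (config.clf_filters, M + 1, config.clf_kernel)),
                            requires_grad=True),
            "clf_b": Tensor(np.zeros(config.clf_filters), requires_grad=True),
            "out_w": Tensor(_glorot(rng, (config.clf_filters, L)), requires_grad=True),
            "out_b": Tensor(np.zeros(L), requires_grad=True),
        }

    def _forward(self, matrices: list) -> Tensor:
        cfg = self.config
        lens = np.array([m.shape[0] for m in matrices])
        Tm = int(lens.max())
        x = np.zeros((len(matrices), cfg.n_concepts + 1, Tm))
        for i, m in enumerate(matrices):
            x[i, :, :m.shape[0]] = np.asarray(m).T
        p = self.params
        z = ad.conv1d(Tensor(x), p["clf_w"], p["clf_b"], stride=cfg.clf_stride,
                      dilation=cfg.clf_dilation, padding="causal").relu()
        mask = (np.arange(Tm)[None, None, :] < lens[:, None, None]).astype(float)
        pooled = (z * Tensor(mask)).sum(axis=2) * Tensor(1.0 / lens)[..., None]
        return ad.log_softmax(pooled @ p["out_w"] + p["out_b"], axis=-1)

    def fit(self, matrices: list, class_indices: Sequence[int], epochs: int = 40,
            lr: float = 3e-3, batch_size: int = 32, seed: int = 0):
        y = np.asarray(class_indices)
        opt = ad.Adam(self.params.values(), lr=lr)
        rng = np.random.default_rng(seed)
        for _ in range(epochs):
            order = rng.permutation(len(matrices))
            for lo in range(0, len(order), batch_size):
                sel = order[lo:lo + batch_size]
                lp = self._forward([matrices[i] for i in sel])
                loss = -ad.gather_last(lp, y[sel][:, None]).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict(self, matrix: np.ndarray) -> int:
        lp = self._forward([matrix])
        return int(np.argmax(lp.data[0]))


def ideal_concept_matrix(window: SensorWindow, config: ModelConfig) -> np.ndarray:
    """One-hot concept matrix built from the generator's hidden segment log:
    bottleneck step t covers input samples [t*r, (t+1)*r) where r is the
    total stride; the step is assigned the concept covering the center of
    that span, or the blank where none does."""
    if not window.boundaries:
        raise ValueError("window has no segment log (generated data only)")
    r = config.fusion_stride * config.mix_stride
    T2 = config.out_len(window.n_samples)
    M = config.n_concepts
    mat = np.zeros((T2, M + 1))
    idx = {c: i for i, c in enumerate(config.concepts)}
    centers = np.arange(T2) * r + r // 2
    for t, center in enumerate(centers):
        col = M  # blank unless a labeled segment covers the center
        for concept, start, end in window.boundaries:
            if start <= center < end:
                col = idx[concept]
                break
        mat[t, col] = 1.0
    return mat
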