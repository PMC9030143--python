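"""Residual 1D-CNN spatial encoder + three-layer LSTM longitudinal classifier.

Each timepoint's functional-connectivity matrix is vectorised to its strict
upper triangle (length R(R-1)/2, row-major) and treated as a 1D signal. A
convolutional encoder with two short-connection (residual) links extracts a
spatial feature vector per timepoint; the SAME encoder parameters are applied
at every timepoint. The three-step feature sequence (baseline, 12 months,
24 months) is fused by a three-layer LSTM whose cell follows the standard
gated recurrence

    f_k = sigma(W_f . [h_{k-1}, x_k] + b_f)        (forget gate)
    i_k = sigma(W_i . [h_{k-1}, x_k] + b_i)        (input gate)
    c~_k = tanh(W_c . [h_{k-1}, x_k] + b_c)        (candidate state)
    c_k = f_k * c_{k-1} + i_k * c~_k
    o_k = sigma(W_o . [h_{k-1}, x_k] + b_o)        (output gate)
    h_k = o_k * tanh(c_k)

and the last hidden state of the top layer maps through a linear head and a
sigmoid to one disease probability (decision threshold 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _engine as eng
from ._engine import Tensor
from .connectome import FCMatrix, TIMEPOINTS

__all__ = [
    "LongitudinalSample",
    "CNNConfig",
    "StackConfig",
    "LSTMCellParams",
    "TrainConfig",
    "TrainResult",
    "lstm_cell_step",
    "CNNEncoder",
    "LSTMStack",
    "SequenceClassifier",
    "build_classifier",
    "cnn_forward",
    "classify",
    "train_model",
    "save_model",
    "load_model",
]


@dataclass
class LongitudinalSample:
    """Ordered (BL, 12m, 24m) FC matrices plus a binary task label.

    Positive class is the more-diseased label (AD in NC-vs-AD, pMCI in
    sMCI-vs-pMCI) so that recall reads as sensitivity to disease.
    """

    fc_sequence: tuple[FCMatrix, ...]
    label: int
    subject_id: str = ""
    provenance: str = "real"

    def __post_init__(self):
        if len(self.fc_sequence) != 3:
            raise ValueError("a longitudinal sample holds exactly 3 timepoints (BL, 12m, 24m)")
        rs = {fc.roi_count for fc in self.fc_sequence}
        if len(rs) != 1:
            raise ValueError(f"inconsistent ROI counts across timepoints: {rs}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def roi_count(self) -> int:
        return self.fc_sequence[0].roi_count

    def feature_sequence(self) -> np.ndarray:
        """(3, R(R-1)/2) array of upper-triangle vectors."""
        return np.stack([fc.upper_triangle() for fc in self.fc_sequence])


@dataclass
class CNNConfig:
    """Residual 1D-CNN encoder configuration.

    ``shortcut_pairs`` lists exactly two short-connection links as
    (source block, destination) where destination is a later block index
    (the source's activation, 1x1-projected and pooled to match, is added to
    that block's input) or the string "output" (added after the last block).
    """

    blocks: tuple[tuple[int, int, int], ...] = ((16, 5, 2), (32, 5, 2), (64, 5, 2))
    shortcut_pairs: tuple[tuple[int, int | str], ...] = ((1, 3), (2, "output"))
    feature_dim: int = 64

    def __post_init__(self):
        if len(self.shortcut_pairs) != 2:
            raise ValueError("exactly two short-connection modules are required")
        n = len(self.blocks)
        for src, dst in self.shortcut_pairs:
            if not (1 <= src <= n):
                raise ValueError(f"shortcut source block {src} out of range 1..{n}")
            if dst != "output" and not (isinstance(dst, int) and src < dst <= n):
                raise ValueError(f"shortcut destination {dst!r} must follow source {src}")
        for ch, k, pool in self.blocks:
            if ch < 1 or k < 1 or k % 2 == 0 or pool < 1:
                raise ValueError("each block needs channels >= 1, odd kernel, pool >= 1")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be positive")


@dataclass
class StackConfig:
    """Three-layer LSTM fuser + sigmoid head."""

    num_lstm_layers: int = 3
    hidden_size: int = 64
    dropout: float = 0.2

    def __post_init__(self):
        if self.num_lstm_layers < 1 or self.hidden_size < 1:
            raise ValueError("layers and hidden size must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class LSTMCellParams:
    """Gate weights over the concatenated [h_{k-1}, x_k] vector.

    Each W_* has shape (hidden_size, hidden_size + input_size) and decomposes
    as [W_*h | W_*x]; each b_* has shape (hidden_size,).
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self):
        h = self.b_f.shape[0]
        for name in ("W_f", "W_i", "W_c", "W_o"):
            w = getattr(self, name)
            if w.ndim != 2 or w.shape[0] != h:
                raise ValueError(f"{name} shape {w.shape} inconsistent with hidden size {h}")
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name} has non-finite entries")
        for name in ("b_f", "b_i", "b_c", "b_o"):
            b = getattr(self, name)
            if b.shape != (h,) or not np.all(np.isfinite(b)):
                raise ValueError(f"{name} shape/values invalid")

    @property
    def hidden_size(self) -> int:
        return self.b_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.hidden_size


def _sigma(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def lstm_cell_step(x_k: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   params: LSTMCellParams) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns (h_k, c_k)."""
    x_k = np.asarray(x_k, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if x_k.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError(
            f"shape mismatch: x {x_k.shape}, h {h_prev.shape} vs params "
            f"(input {params.input_size}, hidden {params.hidden_size})")
    cat = np.concatenate([h_prev, x_k], axis=-1)
    f = _sigma(cat @ params.W_f.T + params.b_f)
    i = _sigma(cat @ params.W_i.T + params.b_i)
    c_tilde = np.tanh(cat @ params.W_c.T + params.b_c)
    c = f * c_prev + i * c_tilde
    o = _sigma(cat @ params.W_o.T + params.b_o)
    h = o * np.tanh(c)
    return h, c


# ---------------------------------------------------------------------------
# trainable modules


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:  # conv (out, in, k)
        fan_in = shape[1] * shape[2]
        fan_out = shape[0] * shape[2]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class CNNEncoder:
    """1D convolutional encoder with two short-connection links."""

    def __init__(self, input_length: int, config: CNNConfig,
                 rng: np.random.Generator):
        self.config = config
        self.input_length = input_length
        self.params: list[Tensor] = []
        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        # shape bookkeeping: (channels, length, pool_depth) before/after each block
        in_shapes = []
        out_shapes = []
        ch, length, depth = 1, input_length, 0
        for c_out, k, pool in config.blocks:
            in_shapes.append((ch, length, depth))
            w = Tensor(_glorot(rng, (c_out, ch, k)), requires_grad=True)
            b = Tensor(np.zeros(c_out), requires_grad=True)
            self.conv_w.append(w)
            self.conv_b.append(b)
            self.params += [w, b]
            ch, length, depth = c_out, length // pool, depth + 1
            if length < 1:
                raise ValueError("signal fully consumed by pooling; reduce blocks or pools")
            out_shapes.append((ch, length, depth))
        self._out_channels = ch
        # shortcut projections (1x1 conv) + required extra pooling
        self.shortcuts = []  # (src_idx0, dst, proj_w, proj_b, n_pools, pool_k)
        for src, dst in config.shortcut_pairs:
            s_ch, s_len, s_depth = out_shapes[src - 1]
            if dst == "output":
                t_ch, t_len, t_depth = out_shapes[-1]
            else:
                t_ch, t_len, t_depth = in_shapes[dst - 1]
            n_pools = t_depth - s_depth
            # the pools crossed between source output and destination are
            # those of blocks src+1 .. src+n_pools (1-indexed)
            pool_ks = [config.blocks[src + step][2] for step in range(n_pools)]
            check = s_len
            for k in pool_ks:
                check = check // k
            if check != t_len:
                raise ValueError(
                    f"shortcut {src}->{dst}: pooled source length {check} != target {t_len}")
            pw = Tensor(_glorot(rng, (t_ch, s_ch, 1)), requires_grad=True)
            pb = Tensor(np.zeros(t_ch), requires_grad=True)
            self.params += [pw, pb]
            self.shortcuts.append((src - 1, dst, pw, pb, pool_ks))
        fd = config.feature_dim
        self.head_w = Tensor(_glorot(rng, (ch, fd)), requires_grad=True)
        self.head_b = Tensor(np.zeros(fd), requires_grad=True)
        self.params += [self.head_w, self.head_b]

    def _project(self, t: Tensor, pw: Tensor, pb: Tensor, pool_ks: list[int]) -> Tensor:
        t = eng.conv1d(t, pw, pb)
        for k in pool_ks:
            t = eng.maxpool1d(t, k)
        return t

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 1, L) -> (N, feature_dim)."""
        block_out: list[Tensor] = []
        h = x
        for bi, (c_out, k, pool) in enumerate(self.config.blocks):
            for src, dst, pw, pb, pool_ks in self.shortcuts:
                if dst != "output" and dst - 1 == bi and src < bi:
                    h = eng.add(h, self._project(block_out[src], pw, pb, pool_ks))
            h = eng.conv1d(h, self.conv_w[bi], self.conv_b[bi])
            h = eng.relu(h)
            h = eng.maxpool1d(h, pool)
            block_out.append(h)
        for src, dst, pw, pb, pool_ks in self.shortcuts:
            if dst == "output":
                h = eng.add(h, self._project(block_out[src], pw, pb, pool_ks))
        pooled = eng.mean_last(h)  # (N, C)
        return eng.add(eng.matmul(pooled, self.head_w), self.head_b)


class LSTMStack:
    """Stacked LSTM layers; parameters stored as [h|x]-concatenated gate matrices."""

    def __init__(self, input_size: int, config: StackConfig, rng: np.random.Generator):
        self.config = config
        self.params: list[Tensor] = []
        self.layers = []
        d_in = input_size
        h = config.hidden_size
        for _ in range(config.num_lstm_layers):
            layer = {}
            for gate in ("f", "i", "c", "o"):
                # orthogonal recurrent block, Glorot input block: standard
                # conditioning for stacked LSTMs
                q, _ = np.linalg.qr(rng.standard_normal((h, h)))
                w = np.vstack([q, _glorot(rng, (d_in, h))])
                w = Tensor(w, requires_grad=True)
                b = Tensor(np.ones(h) if gate == "f" else np.zeros(h),
                           requires_grad=True)
                layer[gate] = (w, b)
                self.params += [w, b]
            self.layers.append(layer)
            d_in = h
        self.input_size = input_size

    def forward(self, xs: list[Tensor], train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """xs: list of (N, d) step inputs; returns top-layer h at the last step."""
        n = xs[0].data.shape[0]
        h_sz = self.config.hidden_size
        seq = xs
        for li, layer in enumerate(self.layers):
            h = Tensor(np.zeros((n, h_sz)))
            c = Tensor(np.zeros((n, h_sz)))
            out_seq = []
            for x in seq:
                cat = eng.concat([h, x], axis=1)
                f = eng.sigmoid(eng.add(eng.matmul(cat, layer["f"][0]), layer["f"][1]))
                i = eng.sigmoid(eng.add(eng.matmul(cat, layer["i"][0]), layer["i"][1]))
                ct = eng.tanh(eng.add(eng.matmul(cat, layer["c"][0]), layer["c"][1]))
                c = eng.add(eng.mul(f, c), eng.mul(i, ct))
                o = eng.sigmoid(eng.add(eng.matmul(cat, layer["o"][0]), layer["o"][1]))
                h = eng.mul(o, eng.tanh(c))
                out_seq.append(h)
            if train and self.config.dropout > 0 and li < len(self.layers) - 1:
                assert rng is not None
                out_seq = [eng.dropout(t, self.config.dropout, rng) for t in out_seq]
            seq = out_seq
        return seq[-1]

    def cell_params(self, layer: int = 0) -> LSTMCellParams:
        """Export one layer's weights in [W_*h | W_*x] row-major gate form."""
        lay = self.layers[layer]
        kw = {}
        for gate in ("f", "i", "c", "o"):
            kw[f"W_{gate}"] = lay[gate][0].data.T.copy()
            kw[f"b_{gate}"] = lay[gate][1].data.copy()
        return LSTMCellParams(**kw)


class SequenceClassifier:
    """Shared CNN per timepoint -> LSTM stack -> linear head -> probability.

    With ``use_lstm=False`` this degrades to the single-timepoint CNN-only
    comparator: encoder then head, no recurrence.
    """

    def __init__(self, input_length: int, cnn_config: CNNConfig,
                 stack_config: StackConfig, seed: int = 0, use_lstm: bool = True):
        rng = np.random.default_rng(seed)
        self.cnn_config = cnn_config
        self.stack_config = stack_config
        self.use_lstm = use_lstm
        self.input_length = input_length
        self.cnn = CNNEncoder(input_length, cnn_config, rng)
        self.params: list[Tensor] = list(self.cnn.params)
        if use_lstm:
            self.lstm = LSTMStack(cnn_config.feature_dim, stack_config, rng)
            self.params += self.lstm.params
            head_in = stack_config.hidden_size
        else:
            self.lstm = None
            head_in = cnn_config.feature_dim
        self.head_w = Tensor(_glorot(rng, (head_in, 1)), requires_grad=True)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)
        self.params += [self.head_w, self.head_b]

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """x: (N, steps, L) feature-vector sequences -> (N,) logits.

        The same CNN parameters encode every step (weight sharing across
        timepoints). For the CNN-only variant the LAST step is used alone.
        """
        n, steps, length = x.shape
        if length != self.input_length:
            raise ValueError(f"input length {length} != model input length {self.input_length}")
        if self.use_lstm:
            # one CNN pass over all timepoints (shared weights), then re-split
            flat = x.reshape(n * steps, 1, length)
            enc = self.cnn.forward(Tensor(flat))  # (n*steps, feature_dim)
            enc = eng.reshape(enc, (n, steps, self.cnn_config.feature_dim))
            feats = [eng.take_step(enc, s) for s in range(steps)]
            top = self.lstm.forward(feats, train=train, rng=rng)
        else:
            top = self.cnn.forward(Tensor(x[:, -1, :][:, None, :]))
        z = eng.add(eng.matmul(top, self.head_w), self.head_b)
        return eng.reshape(z, (n,))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward_logits(x, train=False)
        return _sigma(z.data)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        if len(arrays) != len(self.params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(self.params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.copy()


def build_classifier(roi_count: int, *, cnn_config: CNNConfig | None = None,
                     stack_config: StackConfig | None = None, seed: int = 0,
                     use_lstm: bool = True) -> SequenceClassifier:
    length = roi_count * (roi_count - 1) // 2
    return SequenceClassifier(length, cnn_config or CNNConfig(),
                              stack_config or StackConfig(), seed=seed,
                              use_lstm=use_lstm)


def cnn_forward(fc: FCMatrix, encoder: CNNEncoder) -> np.ndarray:
    """Spatial feature vector of one FC matrix (inference mode)."""
    vec = fc.upper_triangle()[None, None, :]
    return encoder.forward(Tensor(vec)).data[0]


def classify(sample: LongitudinalSample, model: SequenceClassifier) -> float:
    """Disease probability for one subject's (BL, 12m, 24m) sequence."""
    x = sample.feature_sequence()[None, :, :]
    return float(model.predict_proba(x)[0])


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3
    clip_norm: float = 5.0  # global gradient-norm clip; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")
        if self.clip_norm < 0:
            raise ValueError("clip_norm must be non-negative")


@dataclass
class TrainResult:
    model: SequenceClassifier
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int


def _samples_to_arrays(samples: list[LongitudinalSample],
                       n_steps: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.feature_sequence()[:n_steps] for s in samples])
    y = np.array([s.label for s in samples], dtype=np.float64)
    return x, y


def train_model(train_samples: list[LongitudinalSample],
                val_samples: list[LongitudinalSample],
                config: TrainConfig | None = None, *,
                cnn_config: CNNConfig | None = None,
                stack_config: StackConfig | None = None,
                use_lstm: bool = True,
                n_steps: int = 3) -> TrainResult:
    """Minimise binary cross-entropy with Adam; keep the best-validation epoch.

    Deterministic given ``config.seed``: initialisation, batch shuffling and
    dropout masks all derive from it.
    """
    config = config or TrainConfig()
    labels = {s.label for s in train_samples}
    if len(labels) < 2:
        raise ValueError("training set must contain both classes")
    x_tr, y_tr = _samples_to_arrays(train_samples, n_steps)
    x_va, y_va = _samples_to_arrays(val_samples, n_steps) if val_samples else (None, None)
    model = build_classifier(train_samples[0].roi_count, cnn_config=cnn_config,
                             stack_config=stack_config, seed=config.seed,
                             use_lstm=use_lstm)
    rng = np.random.default_rng(config.seed + 1)
    opt = eng.Adam(model.params, lr=config.learning_rate)
    n = len(train_samples)
    train_curve, val_curve = [], []
    # checkpoint on highest validation accuracy, breaking ties by lower loss:
    # with small validation sets the loss of an overconfident model rises even
    # while its decisions improve, so raw loss is a poor selection criterion
    best_key = (-np.inf, -np.inf)
    best_state = model.state_arrays()
    best_epoch = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            z = model.forward_logits(x_tr[idx], train=True, rng=rng)
            loss = eng.bce_with_logits(z, y_tr[idx])
            loss.backward()
            if config.clip_norm > 0:
                total = np.sqrt(sum(float((p.grad**2).sum())
                                    for p in model.params if p.grad is not None))
                if total > config.clip_norm:
                    scale = config.clip_norm / total
                    for p in model.params:
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        train_curve.append(epoch_loss / n)
        if x_va is not None and len(x_va):
            zv = model.forward_logits(x_va, train=False)
            vl = float(eng.bce_with_logits(zv, y_va).data)
            va_acc = float(((zv.data > 0).astype(int) == y_va).mean())
        else:
            vl = train_curve[-1]
            va_acc = -vl
        val_curve.append(vl)
        key = (va_acc, -vl)
        if key > best_key:
            best_key = key
            best_state = model.state_arrays()
            best_epoch = epoch
    model.load_state_arrays(best_state)
    return TrainResult(model=model, train_loss=train_curve, val_loss=val_curve,
                       best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: SequenceClassifier, path: str | Path) -> None:
    """One .npz of parameters plus a JSON architecture descriptor alongside."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    desc = {
        "input_length": model.input_length,
        "use_lstm": model.use_lstm,
        "cnn": {"blocks": [list(b) for b in model.cnn_config.blocks],
                "shortcut_pairs": [list(p) for p in model.cnn_config.shortcut_pairs],
                "feature_dim": model.cnn_config.feature_dim},
        "stack": {"num_lstm_layers": model.stack_config.num_lstm_layers,
                  "hidden_size": model.stack_config.hidden_size,
                  "dropout": model.stack_config.dropout},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(desc, fh, indent=2)


def load_model(path: str | Path) -> SequenceClassifier:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        desc = json.load(fh)
    cnn = CNNConfig(blocks=tuple(tuple(b) for b in desc["cnn"]["blocks"]),
                    shortcut_pairs=tuple(
                        (p[0], p[1]) for p in desc["cnn"]["shortcut_pairs"]),
                    feature_dim=desc["cnn"]["feature_dim"])
    stack = StackConfig(**desc["stack"])
    model = SequenceClassifier(desc["input_length"], cnn, stack,
                               use_lstm=desc["use_lstm"])
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    model.load_state_arrays([data[f"p{i}"] for i in range(len(model.params))])
    return model
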