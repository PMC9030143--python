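"""GAN augmentation of functional-connectivity matrices.

Labelled training sets in longitudinal neuroimaging are small, so a
generative adversarial pair is trained per class on the vectorised strict
upper triangle of the training-fold FC matrices (length R(R-1)/2). The
generator maps Gaussian noise through a small fully connected net with a
tanh output (so raw samples already lie in [-1, 1]); the discriminator is a
logistic critic; both are updated with the standard non-saturating
adversarial losses. Generated vectors are rebuilt into full matrices and
passed through :func:`project_to_valid_fc`, so every emitted sample is a
symmetric, unit-diagonal, [-1, 1]-bounded matrix. Positive semi-definiteness
is deliberately not enforced: the downstream classifier consumes raw matrix
entries and no later step requires PSD.

Synthetic samples carry ``provenance="synthetic"`` so cross-validation can
assert they never leave the training fold that produced them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _engine as eng
from ._engine import Tensor
from .connectome import FCMatrix

__all__ = [
    "GANConfig",
    "GeneratorState",
    "project_to_valid_fc",
    "train_gan",
    "generate_fc",
    "augment_training_set",
    "save_generator",
    "load_generator",
]


@dataclass
class GANConfig:
    noise_dim: int = 32
    generator_widths: tuple[int, ...] = (64, 64)
    discriminator_widths: tuple[int, ...] = (64, 32)
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 2e-4
    per_class: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.noise_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("noise_dim, epochs and batch_size must be positive")
        if any(w < 1 for w in self.generator_widths + self.discriminator_widths):
            raise ValueError("layer widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def _init_mlp(widths: list[int], rng: np.random.Generator) -> list[tuple[Tensor, Tensor]]:
    layers = []
    for d_in, d_out in zip(widths[:-1], widths[1:]):
        lim = np.sqrt(6.0 / (d_in + d_out))
        w = Tensor(rng.uniform(-lim, lim, size=(d_in, d_out)), requires_grad=True)
        b = Tensor(np.zeros(d_out), requires_grad=True)
        layers.append((w, b))
    return layers


def _mlp_forward(layers, x: Tensor, out_activation: str) -> Tensor:
    h = x
    for i, (w, b) in enumerate(layers):
        h = eng.add(eng.matmul(h, w), b)
        if i < len(layers) - 1:
            h = eng.relu(h)
        elif out_activation == "tanh":
            h = eng.tanh(h)
    return h


@dataclass
class GeneratorState:
    """Serializable trained generator: layer arrays plus provenance metadata."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: GANConfig
    roi_count: int
    class_label: int | None = None
    final_losses: tuple[float, float] = (np.nan, np.nan)  # (D, G)

    @property
    def edge_dim(self) -> int:
        return self.roi_count * (self.roi_count - 1) // 2


def project_to_valid_fc(raw: np.ndarray, *, subject_id: str = "",
                        timepoint: str = "BL",
                        provenance: str = "synthetic") -> FCMatrix:
    """Symmetrize, clip to [-1, 1], set the diagonal to 1. Idempotent."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.all(np.isfinite(raw)):
        raise ValueError("input contains non-finite entries")
    m = (raw + raw.T) / 2.0
    np.clip(m, -1.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    return FCMatrix(m, subject_id=subject_id, timepoint=timepoint,
                    provenance=provenance)


def _vec_to_matrix(vec: np.ndarray, r: int) -> np.ndarray:
    m = np.zeros((r, r))
    iu = np.triu_indices(r, k=1)
    m[iu] = vec
    m = m + m.T
    return m


def train_gan(real_samples: list[FCMatrix], config: GANConfig | None = None,
              class_label: int | None = None) -> GeneratorState:
    """Adversarial training on one class's FC matrices.

    Alternates one discriminator and one generator Adam step per minibatch;
    deterministic given ``config.seed`` and the sample order.
    """
    config = config or GANConfig()
    if len(real_samples) < 2:
        raise ValueError("need at least 2 real samples to train a GAN")
    rs = {fc.roi_count for fc in real_samples}
    if len(rs) != 1:
        raise ValueError(f"inconsistent ROI counts: {rs}")
    r = rs.pop()
    edge_dim = r * (r - 1) // 2
    data = np.stack([fc.upper_triangle() for fc in real_samples])
    rng = np.random.default_rng(config.seed)
    g_layers = _init_mlp([config.noise_dim, *config.generator_widths, edge_dim], rng)
    d_layers = _init_mlp([edge_dim, *config.discriminator_widths, 1], rng)
    g_params = [t for pair in g_layers for t in pair]
    d_params = [t for pair in d_layers for t in pair]
    g_opt = eng.Adam(g_params, lr=config.learning_rate, betas=(0.5, 0.999))
    d_opt = eng.Adam(d_params, lr=config.learning_rate, betas=(0.5, 0.999))
    n = data.shape[0]
    d_loss_v = g_loss_v = np.nan
    last_stable = ([w.data.copy() for w, _ in g_layers],
                   [b.data.copy() for _, b in g_layers])
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = data[idx]
            m = len(idx)
            z = rng.standard_normal((m, config.noise_dim))
            # discriminator step
            d_opt.zero_grad()
            fake = _mlp_forward(g_layers, Tensor(z), "tanh")
            d_real = _mlp_forward(d_layers, Tensor(batch), "linear")
            d_fake = _mlp_forward(d_layers, Tensor(fake.data), "linear")
            d_loss = eng.add(
                eng.bce_with_logits(eng.reshape(d_real, (m,)), np.ones(m)),
                eng.bce_with_logits(eng.reshape(d_fake, (m,)), np.zeros(m)))
            d_loss.backward()
            d_opt.step()
            # generator step (non-saturating: maximise log D(G(z)))
            g_opt.zero_grad()
            z2 = rng.standard_normal((m, config.noise_dim))
            fake2 = _mlp_forward(g_layers, Tensor(z2), "tanh")
            d_fake2 = _mlp_forward(d_layers, fake2, "linear")
            g_loss = eng.bce_with_logits(eng.reshape(d_fake2, (m,)), np.ones(m))
            g_loss.backward()
            # only the generator is updated here
            for p in d_params:
                p.grad = None
            g_opt.step()
            d_loss_v, g_loss_v = float(d_loss.data), float(g_loss.data)
            if not (np.isfinite(d_loss_v) and np.isfinite(g_loss_v)):
                state = GeneratorState(weights=last_stable[0], biases=last_stable[1],
                                       config=config, roi_count=r,
                                       class_label=class_label,
                                       final_losses=(d_loss_v, g_loss_v))
                raise TrainingDivergenceError(
                    f"non-finite adversarial loss at epoch {epoch}", state)
        last_stable = ([w.data.copy() for w, _ in g_layers],
                       [b.data.copy() for _, b in g_layers])
    return GeneratorState(weights=[w.data.copy() for w, _ in g_layers],
                          biases=[b.data.copy() for _, b in g_layers],
                          config=config, roi_count=r, class_label=class_label,
                          final_losses=(d_loss_v, g_loss_v))


class TrainingDivergenceError(RuntimeError):
    """Adversarial loss became non-finite; carries the last stable generator."""

    def __init__(self, msg: str, last_stable: GeneratorState):
        super().__init__(msg)
        self.last_stable = last_stable


def generate_fc(state: GeneratorState, n: int, seed: int = 0) -> list[FCMatrix]:
    """Sample n synthetic FC matrices from a trained generator."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, state.config.noise_dim))
    h = z
    n_layers = len(state.weights)
    for i, (w, b) in enumerate(zip(state.weights, state.biases)):
        h = h @ w + b
        if i < n_layers - 1:
            h = np.maximum(h, 0.0)
        else:
            h = np.tanh(h)
    out = []
    for k in range(n):
        m = _vec_to_matrix(h[k], state.roi_count)
        out.append(project_to_valid_fc(
            m, subject_id=f"synthetic_{k:04d}", provenance="synthetic"))
    return out


def augment_training_set(samples_by_class: dict[int, list[FCMatrix]],
                         ratio: float = 1.0,
                         config: GANConfig | None = None,
                         seed: int = 0) -> dict[int, list[FCMatrix]]:
    """Train one generator per class and return ratio*n synthetic samples per class."""
    config = config or GANConfig()
    out = {}
    for label, samples in sorted(samples_by_class.items()):
        n_new = int(round(ratio * len(samples)))
        if n_new == 0:
            out[label] = []
            continue
        cfg = GANConfig(**{**asdict(config), "seed": config.seed + label})
        state = train_gan(samples, cfg, class_label=label)
        out[label] = generate_fc(state, n_new, seed=seed + label)
    return out


def save_generator(state: GeneratorState, path: str | Path) -> None:
    path = Path(path)
    arrays = {}
    for i, (w, b) in enumerate(zip(state.weights, state.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)
    meta = {"config": asdict(state.config), "roi_count": state.roi_count,
            "class_label": state.class_label,
            "n_layers": len(state.weights)}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_generator(path: str | Path) -> GeneratorState:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    cfg = meta["config"]
    cfg["generator_widths"] = tuple(cfg["generator_widths"])
    cfg["discriminator_widths"] = tuple(cfg["discriminator_widths"])
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    weights = [data[f"w{i}"] for i in range(meta["n_layers"])]
    biases = [data[f"b{i}"] for i in range(meta["n_layers"])]
    return GeneratorState(weights=weights, biases=biases, config=GANConfig(**cfg),
                          roi_count=meta["roi_count"],
                          class_label=meta["class_label"])
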