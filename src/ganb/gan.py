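"""Generator/discriminator networks and the adversarial training loop.

The generator maps standard-normal latent vectors to single-channel images
in [0, 1] through dense layers followed by two transposed-convolution
upsampling blocks.  The discriminator is a stack of K addressable blocks
(strided convolutions, a dense bottleneck, and a final sigmoid unit), so
any intermediate block output can serve as a feature representation.

Losses are the usual non-saturating binary cross-entropy pair

    L_G = -E[log D(G(z))]
    L_D = -E[log D(x)] - E[log(1 - D(G(z)))]

and both networks are updated by gradient descent (SGD by default, Adam
optionally), one discriminator step then one generator step per mini-batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "TrainConfig",
    "LossRecord",
    "GeneratorNet",
    "DiscriminatorNet",
    "sample_noise",
    "generator_forward",
    "discriminator_forward",
    "generator_loss",
    "discriminator_loss",
    "gradient_step",
    "train_gan",
    "save_gan",
    "load_gan",
]

gradient_step = nn.gradient_step


@dataclass
class TrainConfig:
    """Hyperparameters of one adversarial training run."""

    learning_rate: float = 0.05
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    optimizer: str = "sgd"
    latent_dim: int = 32
    image_size: int = 32
    gen_hidden: int = 128
    gen_channels: int = 16
    disc_channels: int = 8
    disc_hidden: int = 64

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")


@dataclass
class LossRecord:
    """Per-step loss history with per-epoch means."""

    steps_d: list[float] = field(default_factory=list)
    steps_g: list[float] = field(default_factory=list)
    epoch_bounds: list[int] = field(default_factory=list)  # step count at each epoch end

    def epoch_means(self) -> tuple[list[float], list[float]]:
        md, mg = [], []
        start = 0
        for end in self.epoch_bounds:
            md.append(float(np.mean(self.steps_d[start:end])))
            mg.append(float(np.mean(self.steps_g[start:end])))
            start = end
        return md, mg


class GeneratorNet:
    """latent_dim -> dense -> dense -> reshape -> two transposed-conv blocks -> sigmoid image."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        s, ch = config.image_size, config.gen_channels
        self.latent_dim = config.latent_dim
        self.output_shape = (s, s)
        base = s // 4
        self.net = nn.Sequential([
            nn.Dense(config.latent_dim, config.gen_hidden, rng),
            nn.ReLU(),
            nn.Dense(config.gen_hidden, ch * base * base, rng),
            nn.ReLU(),
            nn.Reshape((ch, base, base)),
            nn.ConvTranspose2d(ch, ch // 2, k=4, stride=2, pad=1, rng=rng),
            nn.ReLU(),
            nn.ConvTranspose2d(ch // 2, 1, k=4, stride=2, pad=1, rng=rng),
            nn.Sigmoid(),
        ])

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def forward(self, z: np.ndarray) -> np.ndarray:
        if z.ndim != 2 or z.shape[1] != self.latent_dim:
            raise ValueError(
                f"noise batch must be (m, {self.latent_dim}), got {z.shape}")
        return self.net.forward(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class DiscriminatorNet:
    """K addressable blocks; block K ends in a sigmoid real-vs-fake probability."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        s, ch = config.image_size, config.disc_channels
        self.input_shape = (s, s)
        flat = 2 * ch * (s // 4) * (s // 4)
        self.blocks: list[nn.Sequential] = [
            nn.Sequential([nn.Conv2d(1, ch, k=3, stride=2, pad=1, rng=rng), nn.LeakyReLU()]),
            nn.Sequential([nn.Conv2d(ch, 2 * ch, k=3, stride=2, pad=1, rng=rng), nn.LeakyReLU()]),
            nn.Sequential([nn.Flatten(), nn.Dense(flat, config.disc_hidden, rng), nn.LeakyReLU()]),
            nn.Sequential([nn.Dense(config.disc_hidden, 1, rng), nn.Sigmoid()]),
        ]
        self.n_layers = len(self.blocks)
        self.feature_layer_default = self.n_layers - 1

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def grads(self):
        return [g for b in self.blocks for g in b.grads()]

    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[2:] != self.input_shape:
            raise ValueError(
                f"image batch must be (m, {self.input_shape[0]}, {self.input_shape[1]}), got {x.shape}")
        return x

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        """Run blocks 1..upto (all K when None); returns the block output."""
        x = self._as_batch(x)
        upto = self.n_layers if upto is None else upto
        for b in self.blocks[:upto]:
            x = b.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return dy


def sample_noise(m: int, latent_dim: int, rng: np.random.Generator) -> np.ndarray:
    """Mini-batch of i.i.d. standard-normal latent vectors, shape (m, latent_dim)."""
    if m < 1 or latent_dim < 1:
        raise ValueError("m and latent_dim must be >= 1")
    return rng.standard_normal((m, latent_dim))


def generator_forward(z: np.ndarray, G: GeneratorNet) -> np.ndarray:
    """Images in [0, 1], shape (m, 1, H, W); deterministic for fixed (z, weights)."""
    return G.forward(np.asarray(z, dtype=float))


def discriminator_forward(x: np.ndarray, D: DiscriminatorNet) -> np.ndarray:
    """Per-image probability of being real, strictly inside (0, 1)."""
    return D.forward(np.asarray(x, dtype=float)).ravel()


def _check_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0 or np.any(p <= 0) or np.any(p >= 1):
        raise ValueError(f"{name} must be non-empty with values in the open interval (0, 1)")
    return p


def generator_loss(d_fake: np.ndarray) -> float:
    """Non-saturating generator loss -mean(log D(G(z)))."""
    p = _check_probs(d_fake, "d_fake")
    return float(-np.mean(np.log(p)))


def discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Binary cross-entropy -mean(log D(x)) - mean(log(1 - D(G(z))))."""
    pr = _check_probs(d_real, "d_real")
    pf = _check_probs(d_fake, "d_fake")
    return float(-np.mean(np.log(pr)) - np.mean(np.log1p(-pf)))


def _make_optimizer(config: TrainConfig):
    if config.optimizer == "adam":
        return nn.Adam(config.learning_rate)
    return nn.SGD(config.learning_rate)


def train_gan(dataset: np.ndarray, config: TrainConfig) -> tuple[GeneratorNet, DiscriminatorNet, LossRecord]:
    """Adversarial training on a (n, H, W) image stack in [0, 1].

    Each iteration samples a real mini-batch and a noise mini-batch,
    updates the discriminator on L_D, then the generator on L_G.  The run
    is reproducible bit-for-bit for a fixed seed.
    """
    data = np.asarray(dataset, dtype=float)
    if data.ndim == 4 and data.shape[1] == 1:
        data = data[:, 0]
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError("dataset must be a non-empty (n, H, W) stack")
    rng = np.random.default_rng(config.seed)
    init_rng = np.random.default_rng(rng.integers(2**31))
    G = GeneratorNet(config, init_rng)
    D = DiscriminatorNet(config, init_rng)
    opt_d = _make_optimizer(config)
    opt_g = _make_optimizer(config)
    record = LossRecord()
    n = data.shape[0]
    m = min(config.batch_size, n)

    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n - m + 1, m):
            real = data[order[start : start + m], None, :, :]
            # --- discriminator step (fakes detached) ---
            z = sample_noise(m, config.latent_dim, rng)
            fake = G.forward(z)
            batch = np.concatenate([real, fake], axis=0)
            p = D.forward(batch).ravel()
            p_real, p_fake = p[:m], p[m:]
            loss_d = discriminator_loss(p_real, p_fake)
            if not np.isfinite(loss_d):
                raise FloatingPointError(f"discriminator loss diverged at step {step}")
            dp = np.concatenate([-1.0 / (m * p_real), 1.0 / (m * (1.0 - p_fake))])
            D.backward(dp[:, None])
            gradient_step(D.params(), D.grads(), config.learning_rate, opt_d)
            # --- generator step ---
            z = sample_noise(m, config.latent_dim, rng)
            fake = G.forward(z)
            p_fake = D.forward(fake).ravel()
            loss_g = generator_loss(p_fake)
            if not np.isfinite(loss_g):
                raise FloatingPointError(f"generator loss diverged at step {step}")
            dp = -1.0 / (m * p_fake)
            dx = D.backward(dp[:, None])
            G.backward(dx)
            gradient_step(G.params(), G.grads(), config.learning_rate, opt_g)
            record.steps_d.append(loss_d)
            record.steps_g.append(loss_g)
            step += 1
        record.epoch_bounds.append(step)
    return G, D, record


def save_gan(G: GeneratorNet, D: DiscriminatorNet, config: TrainConfig, out_dir: str | Path) -> None:
    """Flat-array archive (.npz) plus a JSON architecture descriptor."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"g_{i}": p for i, p in enumerate(G.params())}
    arrays.update({f"d_{i}": p for i, p in enumerate(D.params())})
    np.savez(out / "params.npz", **arrays)
    (out / "architecture.json").write_text(json.dumps(config.__dict__, indent=2))


def load_gan(model_dir: str | Path) -> tuple[GeneratorNet, DiscriminatorNet, TrainConfig]:
    model_dir = Path(model_dir)
    config = TrainConfig(**json.loads((model_dir / "architecture.json").read_text()))
    rng = np.random.default_rng(0)
    G = GeneratorNet(config, rng)
    D = DiscriminatorNet(config, rng)
    with np.load(model_dir / "params.npz") as arch:
        for i, p in enumerate(G.params()):
            p[...] = arch[f"g_{i}"]
        for i, p in enumerate(D.params()):
            p[...] = arch[f"d_{i}"]
    return G, D, config
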