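"""Conditional adversarial reconstruction network, implemented in numpy.

The generator maps a standardised 2 x 240 measurement frame (flattened to
480 values) to a 64 x 64 conductivity image in [0, 1]; the discriminator
scores image/measurement pairs.  Training follows the Pix2Pix recipe:
binary cross-entropy adversarial loss plus a strong L1 reconstruction term,
separate Adam optimisers with asymmetric learning rates for generator
(1e-3) and discriminator (1e-8), and Gaussian measurement-noise
augmentation at a configurable peak SNR.

Layers (dense, batch normalisation, leaky ReLU, sigmoid) and their
backward passes are written directly against numpy: the full network is a
few matrix products per step, so a tensor framework is unnecessary and the
arithmetic stays bit-reproducible under a fixed seed.  Only the entry
layer's weight count depends on the measurement vector length, so other
electrode counts (e.g. 32 electrodes, 2 x 992 inputs) reuse the same
architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "leaky_relu",
    "linear_layer",
    "batch_norm",
    "mean_relative_error",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Generator",
    "Discriminator",
    "TrainConfig",
    "TrainLog",
    "train_cgan",
]


# ---------------------------------------------------------------------------
# functional ops

def leaky_relu(x, alpha: float):
    """Piecewise-linear activation: ``alpha * x`` for x < 0, ``x`` otherwise."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    x = np.asarray(x, float)
    return np.where(x < 0, alpha * x, x)


def linear_layer(x, W, b):
    """Affine map ``y = x W^T + b``."""
    x, W, b = np.asarray(x, float), np.asarray(W, float), np.asarray(b, float)
    if x.shape[-1] != W.shape[1]:
        raise ValueError(f"shape mismatch: x has {x.shape[-1]} features, W expects {W.shape[1]}")
    return x @ W.T + b


def batch_norm(x, W, b, running_mean, running_var, eps: float = 1e-5):
    """Normalise by running statistics, then scale and shift:
    ``y = (x - mean) / sqrt(var + eps) * W + b`` (inference path)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    x = np.asarray(x, float)
    return (x - running_mean) / np.sqrt(running_var + eps) * W + b


def mean_relative_error(y_hat, y) -> float:
    """Relative L2 error ``||y_hat - y|| / ||y||`` (the per-epoch image error)."""
    y_hat, y = np.asarray(y_hat, float).ravel(), np.asarray(y, float).ravel()
    ny = np.linalg.norm(y)
    if ny == 0:
        raise ValueError("reference has zero norm; relative error undefined")
    return float(np.linalg.norm(y_hat - y) / ny)


# ---------------------------------------------------------------------------
# layers with manual backward passes

class _Dense:
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        # He-style init, suitable for leaky-ReLU stacks
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        self.dW += g.T @ self._x
        self.db += g.sum(axis=0)
        return g @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm:
    def __init__(self, n, eps=1e-5, momentum=0.1, dtype=np.float32):
        self.W = np.ones(n, dtype)
        self.b = np.zeros(n, dtype)
        self.dW = np.zeros(n, dtype)
        self.db = np.zeros(n, dtype)
        self.running_mean = np.zeros(n, dtype)
        self.running_var = np.ones(n, dtype)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._training = training
        return self._xhat * self.W + self.b

    def backward(self, g):
        self.dW += (g * self._xhat).sum(axis=0)
        self.db += g.sum(axis=0)
        gx = g * self.W
        if not self._training:
            return gx * self._istd
        m = g.shape[0]
        return (self._istd / m) * (m * gx - gx.sum(axis=0)
                                   - self._xhat * (gx * self._xhat).sum(axis=0))

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _LeakyReLU:
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, training):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)

    def params(self):
        return []


class _Sigmoid:
    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)

    def params(self):
        return []


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self):
        for _, grad in self.params():
            grad[...] = 0.0

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name in ("W", "b", "running_mean", "running_var"):
                if hasattr(layer, name):
                    out[f"{i}.{name}"] = getattr(layer, name)
        return out

    def load_state(self, state):
        for key, value in state.items():
            i, name = key.split(".")
            setattr(self.layers[int(i)], name, np.asarray(value))


class _Adam:
    def __init__(self, params, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# network specs and models

@dataclass(frozen=True)
class GeneratorSpec:
    """Fully connected generator: 480 measurements -> 64 x 64 image."""

    input_len: int = 480
    hidden: tuple = (512, 1024)
    out_shape: tuple = (64, 64)
    alpha: float = 0.2
    bn_eps: float = 1e-5
    dtype: str = "float32"


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Conditional discriminator: (image, measurement vector) -> probability."""

    image_shape: tuple = (64, 64)
    cond_len: int = 480
    hidden: tuple = (256, 64)
    alpha: float = 0.2
    dtype: str = "float32"


class Generator:
    def __init__(self, spec: GeneratorSpec = GeneratorSpec(), rng_seed=0):
        rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
        self.spec = spec
        dt = np.dtype(spec.dtype).type
        n_out = spec.out_shape[0] * spec.out_shape[1]
        layers = []
        n_prev = spec.input_len
        for width in spec.hidden:
            layers += [_Dense(n_prev, width, rng, dt),
                       _BatchNorm(width, eps=spec.bn_eps, dtype=dt),
                       _LeakyReLU(spec.alpha)]
            n_prev = width
        layers += [_Dense(n_prev, n_out, rng, dt), _Sigmoid()]
        self.net = _Sequential(layers)

    def forward(self, measurements, training=False):
        """Map measurement input(s) to image(s) in [0, 1].

        Accepts one ``2 x M`` frame or a batch ``(B, 2, M)`` / ``(B, 2M)``;
        returns ``out_shape`` or ``(B,) + out_shape``.
        """
        x = np.asarray(measurements, float)
        single = (x.ndim == 1 and x.size == self.spec.input_len) or (
            x.ndim == 2 and x.shape == (2, self.spec.input_len // 2))
        flat = x.reshape(1, -1) if single else x.reshape(x.shape[0], -1)
        if flat.shape[1] != self.spec.input_len:
            raise ValueError(f"expected input length {self.spec.input_len}, got {flat.shape[1]}")
        out = self.net.forward(flat.astype(self.spec.dtype, copy=False), training)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("generator produced non-finite values (training divergence)")
        imgs = out.reshape((-1,) + self.spec.out_shape)
        return imgs[0] if single else imgs

    def weight_shapes(self):
        return [tuple(layer.W.shape) for layer in self.net.layers if isinstance(layer, _Dense)]


class Discriminator:
    def __init__(self, spec: DiscriminatorSpec = DiscriminatorSpec(), rng_seed=0):
        rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
        self.spec = spec
        dt = np.dtype(spec.dtype).type
        n_img = spec.image_shape[0] * spec.image_shape[1]
        layers = []
        n_prev = n_img + spec.cond_len
        for width in spec.hidden:
            layers += [_Dense(n_prev, width, rng, dt), _LeakyReLU(spec.alpha)]
            n_prev = width
        layers += [_Dense(n_prev, 1, rng, dt)]
        self.net = _Sequential(layers)
        self._n_img = n_img

    def forward_logits(self, images, conditioning, training=False):
        imgs = np.asarray(images, float)
        cond = np.asarray(conditioning, float)
        single = imgs.shape == self.spec.image_shape
        imgs = imgs.reshape(1, -1) if single else imgs.reshape(imgs.shape[0], -1)
        if imgs.shape[1] != self._n_img:
            raise ValueError(f"expected {self.spec.image_shape} images, got {images.shape}")
        cond = cond.reshape(imgs.shape[0], -1)
        z = self.net.forward(np.concatenate([imgs, cond], axis=1).astype(self.spec.dtype,
                                                                          copy=False), training)
        return z[0, 0] if single else z[:, 0]

    def forward(self, images, conditioning, training=False):
        """Probability that (image, measurement) is a ground-truth pair."""
        z = self.forward_logits(images, conditioning, training)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def weight_shapes(self):
        return [tuple(layer.W.shape) for layer in self.net.layers if isinstance(layer, _Dense)]


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-8
    epochs: int = 100
    batch_size: int = 32
    snr_db: float = 30.0          # measurement-noise augmentation; inf disables
    l1_weight: float = 100.0
    seed: int = 0
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)

    def __post_init__(self):
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainLog:
    generator_loss: list = field(default_factory=list)
    discriminator_loss: list = field(default_factory=list)
    test_ie: list = field(default_factory=list)
    collapse_warning: bool = False

    def as_dict(self):
        return asdict(self)


def _bce_with_logits(z, target):
    """Mean BCE on logits and its gradient: stable softplus form."""
    loss = np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z))))
    grad = (1.0 / (1.0 + np.exp(-z)) - target) / z.size
    return loss, grad


def augment_measurement_noise(x_raw, snr_db, rng):
    """Per-sample complex Gaussian noise on raw (B, 2, M) re/im stacks,
    referenced to each frame's peak magnitude."""
    if np.isinf(snr_db):
        return x_raw
    mag = np.sqrt(x_raw[:, 0] ** 2 + x_raw[:, 1] ** 2)
    sd = mag.max(axis=1) / 10.0 ** (snr_db / 20.0)
    return x_raw + sd[:, None, None] * rng.standard_normal(x_raw.shape)


class Standardizer:
    """Per-channel z-scoring of the 2 x M measurement input."""

    def __init__(self, mean, sd):
        self.mean = np.asarray(mean, float)
        self.sd = np.asarray(sd, float)

    @classmethod
    def fit(cls, x_raw):
        mean = x_raw.mean(axis=0)
        sd = x_raw.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean, sd)

    def __call__(self, x_raw):
        return (x_raw - self.mean) / self.sd


def train_cgan(train_inputs, train_targets, test_inputs, test_targets,
               config: TrainConfig = TrainConfig(),
               standardizer: Optional[Standardizer] = None,
               out_dir=None, progress: bool = False):
    """Adversarial training loop (Pix2Pix convention).

    ``train_inputs`` / ``test_inputs`` are raw (unstandardised) measurement
    stacks of shape (N, 2, M); targets are (N, H, W) images in [0, 1].
    Standardisation constants are fitted on the training split only (or
    passed in).  Returns ``(generator, discriminator, log)``.

    Noise augmentation at ``config.snr_db`` is re-drawn per batch on the raw
    scale before standardisation.  The test-split mean relative image error
    (IE) is logged each epoch.  A discriminator whose loss stays below 1e-4
    for three consecutive epochs triggers a collapse warning.
    """
    rng = np.random.default_rng(config.seed)
    x_train = np.asarray(train_inputs, float)
    y_train = np.asarray(train_targets, np.dtype(config.generator.dtype)).reshape(
        len(train_inputs), -1)
    x_test = np.asarray(test_inputs, float)
    y_test = np.asarray(test_targets, float)
    if standardizer is None:
        standardizer = Standardizer.fit(x_train)

    gen = Generator(config.generator, rng_seed=rng)
    disc = Discriminator(config.discriminator, rng_seed=rng)
    opt_g = _Adam(gen.net.params(), config.lr_generator)
    opt_d = _Adam(disc.net.params(), config.lr_discriminator)
    log = TrainLog()
    n = len(x_train)
    n_img = y_train.shape[1]
    collapse_run = 0

    x_test_std = standardizer(x_test).reshape(len(x_test), -1)

    epochs = range(config.epochs)
    if progress:
        from tqdm import tqdm

        epochs = tqdm(epochs, desc="train")
    for epoch in epochs:
        order = rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb_raw = augment_measurement_noise(x_train[sel], config.snr_db, rng)
            xb = standardizer(xb_raw).reshape(len(sel), -1)
            yb = y_train[sel]

            # --- discriminator step (real pairs -> 1, reconstructions -> 0)
            y_fake = gen.forward(xb, training=True).reshape(len(sel), -1)
            disc.net.zero_grad()
            z_real = disc.forward_logits(yb.reshape(len(sel), -1), xb, training=True)
            loss_r, gr = _bce_with_logits(z_real, 1.0)
            disc.net.backward(gr.reshape(-1, 1))
            z_fake = disc.forward_logits(y_fake, xb, training=True)
            loss_f, gf = _bce_with_logits(z_fake, 0.0)
            disc.net.backward(gf.reshape(-1, 1))
            d_loss = 0.5 * (loss_r + loss_f)
            for _, grad in disc.net.params():
                grad *= 0.5
            opt_d.step()

            # --- generator step: fool the discriminator + L1 reconstruction
            gen.net.zero_grad()
            y_fake = gen.forward(xb, training=True).reshape(len(sel), -1)
            disc.net.zero_grad()
            z = disc.forward_logits(y_fake, xb, training=True)
            adv_loss, gz = _bce_with_logits(z, 1.0)
            g_into_input = disc.net.backward(gz.reshape(-1, 1))
            g_img = g_into_input[:, :n_img]
            diff = y_fake - yb
            l1_loss = np.abs(diff).mean()
            g_l1 = np.sign(diff) / diff.size
            gen.net.backward(g_img + config.l1_weight * g_l1)
            opt_g.step()

            g_loss = adv_loss + config.l1_weight * l1_loss
            if not (np.isfinite(g_loss) and np.isfinite(d_loss)):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (non-finite loss)")
            g_losses.append(g_loss)
            d_losses.append(d_loss)

        y_pred = gen.forward(x_test_std, training=False)
        ie = float(np.mean([mean_relative_error(p, t) for p, t in zip(y_pred, y_test)]))
        log.generator_loss.append(float(np.mean(g_losses)))
        log.discriminator_loss.append(float(np.mean(d_losses)))
        log.test_ie.append(ie)

        if log.discriminator_loss[-1] < 1e-4:
            collapse_run += 1
            if collapse_run >= 3 and not log.collapse_warning:
                log.collapse_warning = True
                import warnings

                warnings.warn("discriminator loss collapsed toward zero for "
                              "3 consecutive epochs")
        else:
            collapse_run = 0

        if out_dir is not None:
            _save_checkpoint(Path(out_dir), gen, disc, standardizer, config, log)

    return gen, disc, log


def _save_checkpoint(out_dir: Path, gen, disc, standardizer, config, log):
    out_dir.mkdir(parents=True, exist_ok=True)
    state = {f"gen_{k}": v for k, v in gen.net.state().items()}
    state.update({f"disc_{k}": v for k, v in disc.net.state().items()})
    state["std_mean"] = standardizer.mean
    state["std_sd"] = standardizer.sd
    np.savez_compressed(out_dir / "checkpoint_last.npz", **state)
    meta = {"config": {k: v for k, v in asdict(config).items()
                       if not isinstance(v, dict)},
            "generator_spec": asdict(config.generator),
            "discriminator_spec": asdict(config.discriminator),
            "log": log.as_dict()}
    (out_dir / "training_log.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path):
    """Rebuild (generator, discriminator, standardizer) from a checkpoint."""
    path = Path(path)
    z = np.load(path / "checkpoint_last.npz" if path.is_dir() else path)
    meta = json.loads((path / "training_log.json").read_text()) if path.is_dir() else None
    gspec = GeneratorSpec(**{**asdict(GeneratorSpec()), **(meta["generator_spec"] if meta else {})})
    dspec = DiscriminatorSpec(**{**asdict(DiscriminatorSpec()), **(meta["discriminator_spec"] if meta else {})})
    gspec = GeneratorSpec(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in asdict(gspec).items()})
    dspec = DiscriminatorSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in asdict(dspec).items()})
    gen = Generator(gspec)
    disc = Discriminator(dspec)
    gen.net.load_state({k[4:]: v for k, v in z.items() if k.startswith("gen_")})
    disc.net.load_state({k[5:]: v for k, v in z.items() if k.startswith("disc_")})
    std = Standardizer(z["std_mean"], z["std_sd"])
    return gen, disc, std
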