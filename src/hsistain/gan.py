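"""Conditional GAN translating compressed HSI patches into stain images.

A U-Net generator G maps a PCA-compressed 3-channel patch x to a
histopathology-like patch G(x); a three-block patch discriminator D
scores (x, y) pairs.  The losses are

    L(G; D) = -log D(G(x)) + lambda * L1(G(x), y)
              - nu * log[(1 + SSIM(G(x), y)) / 2]
    L(D; G) = -log D(y) - log(1 - D(G(x)))

with lambda = nu = 100 by default.  Training uses Adam with the default
moment constants, batch size one under instance normalization, a
constant learning rate followed by a linear decay over the final epochs,
and one model per target (dab_abeta, dab_ptau, fluo_abeta, fluo_ptau)
trained separately.

Networks run in [-1, 1]; the L1 and SSIM loss terms are computed on
[0, 1]-scaled images (lambda therefore weights mean absolute error in
units of the dynamic range), and the SSIM inside the loss is the global
per-patch index of the metrics module with its gradient in closed form.
Everything runs on the in-repo numpy conv-net engine, which keeps
training bit-reproducible under a fixed seed on a fixed platform.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .metrics import SSIMParams, ssim

__all__ = [
    "LossWeights",
    "TrainConfig",
    "ModelBundle",
    "CGANTranslator",
    "generator_loss",
    "discriminator_loss",
    "train_model",
    "predict_patches",
    "TARGETS",
]

TARGETS = ("dab_abeta", "dab_ptau", "fluo_abeta", "fluo_ptau")
_EPS = 1e-7  # probability clamp so logged losses stay finite


@dataclass
class LossWeights:
    lambda_l1: float = 100.0
    nu_ssim: float = 100.0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.nu_ssim < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the full-scale recipe.

    ``learning_rate`` defaults per target (1e-5 for DAB models, 5e-6 for
    fluorescence models); batch size is fixed at one, matching instance
    normalization; the rate is constant for ``epochs - decay_epochs``
    epochs, then decays linearly to zero.  ``tiny()`` is the desk-scale
    preset: 3 levels, base width 16, 20 epochs, learning rate 2e-4 (the
    conventional rate for this conditional-GAN family when training
    small models from scratch).
    """

    learning_rate: float | None = None
    batch_size: int = 1
    normalization: str = "instance"
    epochs: int = 135
    decay_epochs: int = 50
    depth: int = 6
    base_width: int = 64
    max_width: int = 512
    seed: int = 0
    checkpoint_every: int = 0  # in epochs; 0 disables

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("batch_size must be 1 (instance normalization)")
        if self.decay_epochs > self.epochs:
            raise ValueError("decay_epochs cannot exceed total epochs")
        if self.normalization != "instance":
            raise ValueError("only instance normalization is supported")

    @classmethod
    def tiny(cls, epochs: int = 20, seed: int = 0) -> "TrainConfig":
        return cls(learning_rate=2e-4, epochs=epochs,
                   decay_epochs=max(1, epochs // 2), depth=3, base_width=16,
                   max_width=64, seed=seed)

    def resolved_lr(self, target: str) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-5 if target.startswith("dab") else 5e-6

    def lr_at_epoch(self, target: str, epoch: int) -> float:
        base = self.resolved_lr(target)
        flat = self.epochs - self.decay_epochs
        if epoch < flat:
            return base
        return base * (self.epochs - epoch) / max(1, self.decay_epochs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# losses, scalar form as printed


def _check_score(score: float, name: str, lo_open: bool = True,
                 hi_open: bool = False) -> None:
    """Scores live in (0,1); a boundary is allowed only where the log
    it feeds stays finite (D=1 for -log D, D=0 for -log(1-D))."""
    lo_ok = score > 0.0 if lo_open else score >= 0.0
    hi_ok = score < 1.0 if hi_open else score <= 1.0
    if not (lo_ok and hi_ok):
        raise ValueError(f"{name} is outside the domain of its log term, got {score}")


def generator_loss(g_out, y, d_score: float, weights: LossWeights | None = None,
                   ssim_params: SSIMParams | None = None) -> dict:
    """Three-term generator loss; returns the total and each term.

    Images are on the 8-bit scale; the L1 term is the mean absolute
    difference in units of the dynamic range, so a uniform 10-gray-level
    error contributes ``lambda * 10/255``.
    """
    weights = weights or LossWeights()
    ssim_params = ssim_params or SSIMParams()
    _check_score(d_score, "d_score", lo_open=True, hi_open=False)
    g_arr = np.asarray(g_out, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if g_arr.shape != y_arr.shape:
        raise ValueError(f"geometry mismatch: {g_arr.shape} vs {y_arr.shape}")
    adv = -math.log(d_score)
    l1 = weights.lambda_l1 * float(np.mean(np.abs(g_arr - y_arr))) / ssim_params.dynamic_range
    s = ssim(g_arr, y_arr, ssim_params)
    ssim_term = -weights.nu_ssim * math.log((1.0 + s) / 2.0)
    return {"total": adv + l1 + ssim_term, "adversarial": adv, "l1": l1,
            "ssim": ssim_term, "ssim_value": s}


def discriminator_loss(d_real: float, d_fake: float) -> float:
    """``-log D(y) - log(1 - D(G(x)))``."""
    _check_score(d_real, "d_real", lo_open=True, hi_open=False)
    _check_score(d_fake, "d_fake", lo_open=False, hi_open=True)
    return -math.log(d_real) - math.log(1.0 - d_fake)


def _ssim_and_grad(x: np.ndarray, y: np.ndarray, c1: float, c2: float):
    """Global SSIM of CHW images in [0, 1] and its gradient w.r.t. x."""
    channels = x.shape[0]
    n = x.shape[1] * x.shape[2]
    grad = np.empty_like(x)
    total = 0.0
    for ch in range(channels):
        xi, yi = x[ch], y[ch]
        mx, my = xi.mean(), yi.mean()
        dx, dy = xi - mx, yi - my
        vx, vy = (dx * dx).mean(), (dy * dy).mean()
        cxy = (dx * dy).mean()
        a1, a2 = 2 * mx * my + c1, 2 * cxy + c2
        b1, b2 = mx * mx + my * my + c1, vx + vy + c2
        s = (a1 * a2) / (b1 * b2)
        ds = ((2 * my / n) * a2 + a1 * (2 * dy / n)) / (b1 * b2) \
            - s * (2 * mx / (n * b1) + 2 * dx / (n * b2))
        grad[ch] = ds / channels
        total += s
    return total / channels, grad


# ---------------------------------------------------------------------------
# networks


class UNetGenerator:
    """U-Net: strided-conv encoder, nearest-up decoder, additive skips."""

    def __init__(self, in_ch: int, out_ch: int, depth: int, base: int,
                 max_width: int, rng: np.random.Generator):
        self.depth = depth
        widths = [min(base * 2**i, max_width) for i in range(depth + 1)]
        self.inc = _nn.Sequential(_nn.Conv2d(in_ch, widths[0], 3, 1, rng),
                                  _nn.InstanceNorm(widths[0]), _nn.LeakyReLU())
        self.downs = [
            _nn.Sequential(_nn.Conv2d(widths[i], widths[i + 1], 3, 2, rng),
                           _nn.InstanceNorm(widths[i + 1]), _nn.LeakyReLU())
            for i in range(depth)
        ]
        # ups[i] consumes the level depth-i feature, skip level depth-1-i
        self.ups = [
            _nn.Sequential(_nn.Upsample2(),
                           _nn.Conv2d(widths[lev + 1], widths[lev], 3, 1, rng),
                           _nn.InstanceNorm(widths[lev]), _nn.ReLU())
            for lev in reversed(range(depth))
        ]
        self.outc = _nn.Conv2d(widths[0], out_ch, 3, 1, rng)
        self.act = _nn.Tanh()

    def params(self):
        ps = self.inc.params() + self.outc.params()
        for blk in self.downs + self.ups:
            ps += blk.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = [self.inc.forward(x)]
        for blk in self.downs:
            s.append(blk.forward(s[-1]))
        h = s[self.depth]
        for i, blk in enumerate(self.ups):
            h = blk.forward(h) + s[self.depth - 1 - i]
        return self.act.forward(self.outc.forward(h))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.outc.backward(self.act.backward(grad))
        skip_grads = [None] * self.depth  # indexed by encoder level
        for i in reversed(range(self.depth)):
            level = self.depth - 1 - i
            skip_grads[level] = grad
            grad = self.ups[i].backward(grad)
        for level in reversed(range(self.depth)):
            grad = self.downs[level].backward(grad) + skip_grads[level]
        return self.inc.backward(grad)


class PatchDiscriminator:
    """Three convolutional blocks scoring overlapping patches (sigmoid)."""

    def __init__(self, in_ch: int, base: int, rng: np.random.Generator):
        self.net = _nn.Sequential(
            _nn.Conv2d(in_ch, base, 4, 2, rng), _nn.LeakyReLU(),
            _nn.Conv2d(base, base * 2, 4, 2, rng), _nn.InstanceNorm(base * 2),
            _nn.LeakyReLU(),
            _nn.Conv2d(base * 2, 1, 4, 1, rng),
        )

    def params(self):
        return self.net.params()

    def forward_logits(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        self._in_ch_x = x.shape[0]
        return self.net.forward(np.concatenate([x, y], axis=0))

    def backward_to_y(self, grad_logits: np.ndarray) -> np.ndarray:
        return self.net.backward(grad_logits)[self._in_ch_x:]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# bundle and estimator


@dataclass
class ModelBundle:
    """A trained generator/discriminator pair with provenance."""

    target: str
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    config: TrainConfig
    weights: LossWeights
    train_log: list = field(default_factory=list)
    input_shape: tuple | None = None  # (rows, cols, 3)
    output_channels: int = 3
    manifest: dict = field(default_factory=dict)

    def save(self, path) -> None:
        arrays = {}
        for i, p in enumerate(self.generator.params()):
            arrays[f"g{i}"] = p.value
        for i, p in enumerate(self.discriminator.params()):
            arrays[f"d{i}"] = p.value
        meta = {
            "target": self.target,
            "config": asdict(self.config),
            "weights": asdict(self.weights),
            "train_log": self.train_log,
            "input_shape": list(self.input_shape) if self.input_shape else None,
            "output_channels": self.output_channels,
            "manifest": self.manifest,
        }
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["meta"]))
        config = TrainConfig(**meta["config"])
        weights = LossWeights(**meta["weights"])
        rng = np.random.default_rng(0)
        gen = UNetGenerator(3, meta["output_channels"], config.depth,
                            config.base_width, config.max_width, rng)
        disc = PatchDiscriminator(3 + meta["output_channels"], config.base_width, rng)
        for i, p in enumerate(gen.params()):
            p.value = archive[f"g{i}"].astype(_nn.DTYPE)
        for i, p in enumerate(disc.params()):
            p.value = archive[f"d{i}"].astype(_nn.DTYPE)
        ishape = meta["input_shape"]
        return cls(meta["target"], gen, disc, config, weights, meta["train_log"],
                   tuple(ishape) if ishape else None, meta["output_channels"],
                   meta["manifest"])


def _to_net(img: np.ndarray) -> np.ndarray:
    """uint8 HWC (or HW) -> float32 CHW in [-1, 1]."""
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return (np.moveaxis(arr, 2, 0) / 127.5) - 1.0


def _from_net(g: np.ndarray) -> np.ndarray:
    """float CHW in [-1, 1] -> uint8 HWC (squeezed if single channel)."""
    out = np.clip(np.round((np.moveaxis(g, 0, 2) + 1.0) * 127.5), 0, 255).astype(np.uint8)
    return out[:, :, 0] if out.shape[2] == 1 else out


class CGANTranslator:
    """Scikit-learn-style estimator around the conditional GAN.

    ``fit`` trains on the ``role == "train"`` members of a TrainingPair
    list; ``predict`` maps compressed patches to stain patches.  Fitted
    attributes: ``generator_``, ``discriminator_``, ``train_log_``.
    """

    def __init__(self, target: str = "dab_ptau",
                 config: TrainConfig | None = None,
                 weights: LossWeights | None = None):
        if target not in TARGETS:
            raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
        self.target = target
        self.config = config or TrainConfig()
        self.weights = weights or LossWeights()

    def get_params(self, deep: bool = True) -> dict:
        return {"target": self.target, "config": self.config, "weights": self.weights}

    def set_params(self, **params) -> "CGANTranslator":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- training ----------------------------------------------------------

    def fit(self, pairs, checkpoint_dir=None) -> "CGANTranslator":
        train_pairs = [p for p in pairs if getattr(p, "role", "train") == "train"]
        if not train_pairs:
            raise ValueError("empty training dataset")
        kind = "dab" if self.target.startswith("dab") else "fluorescence"
        for p in train_pairs:
            if getattr(p, "stain_kind", kind) != kind:
                raise ValueError(
                    f"pair stain kind {p.stain_kind!r} does not match target {self.target!r}"
                )
        cfg, w = self.config, self.weights
        xs = [_to_net(p.x) for p in train_pairs]
        ys = [_to_net(p.y) for p in train_pairs]
        out_ch = ys[0].shape[0]
        rng = np.random.default_rng(cfg.seed)
        gen = UNetGenerator(xs[0].shape[0], out_ch, cfg.depth, cfg.base_width,
                            cfg.max_width, rng)
        disc = PatchDiscriminator(xs[0].shape[0] + out_ch, cfg.base_width, rng)
        opt_g = _nn.Adam(gen.params(), cfg.resolved_lr(self.target))
        opt_d = _nn.Adam(disc.params(), cfg.resolved_lr(self.target))
        c1, c2 = (0.01) ** 2, (0.03) ** 2  # SSIM constants on the [0,1] scale
        n_px = None
        log = []
        for epoch in range(cfg.epochs):
            lr = cfg.lr_at_epoch(self.target, epoch)
            opt_g.lr = opt_d.lr = lr
            order = rng.permutation(len(train_pairs))
            sums = {"g_total": 0.0, "g_adv": 0.0, "g_l1": 0.0, "g_ssim": 0.0,
                    "d_loss": 0.0}
            for step, idx in enumerate(order):
                x, y = xs[idx], ys[idx]
                if n_px is None:
                    n_px = float(y.size)
                g = gen.forward(x)

                # discriminator update (real + fake, grads via logits)
                opt_d.zero_grad()
                z_fake = disc.forward_logits(x, g)
                p_fake = _sigmoid(z_fake)
                disc.net.backward(p_fake / p_fake.size)
                z_real = disc.forward_logits(x, y)
                p_real = _sigmoid(z_real)
                disc.net.backward((p_real - 1.0) / p_real.size)
                opt_d.step()
                d_loss = (-np.log(np.clip(p_real, _EPS, None)).mean()
                          - np.log(np.clip(1.0 - p_fake, _EPS, None)).mean())

                # generator update against the updated discriminator
                opt_g.zero_grad()
                z_fake2 = disc.forward_logits(x, g)
                p_fake2 = _sigmoid(z_fake2)
                grad_g = disc.backward_to_y((p_fake2 - 1.0) / p_fake2.size)
                g01, y01 = (g + 1.0) * 0.5, (y + 1.0) * 0.5
                diff = g01 - y01
                l1_val = w.lambda_l1 * float(np.abs(diff).mean())
                grad_g = grad_g + (w.lambda_l1 * np.sign(diff) / n_px) * 0.5
                s_val, ds = _ssim_and_grad(g01, y01, c1, c2)
                ssim_val = -w.nu_ssim * math.log((1.0 + s_val) / 2.0)
                grad_g = grad_g + (-w.nu_ssim / (1.0 + s_val)) * ds * 0.5
                gen.backward(grad_g.astype(_nn.DTYPE))
                opt_g.step()

                adv_val = float(-np.log(np.clip(p_fake2, _EPS, None)).mean())
                total = adv_val + l1_val + ssim_val
                if not math.isfinite(total) or not math.isfinite(d_loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, step {step}: "
                        f"G={total}, D={d_loss}"
                    )
                sums["g_total"] += total
                sums["g_adv"] += adv_val
                sums["g_l1"] += l1_val
                sums["g_ssim"] += ssim_val
                sums["d_loss"] += float(d_loss)
            n = len(train_pairs)
            entry = {"epoch": epoch, "lr": lr}
            entry.update({k: v / n for k, v in sums.items()})
            log.append(entry)
            if (checkpoint_dir is not None and cfg.checkpoint_every > 0
                    and (epoch + 1) % cfg.checkpoint_every == 0):
                self._snapshot(gen, disc, log, train_pairs[0]).save(
                    Path(checkpoint_dir) / f"checkpoint_epoch{epoch + 1:03d}.npz")

        self.generator_ = gen
        self.discriminator_ = disc
        self.train_log_ = log
        self.input_shape_ = train_pairs[0].x.shape
        self.output_channels_ = out_ch
        return self

    def _snapshot(self, gen, disc, log, pair0) -> ModelBundle:
        return ModelBundle(self.target, gen, disc, self.config, self.weights,
                           list(log), pair0.x.shape,
                           _to_net(pair0.y).shape[0],
                           {"config_hash": self.config.config_hash()})

    # -- inference ---------------------------------------------------------

    def predict(self, x_patches) -> list:
        if not hasattr(self, "generator_"):
            raise RuntimeError("CGANTranslator is not fitted")
        out = []
        for x in x_patches:
            x = np.asarray(x)
            if x.shape != self.input_shape_:
                raise ValueError(
                    f"patch geometry {x.shape} does not match training geometry "
                    f"{self.input_shape_}"
                )
            out.append(_from_net(self.generator_.forward(_to_net(x))))
        return out

    def to_bundle(self, dataset_hash: str = "") -> ModelBundle:
        if not hasattr(self, "generator_"):
            raise RuntimeError("CGANTranslator is not fitted")
        manifest = {"config_hash": self.config.config_hash(),
                    "dataset_hash": dataset_hash, "target": self.target}
        return ModelBundle(self.target, self.generator_, self.discriminator_,
                           self.config, self.weights, self.train_log_,
                           self.input_shape_, self.output_channels_, manifest)


def train_model(dataset, target: str, config: TrainConfig | None = None,
                weights: LossWeights | None = None, checkpoint_dir=None) -> ModelBundle:
    """Train one of the four translation models; functional wrapper."""
    config = config or TrainConfig()
    est = CGANTranslator(target, config, weights)
    if config.epochs == 0:
        # initialized bundle, no updates, empty log
        pairs = [p for p in dataset if getattr(p, "role", "train") == "train"]
        if not pairs:
            raise ValueError("empty training dataset")
        rng = np.random.default_rng(config.seed)
        out_ch = _to_net(pairs[0].y).shape[0]
        gen = UNetGenerator(3, out_ch, config.depth, config.base_width,
                            config.max_width, rng)
        disc = PatchDiscriminator(3 + out_ch, config.base_width, rng)
        return ModelBundle(target, gen, disc, config, est.weights, [],
                           pairs[0].x.shape, out_ch,
                           {"config_hash": config.config_hash()})
    est.fit(dataset, checkpoint_dir=checkpoint_dir)
    return est.to_bundle()


def predict_patches(bundle: ModelBundle, x_patches) -> list:
    """Inference through a trained bundle (deterministic)."""
    out = []
    for x in x_patches:
        x = np.asarray(x)
        if bundle.input_shape is not None and x.shape != bundle.input_shape:
            raise ValueError(
                f"patch geometry {x.shape} does not match training geometry "
                f"{bundle.input_shape}"
            )
        out.append(_from_net(bundle.generator.forward(_to_net(x))))
    return out
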