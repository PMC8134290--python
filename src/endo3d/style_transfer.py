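"""Unpaired real-to-virtual image translation (cycleGAN).

Two translators are learned from unpaired image folders: ``G: X -> Y`` maps
the real endoscopic domain X into the synthetic-render domain Y (the
direction the depth network needs), and ``F: Y -> X`` maps back.  Patch
discriminators ``D_x`` and ``D_y`` score whether local patches look like
their domain.  Training combines least-squares adversarial losses with a
cycle-consistency L1 term weighted by ``lambda`` (default 10):

    total = L_GAN(G, D_y) + L_GAN(F, D_x) + lambda * L_cyc
    L_cyc = E||F(G(x)) - x||_1 + E||G(F(y)) - y||_1

Generators are the downsample / residual / fractionally-strided-upsample
architecture (two stride-2 convolutions in, residual blocks, two stride-1/2
transposed convolutions out); no identity-mapping term is used.  The desk
configuration (64 x 64, 2 residual blocks, few epochs) trains on one CPU;
the full-scale recipe (288 x 256, 9 residual blocks, 200 epochs, 70 x 70
patches) is available via :meth:`StyleTransferConfig.paper_scale`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn

__all__ = [
    "StyleTransferConfig",
    "TranslatorPair",
    "Generator",
    "PatchDiscriminator",
    "cyclegan_total_loss",
    "train_cyclegan",
    "translate_real_to_virtual",
    "save_cyclegan_checkpoint",
    "load_cyclegan_checkpoint",
]


@dataclass
class StyleTransferConfig:
    image_size: tuple[int, int] = (64, 64)  # (H, W)
    base_channels: int = 12
    n_residual_blocks: int = 2
    n_discriminator_layers: int = 2
    cycle_weight: float = 10.0
    epochs: int = 5
    batch_size: int = 1
    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_weight < 0:
            raise ValueError("cycle_weight must be >= 0")
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("training hyperparameters must be positive")

    @classmethod
    def paper_scale(cls) -> "StyleTransferConfig":
        # 288 x 256 inputs, 9 residual blocks, 70 x 70 patch discriminators,
        # 200 epochs at batch size 1
        return cls(
            image_size=(256, 288),
            base_channels=64,
            n_residual_blocks=9,
            n_discriminator_layers=3,
            epochs=200,
        )


class Generator(nn.Module):
    """c7s1 stem, two stride-2 downs, residual core, two stride-1/2 ups."""

    def __init__(self, config: StyleTransferConfig, rng: np.random.Generator):
        c = config.base_channels
        self.stem = nn.Conv2d(3, c, 7, 1, 3, rng)
        self.norm0 = nn.InstanceNorm2d(c)
        self.down1 = nn.Conv2d(c, 2 * c, 3, 2, 1, rng)
        self.norm1 = nn.InstanceNorm2d(2 * c)
        self.down2 = nn.Conv2d(2 * c, 4 * c, 3, 2, 1, rng)
        self.norm2 = nn.InstanceNorm2d(4 * c)
        self.blocks = [
            nn.ResidualBlock(4 * c, rng) for _ in range(config.n_residual_blocks)
        ]
        self.up1 = nn.ConvTranspose2d(4 * c, 2 * c, 4, 2, 1, rng)
        self.norm3 = nn.InstanceNorm2d(2 * c)
        self.up2 = nn.ConvTranspose2d(2 * c, c, 4, 2, 1, rng)
        self.norm4 = nn.InstanceNorm2d(c)
        self.head = nn.Conv2d(c, 3, 7, 1, 3, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.norm0(self.stem(x)).relu()
        h = self.norm1(self.down1(h)).relu()
        h = self.norm2(self.down2(h)).relu()
        for b in self.blocks:
            h = b(h)
        h = self.norm3(self.up1(h)).relu()
        h = self.norm4(self.up2(h)).relu()
        return self.head(h).sigmoid()  # images live in [0, 1]


class PatchDiscriminator(nn.Module):
    """PatchGAN: a grid of real/fake scores over overlapping patches."""

    def __init__(self, config: StyleTransferConfig, rng: np.random.Generator):
        c = config.base_channels
        mods: list[nn.Module] = [nn.Conv2d(3, c, 4, 2, 1, rng), nn.LeakyReLU(0.2)]
        ch = c
        for _ in range(config.n_discriminator_layers - 1):
            mods += [
                nn.Conv2d(ch, 2 * ch, 4, 2, 1, rng),
                nn.InstanceNorm2d(2 * ch),
                nn.LeakyReLU(0.2),
            ]
            ch *= 2
        mods.append(nn.Conv2d(ch, 1, 4, 1, 1, rng))
        self.net = nn.Sequential(*mods)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.net(x)


@dataclass
class TranslatorPair:
    G: Generator  # X (real) -> Y (synthetic style)
    F: Generator  # Y -> X
    D_x: PatchDiscriminator
    D_y: PatchDiscriminator
    config: StyleTransferConfig
    history: list[dict] = field(default_factory=list)

    @classmethod
    def initialize(cls, config: StyleTransferConfig) -> "TranslatorPair":
        rng = np.random.default_rng(config.seed)
        return cls(
            G=Generator(config, rng),
            F=Generator(config, rng),
            D_x=PatchDiscriminator(config, rng),
            D_y=PatchDiscriminator(config, rng),
            config=config,
        )


# ----------------------------------------------------------------------
# Losses
# ----------------------------------------------------------------------

def _lsgan_toward(d_out: nn.Tensor, target: float) -> nn.Tensor:
    return (d_out - target).pow(2).mean()


def cyclegan_total_loss(
    batch_x: np.ndarray,
    batch_y: np.ndarray,
    models: TranslatorPair,
    lam: float | None = None,
):
    """Generator-side objective on one unpaired batch pair.

    Returns a dict of scalar losses (adversarial_G, adversarial_F, cycle,
    total) plus the scalar loss Tensor for backprop.  Adversarial terms are
    least-squares (LSGAN): the translator is pushed toward discriminator
    score 1 on its outputs.
    """
    lam = models.config.cycle_weight if lam is None else lam
    if batch_x.shape[1:] != batch_y.shape[1:]:
        raise ValueError(
            f"domain batches disagree in shape: {batch_x.shape} vs {batch_y.shape}"
        )
    x = nn.Tensor(batch_x)
    y = nn.Tensor(batch_y)
    fake_y = models.G(x)
    fake_x = models.F(y)
    adv_G = _lsgan_toward(models.D_y(fake_y), 1.0)
    adv_F = _lsgan_toward(models.D_x(fake_x), 1.0)
    cyc = nn.l1_loss(models.F(fake_y), x) + nn.l1_loss(models.G(fake_x), y)
    total = adv_G + adv_F + lam * cyc
    scalars = {
        "adversarial_G": float(adv_G.data),
        "adversarial_F": float(adv_F.data),
        "cycle": float(cyc.data),
        "total": float(total.data),
    }
    return scalars, total, (fake_y, fake_x)


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

def _load_domain(directory, size: tuple[int, int]) -> np.ndarray:
    from .io import read_rgb_png

    files = sorted(Path(directory).glob("*.png"))
    if not files:
        raise ValueError(f"no PNG images found in domain directory {directory}")
    H, W = size
    imgs = []
    for f in files:
        img = read_rgb_png(f)
        if img.shape[:2] != (H, W):
            img = resize(img, (H, W), order=1, anti_aliasing=True)
        imgs.append(img.transpose(2, 0, 1).astype(np.float32))
    return np.stack(imgs)


def train_cyclegan(
    real_dir,
    synthetic_dir,
    config: StyleTransferConfig | None = None,
    checkpoint_path=None,
    log_csv=None,
) -> TranslatorPair:
    """Train G/F/D_x/D_y on two unpaired image folders; fully seeded."""
    config = config or StyleTransferConfig()
    X = _load_domain(real_dir, config.image_size)
    Y = _load_domain(synthetic_dir, config.image_size)
    models = TranslatorPair.initialize(config)
    rng = np.random.default_rng(config.seed + 1)
    opt_G = nn.Adam(
        models.G.parameters() + models.F.parameters(),
        config.learning_rate,
        config.betas,
    )
    opt_D = nn.Adam(
        models.D_x.parameters() + models.D_y.parameters(),
        config.learning_rate,
        config.betas,
    )
    steps_per_epoch = max(len(X), len(Y)) // config.batch_size
    step = 0
    for epoch in range(config.epochs):
        for _ in range(steps_per_epoch):
            bx = X[rng.integers(0, len(X), size=config.batch_size)]
            by = Y[rng.integers(0, len(Y), size=config.batch_size)]
            # translators
            scalars, total, (fake_y, fake_x) = cyclegan_total_loss(
                bx, by, models
            )
            opt_G.zero_grad()
            total.backward()
            opt_G.step()
            # discriminators (fakes detached: data only)
            x = nn.Tensor(bx)
            y = nn.Tensor(by)
            d_loss = (
                _lsgan_toward(models.D_y(y), 1.0)
                + _lsgan_toward(models.D_y(nn.Tensor(fake_y.data)), 0.0)
                + _lsgan_toward(models.D_x(x), 1.0)
                + _lsgan_toward(models.D_x(nn.Tensor(fake_x.data)), 0.0)
            ) * 0.5
            opt_D.zero_grad()
            d_loss.backward()
            opt_D.step()
            step += 1
            scalars.update(
                {"epoch": epoch, "step": step, "d_loss": float(d_loss.data)}
            )
            models.history.append(scalars)
    if log_csv is not None:
        with open(log_csv, "w", newline="") as fh:
            w = csv.DictWriter(
                fh,
                fieldnames=[
                    "epoch", "step", "adversarial_G", "adversarial_F",
                    "cycle", "total", "d_loss",
                ],
            )
            w.writeheader()
            w.writerows(models.history)
    if checkpoint_path is not None:
        save_cyclegan_checkpoint(checkpoint_path, models)
    return models


# ----------------------------------------------------------------------
# Inference / checkpoints
# ----------------------------------------------------------------------

def translate_real_to_virtual(img: np.ndarray, G: Generator) -> np.ndarray:
    """Translate one H x W x 3 RGB image in [0, 1]; deterministic."""
    x = np.asarray(img, dtype=np.float32)
    out = G(nn.Tensor(x.transpose(2, 0, 1)[None]))
    return out.data[0].transpose(1, 2, 0).astype(np.float64)


def save_cyclegan_checkpoint(path, models: TranslatorPair) -> None:
    cfg = asdict(models.config)
    cfg["image_size"] = list(models.config.image_size)
    cfg.pop("history", None)
    nn.save_checkpoint(
        path,
        {"G": models.G, "F": models.F, "D_x": models.D_x, "D_y": models.D_y},
        {"style_transfer": cfg},
    )


def load_cyclegan_checkpoint(path) -> TranslatorPair:
    states, cfg = nn.load_checkpoint(path)
    c = cfg["style_transfer"]
    c["image_size"] = tuple(c["image_size"])
    c["betas"] = tuple(c["betas"])
    config = StyleTransferConfig(**c)
    models = TranslatorPair.initialize(config)
    for name, mod in (
        ("G", models.G), ("F", models.F), ("D_x", models.D_x), ("D_y", models.D_y)
    ):
        mod.load_state_dict(states[name])
    return models
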