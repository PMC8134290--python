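"""Differentiable loss building blocks and checkpoint I/O."""

from __future__ import annotations

import json

import numpy as np

from .tensor import Tensor

__all__ = [
    "gaussian_kernel_1d",
    "gaussian_kernel_2d",
    "l1_loss",
    "mse_loss",
    "ssim_tensor",
    "save_checkpoint",
    "load_checkpoint",
]


def gaussian_kernel_1d(sigma: float = 1.5, truncate: float = 3.5) -> np.ndarray:
    """Sampled, normalized Gaussian; radius = int(truncate * sigma)."""
    radius = int(truncate * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_kernel_2d(sigma: float = 1.5, truncate: float = 3.5) -> np.ndarray:
    k = gaussian_kernel_1d(sigma, truncate)
    return np.outer(k, k)


def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    return (pred - target).abs().mean()


def mse_loss(pred: Tensor, target: Tensor) -> Tensor:
    return (pred - target).pow(2).mean()


def ssim_tensor(
    x: Tensor,
    y: Tensor,
    data_range: float = 1.0,
    sigma: float = 1.5,
    truncate: float = 3.5,
) -> Tensor:
    """Differentiable mean SSIM of two N x 1 x H x W tensors.

    Gaussian window (default 11 x 11), population second moments, standard
    stabilizing constants C1 = (0.01 L)^2, C2 = (0.03 L)^2; the mean is taken
    over the valid (fully-windowed) region.  Matches the numpy implementation
    in :mod:`endo3d.evaluation` on identical inputs.
    """
    k2d = gaussian_kernel_2d(sigma, truncate)
    win = k2d.shape[0]
    if x.shape[2] < win or x.shape[3] < win:
        raise ValueError(
            f"image {x.shape[2]}x{x.shape[3]} smaller than SSIM window {win}"
        )
    w = Tensor(k2d[None, None])  # fixed, not trained
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2

    def blur(t: Tensor) -> Tensor:
        return t.conv2d(w, None, 1, 0)

    mu_x, mu_y = blur(x), blur(y)
    mu_xx, mu_yy, mu_xy = mu_x * mu_x, mu_y * mu_y, mu_x * mu_y
    sig_x = blur(x * x) - mu_xx
    sig_y = blur(y * y) - mu_yy
    sig_xy = blur(x * y) - mu_xy
    num = (2.0 * mu_xy + c1) * (2.0 * sig_xy + c2)
    den = (mu_xx + mu_yy + c1) * (sig_x + sig_y + c2)
    return (num / den).mean()


def save_checkpoint(path, modules: dict, config: dict | None = None) -> None:
    """Save named module state dicts (and a JSON config) to one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for mod_name, module in modules.items():
        for k, v in module.state_dict().items():
            arrays[f"{mod_name}/{k}"] = v
    arrays["__config__"] = np.frombuffer(
        json.dumps(config or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, dict[str, np.ndarray]], dict]:
    """Returns ({module_name: state_dict}, config)."""
    data = np.load(path)
    states: dict[str, dict[str, np.ndarray]] = {}
    config: dict = {}
    for key in data.files:
        if key == "__config__":
            config = json.loads(bytes(data[key]).decode())
            continue
        mod_name, param = key.split("/", 1)
        states.setdefault(mod_name, {})[param] = data[key]
    return states, config
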