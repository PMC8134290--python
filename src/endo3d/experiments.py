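"""End-to-end experiment protocols at desk scale.

These drive the same closed loops a full-scale deployment would, shrunk to
sizes that run on one CPU in minutes: the depth network is trained on a few
hundred 64 x 64 simulator frames instead of thousands of full-resolution
renders, and the style-transfer sanity experiment uses a synthetic domain
gap (a fixed channel permutation) whose ground-truth mapping is known, so
convergence can be measured without human judgement.
"""

from __future__ import annotations

import shutil
import tempfile
from pathlib import Path

import numpy as np

from . import simulator as sim
from .depth_net import DepthNetConfig, predict_depth, train_depth
from .evaluation import nrmse as nrmse_metric
from .evaluation import ssim as ssim_metric
from .io import load_manifest, read_depth_png, read_rgb_png, write_rgb_png
from .style_transfer import (
    StyleTransferConfig,
    train_cyclegan,
    translate_real_to_virtual,
)

__all__ = [
    "depth_closed_loop",
    "style_permutation_experiment",
    "channel_histograms",
]


def depth_closed_loop(
    seed: int = 0,
    n_frames: int = 300,
    n_test: int = 50,
    epochs: int = 10,
    image_size: int = 64,
    work_dir: str | Path | None = None,
) -> dict:
    """Generate, train, and score the depth estimator on held-out frames.

    Renders ``n_frames`` along a lumen trajectory, holds out ``n_test`` of
    them, trains the desk-scale depth network on the rest, and reports the
    held-out mean/SD of SSIM and NRMSE on normalized maps.
    """
    cleanup = work_dir is None
    work = Path(work_dir or tempfile.mkdtemp(prefix="endo3d_depth_"))
    try:
        scene = sim.generate_airway_scene(seed=seed)
        traj = sim.generate_trajectory(
            scene, n_frames, speed=2.5, sample_rate=50, seed=seed + 1
        )
        K = sim.default_intrinsics(image_size, image_size)
        sim.generate_dataset(scene, traj, K, out_dir=work / "dataset")
        manifest = load_manifest(work / "dataset")

        rng = np.random.default_rng(seed + 2)
        order = rng.permutation(n_frames)
        test_idx = set(order[:n_test].tolist())
        train_manifest = dict(manifest)
        train_manifest["entries"] = [
            e for e in manifest["entries"] if e["frame_index"] not in test_idx
        ]
        test_entries = [
            e for e in manifest["entries"] if e["frame_index"] in test_idx
        ]

        config = DepthNetConfig(
            input_size=(image_size, image_size), epochs=epochs, seed=seed + 3
        )
        model, history = train_depth(train_manifest, config)

        ssim_vals, nrmse_vals = [], []
        for e in test_entries:
            pred = predict_depth(read_rgb_png(e["rgb_path"]), model)
            gt = read_depth_png(e["depth_path"])
            ssim_vals.append(ssim_metric(pred, gt))
            nrmse_vals.append(nrmse_metric(pred, gt))
        return {
            "n_train": len(train_manifest["entries"]),
            "n_test": len(test_entries),
            "epochs": epochs,
            "final_train_loss": history[-1]["loss"],
            "ssim_mean": float(np.mean(ssim_vals)),
            "ssim_sd": float(np.std(ssim_vals)),
            "nrmse_mean": float(np.mean(nrmse_vals)),
            "nrmse_sd": float(np.std(nrmse_vals)),
            "model": model,
        }
    finally:
        if cleanup:
            shutil.rmtree(work, ignore_errors=True)


def channel_histograms(images: list[np.ndarray], bins: int = 32) -> np.ndarray:
    """Per-channel normalized histograms over a stack of RGB images."""
    arr = np.stack(images)
    return np.stack(
        [
            np.histogram(arr[..., c], bins=bins, range=(0.0, 1.0), density=True)[0]
            for c in range(3)
        ]
    )


def style_permutation_experiment(
    seed: int = 0,
    n_images: int = 40,
    epochs: int = 5,
    image_size: int = 64,
    work_dir: str | Path | None = None,
) -> dict:
    """Train the translators across a known synthetic domain gap.

    Domain X holds simulator renders; domain Y holds renders of a different
    scene with a fixed RGB channel permutation applied, so the two unpaired
    domains differ by exactly one invertible color mapping.  Reported are
    the mean per-channel histogram distance of G(x) to domain Y relative to
    the pre-translation gap, and the cycle reconstruction error of F(G(x)).
    """
    cleanup = work_dir is None
    work = Path(work_dir or tempfile.mkdtemp(prefix="endo3d_style_"))
    perm = [1, 2, 0]
    try:
        K = sim.default_intrinsics(image_size, image_size)
        dir_x = work / "domain_x"
        dir_y = work / "domain_y"
        dir_x.mkdir(parents=True, exist_ok=True)
        dir_y.mkdir(parents=True, exist_ok=True)
        scene_x = sim.generate_airway_scene(seed=seed + 10)
        scene_y = sim.generate_airway_scene(seed=seed + 11)
        traj_x = sim.generate_trajectory(scene_x, n_images, 2.5, 50, seed + 12)
        traj_y = sim.generate_trajectory(scene_y, n_images, 2.5, 50, seed + 13)
        for i in range(n_images):
            fx = sim.render_frame(scene_x, traj_x.poses[i], K)
            write_rgb_png(dir_x / f"{i:03d}.png", fx.rgb)
            fy = sim.render_frame(scene_y, traj_y.poses[i], K)
            write_rgb_png(dir_y / f"{i:03d}.png", fy.rgb[:, :, perm])

        config = StyleTransferConfig(
            image_size=(image_size, image_size), epochs=epochs, seed=seed + 14
        )
        models = train_cyclegan(dir_x, dir_y, config)

        X = [read_rgb_png(p) for p in sorted(dir_x.glob("*.png"))]
        Y = [read_rgb_png(p) for p in sorted(dir_y.glob("*.png"))]
        GX = [translate_real_to_virtual(x, models.G) for x in X]
        h_y = channel_histograms(Y)
        gap_before = float(np.abs(channel_histograms(X) - h_y).mean())
        gap_after = float(np.abs(channel_histograms(GX) - h_y).mean())
        cycle_mae = float(
            np.mean(
                [
                    np.abs(translate_real_to_virtual(gx, models.F) - x).mean()
                    for gx, x in zip(GX, X)
                ]
            )
        )
        first_epoch = [h["cycle"] for h in models.history if h["epoch"] == 0]
        last_epoch = [
            h["cycle"] for h in models.history if h["epoch"] == epochs - 1
        ]
        return {
            "n_images": n_images,
            "epochs": epochs,
            "hist_gap_before": gap_before,
            "hist_gap_after": gap_after,
            "hist_gap_reduction_pct": 100.0 * (1.0 - gap_after / gap_before),
            "cycle_mae": cycle_mae,
            "cycle_first_epoch_mean": float(np.mean(first_epoch)),
            "cycle_last_epoch_mean": float(np.mean(last_epoch)),
            "models": models,
        }
    finally:
        if cleanup:
            shutil.rmtree(work, ignore_errors=True)
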