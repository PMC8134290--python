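# endo3d

Depth-anchored 3D annotation for tracked monocular endoscopy.

During endoscopic sinus and skull-base work, annotations drawn on the video
display are normally 2D: they stick to the screen, not to the anatomy, and
become meaningless the moment the camera moves.  `endo3d` implements the
full pipeline needed to anchor a marker to the *tissue surface* instead,
using only a monocular endoscope and an electromagnetic (EM) pose sensor on
its tip:

1. a **procedural airway simulator** renders endoscopic views of a tubular
   lumen with inverse-square point-light shading and exact per-pixel
   ground-truth depth;
2. a **monocular depth network** (encoder–decoder with skip connections)
   is trained purely on those synthetic pairs;
3. an **unpaired style-transfer network** (two translators G, F with patch
   discriminators, adversarial + cycle-consistency losses) maps real-domain
   frames into the synthetic style so the virtual-trained depth network can
   consume them;
4. **pose integration and anchoring**: with camera intrinsics K, predicted
   depth d at a clicked pixel (u, v), sensor pose ᵉᵐT_s and hand–eye
   transform ᶜT_s,

       p_c = K⁻¹ · d · [u, v, 1]ᵀ
       ʷT_c = ᵉᵐT_s · (ᶜT_s)⁻¹
       [p_w; 1] = ʷT_c · [p_c; 1]

   anchors the marker at the world-frame point p_w, which every later frame
   re-projects (with apparent radius fx·r/z, a natural depth cue);
5. **evaluation protocols**: frame-wise NRMSE and SSIM against ground-truth
   depth, and a stability protocol that tracks a known wall point during
   slow forward–backward camera motion and reports the mean absolute error
   between true and predicted target depth.

Supporting machinery includes SVD least-squares rigid registration
(model → EM frame, with reflection correction), Tsai–Lenz hand–eye
calibration (AX = XB), a simulated noisy EM sensor, Brown–Conrady
undistortion, stream-latency synchronization, and strict YAML-configured,
fully seeded runs.  The networks run on a compact numpy autodiff engine
shipped with the package, so everything trains and evaluates on one CPU.

See `docs/methods.md` for conventions (z-depth, the 0.01–25 mm normalized
span, frame labels) and design rationale.

## Worked example

```python
import numpy as np
from endo3d import simulator as sim
from endo3d.annotation import place_annotation, reproject_annotation
from endo3d.calibration import EMSensorModel
from endo3d.evaluation import OracleDepthProvider, evaluate_stability
from endo3d.geometry import PixelCoord
from endo3d.simulator import normalize_depth

scene = sim.generate_airway_scene(seed=1)
K = sim.default_intrinsics(64, 64)
traj = sim.generate_trajectory(scene, 150, speed=2.5, sample_rate=50,
                               seed=2, mode="forward_backward")

frame0 = sim.render_frame(scene, traj.poses[0], K)
marker = place_annotation(PixelCoord(32, 16), normalize_depth(frame0.depth),
                          K, traj.poses[0], radius=0.5, label="target")
print(f"anchored marker at p_w = {np.round(marker.p_w.as_array(), 3)} mm")

px, radius_px, visible = reproject_annotation(marker, traj.poses[100], K)
print(f"frame 100: pixel ({px.u:.2f}, {px.v:.2f}), "
      f"apparent radius {radius_px:.2f} px, visible={visible}")

trace = evaluate_stability(scene, marker.p_w, traj,
                           OracleDepthProvider(scene, K),
                           EMSensorModel(), K)
print(f"stability trace: {len(trace.timestamps)} samples at 50 Hz, "
      f"MAE = {trace.mae:.6f} mm")
```

Output:

```
anchored marker at p_w = [ 1.413 -3.43  16.565] mm
frame 100: pixel (32.94, 4.05), apparent radius 3.45 px, visible=True
stability trace: 115 samples at 50 Hz, MAE = 0.000000 mm
```

The marker was placed on the lumen wall 16.6 mm down the airway from the
first camera pose.  One hundred frames later — the camera having advanced
and retreated along the lumen — re-projecting the *same world point* puts
it at a different pixel with a smaller apparent radius, i.e. the annotation
tracks the anatomy, not the screen.  With the simulator's exact depth as
the depth source, the stability protocol's reference-vs-predicted MAE is
zero to numerical precision (35 of 150 frames are excluded with a warning
because the target leaves the field of view at the far end of the sweep).
Replacing the oracle with a trained depth model (`NetworkDepthProvider`)
gives the end-to-end stability figure for that model.

## Command-line interface

Every stage is also a subcommand: `endo3d simulate`, `train-style`,
`train-depth`, `translate`, `predict-depth`, `annotate`, `eval-accuracy`,
`eval-stability`, `calibrate` — each taking `--config <yaml>`, `--seed`
and `--out`, writing a manifest with the resolved configuration and its
hash so runs are reproducible byte for byte.

```bash
endo3d simulate --seed 7 --out dataset/
endo3d train-depth --data dataset/ --seed 7 --out run/
endo3d eval-accuracy --pred preds/ --gt dataset/ --out report
```

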