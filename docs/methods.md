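# Methods

`endo3d` implements a depth-anchored 3D annotation pipeline for tracked
monocular endoscopy, together with the simulation and evaluation machinery
needed to test every link of the chain on one CPU.  This note records the
models, conventions, parameters and deliberate design choices.

## Problem setting

A monocular endoscope with a rigidly attached 6-DoF electromagnetic (EM)
pose sensor observes a nasal-airway-like lumen.  A clinician clicks a pixel
(u, v); the system must anchor a small spherical marker to the anatomical
surface under that pixel so that, as the camera moves, the marker stays
fixed to the anatomy (not to the screen) and its apparent size shrinks with
distance.  Doing this requires per-pixel metric depth, which a monocular
camera does not measure; the pipeline estimates it with a convolutional
network trained entirely on synthetic renders, bridged to real imagery by an
unpaired real-to-virtual style transfer network.

## Coordinate and depth conventions

* Right-handed camera frame, +z along the optical axis, +x right, +y down;
  pixel origin top-left, u = column, v = row, pixel centers at integers.
* All lengths in millimetres.  Rigid transforms carry frame labels
  (`target<-source`) and composition checks them, which catches most
  pose-chain bugs at call time.  Rotations are stored as 3x3 matrices and
  serialized as unit quaternions (x, y, z, w).
* Depth is **z-depth**: the camera-frame z-coordinate of the surface point,
  not the Euclidean ray length.  This is forced by the back-projection
  `p_c = K^-1 * d * [u, v, 1]^T`, whose third component is exactly `d`.
* The observable depth span is 0.01–25 mm.  Normalized depth maps this span
  linearly to [0, 1] with 0 = far (25 mm) and 1 = near (0.01 mm).  Only the
  endpoints of this map are externally fixed; linearity in metric depth is
  our choice (the simplest consistent one) and the single constant
  conversion is shared by the simulator, the depth network and the
  annotation code so no component can disagree about what a normalized
  value means.
* The world frame is identified with the EM tracker frame.  The camera pose
  is `wTc = emTs · cTs^-1`, where `emTs` is the streamed sensor pose and
  `cTs` the fixed hand-eye transform.  Annotation anchoring composes this
  with back-projection: `[p_w; 1] = wTc · [p_c; 1]`.

## Simulator

The simulator replaces a game-engine scene with a procedural one so that
ground-truth depth is exact and every byte is reproducible from a seed.

* **Geometry.** A curved tube whose centerline is a gentle 3D curve and
  whose wall radius is `mean_radius + amplitude * f(s, theta)`, with `f` a
  seeded band-limited random field (a weight-normalized sum of sinusoids in
  arclength and azimuth, so |f| <= 1 by construction).  Defaults: length
  60 mm, mean radius 4 mm, amplitude 1 mm.  Parameters admitting wall radii
  at or below 1 mm are rejected.  Ring frames are parallel-transported along
  the centerline to avoid twist.
* **Shading.** Uniform light-red albedo (0.85, 0.42, 0.38) — mucosa-like,
  deliberately textureless.  Two point lights ride with the camera at
  ±1 mm lateral offset; irradiance is Lambertian with inverse-square
  fall-off, `albedo * sum_l P_l * max(0, n·l) / r_l^2`, clamped to [0, 1],
  with no shadows or interreflections.  The inverse-square term is the
  monocular depth cue the whole pipeline leans on; near-wall saturation
  from the clamp is a realistic failure mode, not a bug.
* **Rendering.** One primary ray per pixel center; depth is the ray
  parameter with the camera-frame ray scaled to unit z, so depth is exactly
  z-depth.  Misses take the far clamp (25 mm) and black RGB, keeping depth
  maps dense for training.  The ray caster is a vectorized
  ray–triangle intersector with view-cone, distance and interior backface
  culling; analytic plane and sphere scenes bypass the mesh entirely and
  are intersected in closed form, which is what lets renderer tests demand
  1e-6 mm agreement.
* **Trajectories.** Poses follow the centerline at `speed / sample_rate`
  per step with smooth seeded lateral/angular jitter; the stability
  protocol uses a forward–backward oscillation, 50 Hz sampling and speeds
  below 3 mm/s.
* **Datasets.** 8-bit RGB PNGs plus 16-bit greyscale depth PNGs
  (code = round(normalized x 65535); 8 bits would quantize the span to
  0.1 mm steps, too coarse against the 0.01 mm near plane), a pose CSV, an
  intrinsics JSON and a manifest with a config hash.  Generation is a pure
  function of (seed, config).

What the simulator does **not** emulate: vascular surface texture, specular
wet-mucosa reflectance, global illumination, tissue deformation, EM field
distortion.  Green tests therefore demonstrate internal consistency of the
pipeline and learnability of shading-based depth under ideal photometry;
they do not certify accuracy on real patient imagery.

## Calibration and registration

* **Rigid registration** (model landmarks -> EM-probed phantom landmarks)
  minimizes the least-squares correspondence error via SVD of the centered
  cross-covariance, with the standard det<0 sign correction so the result
  is always a proper rotation.  Six non-coplanar landmarks are the default
  fixture size.  Collinear configurations are rejected by a singular-value
  test.
* **Hand–eye calibration** solves AX = XB from relative motion pairs with
  the Tsai–Lenz two-step method (rotation from the modified-Rodrigues
  axis relations, then a linear solve for translation).  Relative motions
  rather than absolute poses are used because the absolute formulation
  needs a world anchor the tracked system does not define.  Fewer than two
  pairs, or pairs with parallel rotation axes, raise an unobservability
  error rather than returning garbage.
* **EM sensor model.** A simulated sensor with seeded Gaussian translation
  and rotation noise, latency, and a configurable true hand-eye transform
  (default: 2 mm lateral offset from the optical axis, the mounting
  geometry this system assumes).  Noise is derived deterministically from
  (seed, sample time) so streams are replayable.

## Networks

No deep-learning framework is a dependency: both networks run on a small
reverse-mode autodiff engine written on numpy (im2col convolutions,
transposed convolutions, instance norm, the usual activations, Adam).  At
the desk scale used here (64 x 64 inputs, tens of channels) this trains in
minutes on one CPU, and it keeps the package's only heavy dependencies
numerical rather than infrastructural.

* **Depth estimator.** A U-shaped encoder–decoder: conv stem, three
  stride-2 stages, bottleneck, then nearest-upsample + conv decoder blocks
  with skip concatenation at equal spatial size; sigmoid head in [0, 1].
  Width, depth and input size are configuration (`paper_scale()` expresses
  a 640 x 480, 64-channel variant).  Loss:
  `lambda * mean|pred - gt| + (1 - SSIM(pred, gt)) / 2` with lambda = 0.1.
  An optional image-gradient term exists but defaults off.  Desk training:
  Adam, lr 1e-3 (the full-scale recipe uses 1e-4; a from-scratch tiny net
  wants the larger step), batch 4, 10 epochs over 250 frames.
  A `pretrained_encoder` hook exists for initializing from an external
  checkpoint; by default training starts from random weights.
* **Style transfer.** Standard two-translator unpaired setup: G maps the
  real domain toward the synthetic domain, F maps back; least-squares
  adversarial losses from PatchGAN discriminators plus an L1
  cycle-consistency term weighted lambda = 10.  Generators are
  downsample (2 stride-2 convs) / residual blocks / upsample (2
  fractionally-strided convs), sigmoid output in [0, 1].  "Stride 1/2" is
  implemented as true transposed convolution.  No identity-mapping loss
  term is used.  The least-squares adversarial objective is our reading of
  an underspecified choice; it is the better-conditioned of the two common
  options at tiny batch sizes.  Desk defaults: 64 x 64, 12 base channels,
  2 residual blocks, 2-layer discriminators, 5 epochs, batch 1, Adam
  lr 2e-4 with betas (0.5, 0.999).

## Evaluation protocols

* **Accuracy.** Frame-paired NRMSE and SSIM on normalized maps.
  NRMSE = RMS error / (ground-truth max - min); the ground-truth range is
  used for normalization because prediction-range normalization would
  reward degenerate flat predictions.  SSIM uses the 11 x 11 Gaussian
  window (sigma 1.5), population local moments and constants
  C1 = (0.01 L)^2, C2 = (0.03 L)^2 on data range 1, averaged over the
  fully-windowed interior; it is checked against scikit-image's
  implementation to 1e-6 in the tests, and metrics are computed on
  normalized rather than metric maps so the SSIM constants are scale-free.
* **Stability.** A marker is placed at a known wall point; the camera
  oscillates forward–backward below 3 mm/s at 50 Hz.  Per sample the
  *reference depth* is the target's z in the true camera frame and the
  *predicted depth* is the depth source's value at the target's projected
  pixel (projection uses the sensor-derived pose, so pose noise propagates
  exactly as it would live).  The trace's MAE summarizes consistency;
  frames where the target leaves the view are excluded with a warning.
  "Distance to the target" is deliberately z-depth for consistency with
  the back-projection convention; the Euclidean camera–target distance is
  logged alongside for comparison.  The oracle depth source answers
  queries by casting the exact sub-pixel ray, so protocol self-tests can
  demand MAE at numerical-noise level and a deliberately injected 1 mm
  bias must be recovered exactly.
* **Multi-trial aggregation** is MAE per trial, then mean ± SD across
  trials.

## Scaled-down closed loops

Two end-to-end experiments (in `endo3d.experiments`) exercise learning at
sizes chosen to finish in minutes on one CPU:

* **Depth closed loop:** 300 simulator frames at 64 x 64, 50 held out, 10
  training epochs; reports held-out mean SSIM and NRMSE.
* **Style-transfer loop:** two unpaired domains that differ by a fixed RGB
  channel permutation (a known, invertible domain gap), 40 images each,
  5 epochs; reports the reduction in per-channel histogram distance of
  G(x) to the target domain and the cycle reconstruction MAE.  The
  permutation gap makes convergence measurable without human judgement.

`scripts/acceptance.py` re-runs all protocols from scratch with a single
seed and writes the measured numbers as JSON.

## Numerical notes and edge cases

* Annotation depth lookup uses nearest-pixel sampling: bilinear
  interpolation across a depth discontinuity would fabricate a phantom 3D
  point between two surfaces.
* Rotation matrices are re-orthonormalized (SVD projection) when
  composition drift exceeds 1e-9, so arbitrarily long pose chains stay in
  SO(3).
* Lens distortion is Brown–Conrady (k1, k2, k3, p1, p2) — the de facto
  endoscope-calibration model; undistortion resamples through the forward
  map, and the point-level inverse uses fixed-point iteration (20 rounds).
* The SVD registration's collinearity guard and the hand-eye parallel-axis
  guard both use explicit rank checks rather than relying on lstsq noise.
* Depth PNG quantization is 1/65535 in normalized units (~3.8e-4 mm);
  tests that read depth from disk budget for exactly this step.
* Training determinism: all weight init, shuffling and noise flow from the
  configuration seed; inference is pure numpy and bit-deterministic.

## Known limitations

* The simulator's photometric realism is limited (no texture, no specular
  term, no photometric camera calibration); transfer to real endoscopes is
  out of scope of the tests.
* Per-frame depth prediction has no temporal coupling, so real deployments
  see frame-to-frame flicker; the stability protocol exists precisely to
  quantify that.
* The desk-scale networks are small; the configuration can express
  full-scale variants, but their training budgets are outside this
  package's test envelope.
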