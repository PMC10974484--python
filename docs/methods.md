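# Methods

## Geometry and coordinate conventions

The camera is modelled as an ideal pinhole with intrinsics
`(f_x, f_y, c_x, c_y)` and a level mount: camera axes are x right, y down,
z forward along the optical axis, and every "horizontal" quantity below is
taken in the camera x–z plane. Lens distortion and extrinsic calibration
are out of scope; landmarks and depth are assumed registered to the same
pixel grid by the acquisition stack. Pixels are 0-based `(i=row,
j=column)`; normalized landmark coordinates are denormalized by
`j = round(u·W)`, `i = round(v·H)` (half-up), clamped so `u = 1.0` maps to
the last valid column.

Depth rasters store millimeters in 16-bit PGM (`depth_scale = 0.001`).
A raster value of 0 marks sensor dropout; `lookup_depth` fills it with the
median of positive values in a 5×5 window (configurable), returning
MISSING only when the whole window is invalid. Single-pixel dropout is
endemic to structured-light sensors, and a small median recovers joint
depth without bleeding across silhouette edges. Back-projection requires
`z > 0`; forward projection is its exact algebraic inverse, with stored
depth `round(z / depth_scale)`. Under 16-bit millimeter quantization and
integer-pixel rasterization the round-trip positional error stays below
1 cm for z ≤ 5 m at the reference intrinsics (f = 500 px, 640×480), which
bounds the geometric noise floor of every parameter.

## Skeleton assembly

Exactly 33 joints per frame is a constructor-enforced invariant. A joint
is MISSING when its landmark visibility falls below `min_visibility`
(default 0.5, the midpoint of the score range) or its depth cannot be
recovered. One skeleton per frame is assumed; the stream reader rejects
records without exactly 33 landmarks. Landmark and depth frames are paired
by nearest timestamp within half a frame period; unmatched frames are
dropped with a warning rather than interpolated.

Temporal smoothing is a per-joint, per-coordinate running median (default
window 5 frames ≈ 0.17 s at 30 fps) — robust to the single-frame depth
spikes this sensor class produces, and short enough not to lag the
clinical motions of interest (trunk tilt changes at ≲ 30°/s during a
sit-to-stand). MISSING runs are bridged by linear interpolation only when
the surrounding samples are ≤ 0.5 s apart; longer occlusions stay MISSING
so downstream series show gaps instead of fabricated data. With window 1
no median is applied (identity on gap-free input).

## Parameters

All angles use `arccos` of the normalized dot product with the cosine
clamped to [−1, 1]; vectors shorter than 1 µm raise a degenerate-geometry
error (series functions emit MISSING instead of raising per frame).
Design choices where the underlying definitions were open:

- **Trunk swing** is the inclination of the shoulder-to-shoulder segment
  with respect to the camera horizontal plane, 0° = level. This reading of
  "inclination of the shoulders" is well-defined for any camera-facing or
  oblique pose.
- **Heel separation** uses lateral (x) distance and **stride** uses depth
  (z) distance, mirroring a frontal capture; `ground_plane=True` switches
  heel separation to the full x–z distance for oblique captures.
- **Speed** uses the 3D displacement of the hip midpoint over sliding 1-s
  windows (per-frame emission); for level gait the difference from
  ground-plane displacement is below the depth noise. On sampled data the
  window start is the frame nearest `t − 1 s` and must match within half a
  frame period, else the sample is MISSING.
- **Hand separation** is the 3D wrist distance (the lateral-only variant
  would hide fore-aft arm swing, which is the clinically interesting
  signal during gait).
- **Stride peaks**: local maxima of the median-smoothed ankle
  depth-difference with prominence ≥ 0.05 m and ≥ 0.3 s separation. The
  prominence floor sits well above the smoothed depth-noise amplitude
  (≈ 1 cm) and below the shortest clinically meaningful step (≈ 10 cm);
  0.3 s caps detection at ~3.3 steps/s, faster than elderly gait.
- **Sit↔stand transitions** are crossings of the mean trunk tilt through
  140°, midway between the seated (≈ 120°) and standing (> 160°) regimes;
  arm support is flagged when either shoulder–elbow–wrist angle dips below
  100° within ±1 s of a transition. Arm bends far from any transition
  (e.g. comfortably seated) are deliberately ignored.

The test catalog (which parameters feed which item of Tinetti, Berg, DGI,
TUG, FRT, FSST, SLS — 42 items in total) ships as versioned YAML so
clinicians can amend the mapping without code changes; two-way ambiguous
cells in the source mapping are flagged `per table, unverified` in file
comments. Item evaluation never aborts on a single failing parameter: each
failure is recorded per series in the report.

## Synthetic rig

The simulator emulates the laboratory captures the parameters were
designed around: a single subject facing a tripod-mounted RGB-D camera,
performing standing balance, forced sway, sit-to-stand (with or without
arm push-off) and straight/curved walks. Default study conditions, chosen
once: reference intrinsics f_x = f_y = 500 px, 640×480, millimeter depth;
stature 1.70 m, shoulder width 0.40 m, hip width 0.30 m; camera 0.8 m
above the floor (a tripod height that keeps the whole body in frame over
the working range); stationary scenarios at 3 m depth; walks from 4.5 m
toward the camera at `cadence × step_length / 2` m/s (the default 0.45 m ×
1.5 steps/s walk covers 2.7 m in 8 s, within the sensor's < 5 m range);
rendering noise of 0.01 m depth s.d. and 1 px landmark jitter.

Kinematics are deterministic closed forms: sway rotates the upper body
about the hip midpoint in the frontal plane (so the scripted roll *is* the
true trunk swing); walking alternates the ankles fore-aft by half a step
length at the scripted cadence (the ankle depth gap peaks exactly at the
step length) with opposing arm swing and a 2 cm lateral hip sway; the
sit-to-stand interpolates hip/knee placement and the sagittal
shoulder–hip–knee angle from 120° seated to `180° − lean` with a
smoothstep over the middle third of the duration, the elbow interior angle
dipping to the scripted push-off angle at mid-transition. Because the
shoulders sit laterally wider than the hips, the true 3D shoulder–hip–knee
angle is slightly below the scripted sagittal profile; ground-truth angle
series are therefore evaluated geometrically on the true poses (never on
rendered output), while the sagittal construction is unit-tested against
the scripted profile directly.

Rendering projects each true joint through the forward camera model and
rasterizes a depth disc of radius 4 px (nearer joints win on overlap),
giving the 5×5 dropout fill real support; body surfaces are not rendered
because every parameter depends only on joint-pixel depth. Arms hang
slightly lateral of the torso so that wrist and hip discs never overlap at
different depths. All randomness derives from the script's single seed via
per-frame child generators, so equal scripts render bit-identical streams
regardless of evaluation order.

### What the simulator does and does not show

Passing the full-loop suites demonstrates that the geometry, filtering and
detectors invert the acquisition model faithfully under quantization and
sensor-like noise. The rig does not emulate pose-estimator failure modes
(landmark swaps, depth bleeding at silhouette edges, multi-person scenes),
soft-tissue artifacts, or non-level camera mounts — real-world accuracy is
bounded below by the upstream pose model, not by this pipeline.

## Verification problem sizes

Unit and acceptance suites run scenarios of 8–10 s at 30 fps (240–300
frames), the natural length of one test item; geometric property checks
use 1000 random points over 0.3–5 m. Full-loop recovery at default noise
holds to ≤ 2° mean absolute error for angle series, ≤ 3 cm for distances
and detected stride lengths, and ≤ 0.05 m/s for speed, across all five
scenario kinds.

## Known limitations

- The pipeline consumes landmarks; it does not run a pose network, so its
  output quality is conditional on the upstream estimator.
- Frontal-capture assumptions (heel separation lateral, stride in depth)
  degrade gracefully but are not corrected for strongly oblique viewpoints.
- Clinical scoring (0/1/2 points per item) is intentionally out of scope:
  the reports are evidence for a therapist, not automated scores.
- The item→parameter catalog is a design mapping awaiting empirical
  clinical validation; it is shipped as data for exactly that reason.
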