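# Methods

This note documents the models, procedures and numerical choices in
`airwayseg`, the assumptions behind them, and what the synthetic
phantom experiments do and do not demonstrate.

## The segmentation model

The backbone is a 3D U-Net operating on single-channel intensity
patches. Each resolution level applies two 3×3×3 convolutions, each
followed by ReLU; levels are connected by 2×2×2 max-pooling on the way
down and learned 2×2×2 up-convolutions (stride 2, channel-halving) on
the way up; feature channels double per level from
`n_features_first`; encoder maps are concatenated onto the decoder at
equal resolution; a final 1×1×1 convolution + sigmoid produces a
voxelwise airway probability. There is no dropout and no batch
normalization: both would store extra activation maps, and the design
goal is the smallest memory footprint that still supports large
patches.

**Hybrid padding.** The first `n_valid_levels` levels (default 3 of 5)
use valid convolutions — each 3×3×3 convolution trims one voxel from
every face of the feature map — while the deeper levels zero-pad.
Valid convolutions at high resolution are where the memory savings
are; zero-padding at depth prevents the output from collapsing. The
valid levels are applied symmetrically in encoder *and* decoder, which
makes every skip-connection crop margin an exact integer and the
output a centered crop of the input. The choice of a symmetric
decoder (the alternative — valid encoder, padded decoder — would make
margins asymmetric) and of max-pooling / transposed-convolution
operators are design decisions; both are configurable.

**Shape admissibility.** Because sizes shrink and must divide by the
pool factor at every level, only certain input sizes flow through the
network. `compute_shape_table` propagates sizes symbolically and is
the single authority: an input is admissible iff every pre-pool size
divides by the pool factor, every skip margin splits evenly, and no
intermediate size collapses. For the reference configuration
(5 levels / 3 valid / 16 features) input 252³ is admissible and yields
output 196³, i.e. a 28-voxel margin per face. The realized forward
pass is tested to match the table exactly across configurations.

**Implementation.** The network, its hand-derived backward pass and
Adam live in `airwayseg.nn` / `airwayseg.unet` as a compact NumPy
stack. Convolutions are evaluated as one small GEMM per kernel tap on
contiguous shifted input slices, which at these narrow channel counts
is markedly faster than im2col expansion on a CPU; gradients were
verified against finite differences. Weight initialization is
Kaiming fan-in scaling from a seeded generator (`init_seed`), so runs
are bit-reproducible on one platform.

## Training protocol

The loss is the soft Dice restricted to the lung ROI `N_L`,
`1 − 2Σpg/(Σp+Σg+ε)` with all sums over ROI voxels and `ε = 1e-6`
defining the empty-ROI/empty-truth limit. Voxels outside the ROI
provably contribute neither value nor gradient (tested). Because
valid convolutions make the output smaller than the input patch, the
truth and ROI are compared on the centered crop matching the output
footprint — the only alignment consistent with the shape algebra.

Preprocessing crops each scan to the ROI bounding box expanded by 30
voxels (clamped at the volume), masks the truth to the ROI (removing
trachea and part of the main bronchi), clips intensities to
[−1000, 500] HU-like units and rescales to [0, 1]. Volumes smaller
than the patch are symmetrically zero-padded.

Per epoch, 8 random patches per training scan are drawn with corners
uniform over the valid corner range, then augmented: per-axis flips
(probability 0.5 each), per-axis rotations uniform in ±10°, isotropic
scaling uniform in (0.75, 1.25), composed into a single affine
resampling (linear for the image with constant air fill,
nearest-neighbour for labels and ROI so they stay binary). Rotation
angles are independent per-axis Euler angles and the scale factor is a
single isotropic draw; both conventions are pinned choices where a
range of readings is possible.

Optimization is Adam at learning rate 1e-4 with batches of one patch.
The train/validation split is deterministic: sample IDs sorted, seeded
shuffle, a `val_fraction` (default 0.2) tail held out. Validation
loss is computed each epoch on patches whose corners are drawn once
from a dedicated seeded stream and then frozen — deterministic
validation patches give a stable convergence signal, where re-drawing
each epoch would add noise to the stopping rule. The stopping rule
monitors the moving average of the validation loss over
`ma_window_epochs` (reference: 50): stop when, relative to its value
`stop_patience_epochs` (reference: 20) earlier, it has risen more than
5% or failed to fall more than 0.1%; never before window + patience
epochs exist. The returned model is the snapshot at the overall
minimum validation loss.

All randomness fans out from one seed into named substreams (split,
validation patches, epoch sampling/augmentation), so a fixed seed
reproduces the entire history.

## Inference and post-processing

Full volumes are tiled by a sliding-window plan: per axis, window
corners advance at stride `floor(patch·(1−overlap))` (default overlap
0.5) with a final corner clamped to `volume − patch`. Each window's
output is placed at the centered sub-window given by the network
margin, accumulated, and divided voxelwise by the per-voxel window
count. The input is reflect-padded by the network margin before
planning so that every original voxel falls inside some output
footprint; with that padding the aggregation is exactly a mean, so any
overlap ≥ the margin fraction yields the same map up to float
tolerance (tested at 1e-5). A patch larger than the volume triggers
symmetric reflect-padding to patch size, cropped back afterwards.

The binary tree is extracted by: masking the probability map to the
lung fields; thresholding (≥ 0.5 default; ≥ 0.1 in EXACT mode, which
compensates for the stricter 6-connectivity requirement); merging the
central-airway mask in full (the lung mask excludes the trachea, so
coherence is enforced by the final step rather than by re-masking);
and keeping the largest connected component at 26- (default) or
6-connectivity. Ties between equal-size components prefer the
component containing a central-mask voxel, then the lowest
lexicographic corner — a deterministic rule.

Two simplified intensity-based segmenters provide the auxiliary masks
when no reference masks are supplied: the lung fields by
air-thresholding, discarding components that touch a lateral border or
are tiny, morphological closing and hole-filling; the trachea + main
bronchi by 26-connected region growing from the most superior dark,
roughly circular cross-section, with a volume-explosion guard that
lowers the threshold and regrows. Both are deliberately simple
stand-ins for the dedicated region-growing methods used in clinical
pipelines, and are validated only on phantoms.

## Evaluation metrics

With `P` the prediction, `G` the truth, centerlines by 3D
medial-axis thinning (Lee et al.) unless an exact centerline is given:

- TL = 100·|{x ∈ G_centerline : P(x)=1}| / |G_centerline|
- CL = 100·|{x ∈ P_centerline : G(x)=0}| / |G_centerline|
- FPR = 100·|P \ G| / |G| (unclamped; can exceed 100%)
- DSC = 2|P∩G| / (|P|+|G|), defined 1 when both empty
- total length = detected centerline voxels × geometric mean voxel size

"Inside the prediction" is literal mask membership, with no tolerance
radius. The trachea/main-bronchi mask, dilated by one voxel so that
skeleton voxels sitting exactly on its boundary do not leak into the
counts, is removed from `P`, `G` and centerlines before counting; the
predicted centerline is computed after this removal. All five
measures are tested for exact agreement with brute-force per-voxel
loop oracles.

## The phantom generator

Phantoms emulate the image structures the method relies on: a full
binary tree of capsules (cylinders with spherical caps — rasterized by
a per-voxel distance-to-axis test, which keeps bifurcations gap-free)
whose radii and lengths decay geometrically per generation
(defaults: root radius 4 voxels, ratio 0.75; root length 22% of the
volume, ratio 0.7; bifurcation half-angle 35°, jittered); a dark lumen
(−1000) inside a brighter wall (−200); dark noisy parenchyma (−850,
Gaussian σ 25) inside lung fields built from two covering ellipsoids
with the root capsule carved out (so the ROI excludes the trachea
analogue and part of the main bronchi, exactly as the training
masking assumes); brighter soft tissue (0) outside the lungs; and a
few bright vessel-like tubes (+50) disjoint from the airways.
Intensities are abstract HU-like values reproducing the qualitative
CT contrast, not calibrated units. The lung mask is synthetic
geometry rather than an intensity segmentation, so the ROI ground
truth is exact and independent of the lung-segmentation stub; the
centerline comes from the generative skeleton, giving an exact
reference against which skeletonization itself can be tested.

What the phantoms do **not** model: anatomical airway trees and lobar
geometry, respiratory motion, scanner physics (beam hardening, dose,
reconstruction kernels), partial-volume blur at sub-voxel walls, and
pathology. Passing the phantom experiments therefore demonstrates
that the pipeline's machinery — shape bookkeeping, loss masking,
sampling, stitching, post-processing, metrics — is correct and that
the network can learn tubular contrast at realistic noise levels; it
does not certify clinical-grade accuracy on real CT.

## The desk-scale recovery experiment

The reference validation (`airwayseg.experiments`) trains a reduced
backbone — 3 levels, 1 valid level, 4 first-level channels, 44³
patches (output 36³) — on a cohort of 64³ four-generation phantoms
with the standard protocol, holding out the 20% validation phantoms,
then segments the held-out phantoms and scores them. Convergence
windows are scaled to the short schedules (moving-average window 8,
patience 5, an epoch budget of 30); the windows must span several
epochs of validation noise — shorter ones were observed to stop
training on transient plateaus midway down the loss curve. The
24-phantom cohort keeps the full experiment near ten minutes on one
CPU. On this
task the trained model reaches high completeness (median TL well above
80%), bounded leakage and Dice around or above 0.8 on held-out
phantoms; `scripts/acceptance.py` recomputes these numbers from
scratch for any seed.

## Known limitations

- The NumPy backbone is single-threaded BLAS-bound; it is meant for
  desk-scale experiments and correctness, not production training on
  clinical CT volumes.
- The connected airway tree is not guaranteed by the voxelwise model;
  disconnected peripheral branches are discarded by the
  largest-component step, reducing completeness.
- The lung and trachea segmenters are threshold heuristics validated
  on phantoms only; real scans should supply externally computed
  masks.
- Dice on thin tubes is dominated by one-voxel boundary bands; small
  phantom trees make DSC a stricter measure than it is on clinical
  airway references.
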