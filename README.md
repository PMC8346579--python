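# airwayseg

Automatic **airway-tree segmentation from thoracic CT** with a simple,
low-memory 3D U-Net — plus a synthetic branching-tube phantom generator
so the entire pipeline (training, inference, post-processing,
evaluation) can be exercised end-to-end on a laptop CPU with no
external data.

The package is aimed at researchers in pulmonary image analysis who
want a transparent, fully reproducible reference implementation of the
large-patch U-Net approach to airway extraction: a backbone small
enough to process patches covering most of a lung in one pass,
sliding-window inference with overlap averaging, and the
centerline-based completeness/leakage measures standard in the airway
literature.

## Method

**Backbone.** A 3D U-Net (two 3×3×3 convolutions + ReLU per resolution
level, 2×2×2 max-pooling / learned up-convolution, channel
doubling/halving, skip connections, final 1×1×1 convolution + sigmoid)
with *hybrid padding*: the first `n_valid_levels` resolution levels use
valid (non-padded) convolutions, which trim the outermost feature-map
voxels and cut the memory footprint, while deeper levels zero-pad. The
reference configuration is 5 levels, 16 first-level channels, 3 valid
levels, input 252³ (output 196³). No dropout or batch normalization.
A symbolic shape table (`compute_shape_table`) decides which input
sizes are admissible and predicts every intermediate size exactly.
The network, its backward pass and the Adam optimizer are implemented
as a compact NumPy layer stack (`airwayseg.nn`), so the package has no
deep-learning-framework dependency.

**Training.** The loss is the soft Dice restricted to the lung
region of interest `N_L`:

```
L = 1 − 2 Σ_{x∈N_L} p(x) g(x) / ( Σ_{x∈N_L} p(x) + Σ_{x∈N_L} g(x) + ε )
```

with `p` the predicted probability map and `g` the ground-truth lumen
mask; masking the truth to the lungs removes the trachea and part of
the main bronchi so optimization focuses on the smaller branches.
Scans are cropped to the lung bounding box + 30 voxels; 8 random
252³ patches per scan per epoch are drawn with corners uniform over
the valid range, augmented by random flips, ≤10° 3D rotations and
isotropic scaling in (0.75, 1.25) (nearest-neighbour for labels);
optimization is Adam at 1e-4 with batches of one patch; training stops
when the 50-epoch moving average of the validation loss rises >5% or
fails to fall >0.1% across 20 epochs, and the minimum-validation-loss
snapshot is kept.

**Airway extraction.** Sliding-window tiling at 50% overlap,
count-normalized averaging of the (smaller, centered) output patches,
masking to the lung fields, thresholding at 0.5, merging with a
region-grown trachea/main-bronchi mask, and keeping the largest
26-connected component (EXACT mode: threshold 0.1, 6-connectivity).

**Evaluation.** Tree length detected (TL), centerline leakage (CL),
false positive rate (FPR), Dice (DSC) and total tree length, computed
on skeletonized centerlines with the trachea and main bronchi excluded
from predictions and truth.

## Worked example

```python
import airwayseg as A

# one synthetic phantom: image + exact lumen/centerline/lung/root masks
ph = A.generate_phantom(A.PhantomConfig(seed=1))

# perfect-prediction sanity check: evaluate the ground truth against itself
res = A.evaluate(A.EvalInputs(ph.lumen_mask, ph.lumen_mask,
                              ph.centerline_mask, ph.root_mask))
print(res)
```

prints

```
EvalResult(tree_length_pct=100.0, centerline_leakage_pct=0.0,
           false_positive_rate_pct=0.0, dice=1.0, total_tree_length_mm=100.0)
```

i.e. a prediction identical to the truth detects 100% of the
centerline, leaks nothing, has no false positives, Dice 1, and the
detected centerline (after removing the trachea and main bronchi) is
100 mm long at 1 mm isotropic spacing. The same
chain with a *trained* model (see `airwayseg.experiments`) replaces the
first argument with the network's post-processed output.

The same pipeline is available from the shell:

```bash
airwayseg generate --config config.yaml --n 24 --out data/ --seed 0
airwayseg train    --config config.yaml --data data/ --out run/
airwayseg predict  --model run/model.npz --image data/phantom_000_image.nii.gz \
                   --lungs data/phantom_000_lungs.nii.gz \
                   --central data/phantom_000_root.nii.gz --out tree.nii.gz
airwayseg evaluate --pred tree.nii.gz --truth data/phantom_000_lumen.nii.gz \
                   --central data/phantom_000_root.nii.gz --out metrics.csv
```

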