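# autocascade

Auto-context cascade of orthogonal-plane 2D networks for segmenting a
single connected bright structure — the bony labyrinth of the inner ear —
in 3D micro-CT volumes, together with a synthetic phantom generator, an
eight-metric evaluation suite and a cross-validation / comparison harness.

## The problem

The inner ear (cochlear scalae, semicircular canals, vestibule) must be
delineated in temporal-bone micro-CT for applications from cochlear-implant
planning to anatomical modelling.  Slice-wise 2D segmentation networks are
data-efficient on such volumes but fail in a characteristic way: the
temporal bone contains pneumatized *air cells* whose 2D cross-sections are
indistinguishable from inner-ear lumina.  Telling them apart needs 3D
context — the labyrinth is one connected structure; air cells are
disconnected from it.

## The method

A three-stage cascade injects that 3D prior into 2D networks.  Stage *s*
is a 2D encoder-decoder (U-Net, residual U-Net, or squeeze-and-excitation
U-Net) with X = *s* input channels, applied slice-by-slice along one
anatomical orientation (default order coronal → sagittal → axial):

1. slice the volume along the stage's orientation and predict per-slice
   posteriors p(x) ∈ [0, 1];
2. reassemble the 3D posterior volume, binarize (p > 0.5), and keep the
   **largest 3D connected component** (26-connectivity);
3. feed that mask to the next stage as an extra input channel alongside
   the raw intensities and any earlier stage masks.

The final stage's post-processed mask is the output, so it has at most one
connected component by construction.  Evaluation uses, with X the predicted
and Y the true voxel sets: Dice 2|X∩Y|/(|X|+|Y|), Jaccard |X∩Y|/|X∪Y|,
accuracy, precision |X∩Y|/|X|, recall |X∩Y|/|Y|, specificity, voxelwise
ROC-AUC, and the symmetric 3D Hausdorff distance in mm, plus paired
two-sided Wilcoxon signed-rank tests for model comparison (exact null up to
25 pairs).

Because real micro-CT specimens are large external downloads, the package
ships a parametric phantom generator that reproduces the *structure* of the
problem at desk scale: a connected labyrinth (tapering cochlear helix,
three canal arcs, vestibule) in textured bone, with disconnected
target-intensity confounder blobs, partial-volume blur and noise.  All
training, cascade and metric code is exercised end-to-end on phantoms; see
`docs/methods.md` for what the phantoms do and do not emulate.

## Worked example

Miniature cascade on 32³ phantoms (`examples/03_train_tiny_cascade.py`,
about a minute on one CPU):

```
$ python examples/03_train_tiny_cascade.py
train volume: Dice 0.940, 392 predicted vs 431 true voxels
held-out volume: Dice 0.923, 294 predicted vs 330 true voxels
```

Dice is the voxel overlap 2|X∩Y|/(|X|+|Y|): 0.94 on a training volume and
0.92 on an unseen phantom mean the predicted labyrinth nearly coincides
with the ground truth, with the residual at the blurred tube boundaries.
The other examples generate and inspect a phantom (`01`), compute all eight
metrics on a deliberately degraded mask (`02`), and run the
baseline-vs-cascade comparison (`04`), which on two held-out confounder
phantoms prints:

```
              baseline_mean  cascade_mean
metric
dice                  0.698         0.835
jaccard               0.536         0.717
accuracy              0.997         0.998
precision             0.840         0.807
recall                0.597         0.865
specificity           0.999         0.999
auc                   0.992         0.982
hausdorff_mm          1.528         0.472
```

The auto-context stages recover target voxels the single-orientation
baseline misses (recall 0.87 vs 0.60) and remove stray detections
(Hausdorff 0.47 mm vs 1.53 mm).

A thin CLI wraps the same API:

```bash
autocascade phantom --n 10 --seed 7 --out data/
autocascade train --config run.yaml --data data/ --out model/
autocascade predict --model model/ --in data/sample_000_img.nii.gz --out mask.nii.gz
autocascade evaluate --pred preds/ --gt labels/ --out metrics.csv
autocascade crossval --config run.yaml --data data/ --out results/
autocascade compare --config run.yaml --data data/ --arch unet
```

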