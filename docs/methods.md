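# Methods

## Problem and approach

Segmenting the bony labyrinth (cochlear scalae, semicircular canals,
vestibule) in temporal-bone micro-CT is hard for slice-wise 2D networks for
one structural reason: the temporal bone is riddled with pneumatized air
cells whose cross-sections look exactly like inner-ear lumina.  A 2D model
has no way to tell them apart; a 3D prior does, because the labyrinth is a
single connected structure and the air cells are disconnected from it.

The toolkit implements that prior as a three-stage *auto-context cascade*.
Each stage is a 2D encoder-decoder network applied slice by slice along one
anatomical orientation (default order: coronal, sagittal, axial).  After a
stage, its per-slice posteriors are reassembled into a 3D volume, binarized,
and reduced to the largest 3D connected component; that mask is appended as
an extra input channel for the next stage, which slices along a different
orientation.  Stage *s* therefore consumes X = *s* channels: the raw slice
plus the post-processed masks of all predecessors.  The final stage's
post-processed mask is the system output, so it always has at most one
connected component at the configured connectivity.

## Preprocessing

Volumes are resampled once, up front, to a fixed cubic grid (default 256³;
all pipeline code is size-agnostic) with cubic-spline interpolation; label
masks use nearest-neighbour resampling, because a spline would fabricate
non-binary label values at boundaries.  The output spacing along axis *i*
is `spacing_i × extent_i / size`, so physical extent is preserved and
Hausdorff distances stay in true millimetres (per-volume spacing, since
original sizes differ).

Intensities are zero-centred and scaled by the pooled standard deviation of
the *training* volumes of the current experiment/fold — population standard
deviation, fitted strictly after the split, refitted per fold.  The API
makes leakage structurally impossible: `fit_normalizer` only ever receives
the training list.

Anatomical axis labels (axial/coronal/sagittal → grid axes) are read from
NIfTI orientation metadata when present and otherwise taken from explicit
configuration; they are never guessed from the data.

## Architectures

Three 2D architectures share one U-shaped skeleton: `depth` contracting
steps of [block → 2×2 max-pool] with filters doubling from `base_filters`,
a bottleneck block with dropout (rate 0.2), and a mirrored expanding path of
[2×2 stride-2 transposed convolution → skip concatenation → block], closed
by a 1×1 convolution with sigmoid.  Convolutions are 3×3, zero-padded
"same", each followed by batch normalization and ReLU.

* **unet** — block = two conv-BN-ReLU units.
* **resunet** — the same 3×3 path summed with a parallel 1×1 projection of
  the block input, then ReLU.
* **seunet** — the plain block followed by squeeze-and-excitation channel
  recalibration (global average pool → C/r → ReLU → C → sigmoid gate), with
  one constant reduction ratio r (default 8) at every level.

Defaults are depth 4 and 16 base filters; the unit and benchmark suites use
depth 2 and 8 base filters, which train on a CPU in minutes.

The layers are implemented directly on numpy (im2col + GEMM convolutions,
explicit backward passes, Adam) as a compact, fully deterministic CPU
trainer: all randomness (initialisation, shuffling, dropout) flows from
explicit integer seeds, so retraining with the same configuration is
bit-identical.  Batch-norm uses eps 1e-5 and running-statistic momentum 0.9;
inference always uses running statistics with dropout off.

## Training protocol

Per-voxel binary cross entropy, Adam (default learning rate 1e-4), shuffled
mini-batches of 20 slices, up to 200 epochs.  After every epoch the weights
are checkpointed if the epoch training loss is the lowest seen so far;
training stops early after 20 epochs without improvement (configurable),
and the checkpointed — not final — weights are returned.  The checkpoint
criterion is deliberately the *training* loss, which keeps the full
training set available when specimens are scarce; the caveat is that it
cannot detect overfitting the way a validation-loss criterion would.

Stages train strictly sequentially.  For stage s > 1, the prior channels
are the post-processed *predictions* of the already-trained stages on the
training volumes, not the ground-truth masks: feeding ground truth during
training would present the later stages with a cleaner prior distribution
than they will ever see at inference time.

Cross-validation is specimen-level (every slice of a volume stays in its
volume's fold); fold sizes differ by at most one (17 specimens into 4 folds
gives 5+4+4+4).  The comparison harness trains, on identical data and
budget, a single-orientation baseline (axial by default) of the same
architecture with the same largest-component post-processing, and reports
paired per-volume metrics with two-sided Wilcoxon signed-rank p-values.

## Evaluation metrics

With X the predicted and Y the true foreground voxel sets:
Dice 2|X∩Y|/(|X|+|Y|), Jaccard |X∩Y|/|X∪Y|, accuracy, precision |X∩Y|/|X|,
recall |X∩Y|/|Y|, specificity, voxelwise ROC-AUC, and the symmetric 3D
Hausdorff distance max{sup_x inf_y d(x,y), sup_y inf_x d(x,y)} over the full
foreground sets, with d the Euclidean distance between voxel centres scaled
by the (possibly anisotropic) voxel spacing, reported in mm.

Numerical conventions:

* 0/0 ratio metrics resolve by agreement-on-emptiness (both masks empty →
  1.0, one-sided → 0.0) and are flagged in the report.
* Hausdorff of an empty mask is undefined and reported as missing, never 0.
* AUC uses the final stage's assembled probability volume (thresholded
  masks would make AUC uninformative) and is computed per volume, then
  averaged — never pooled across volumes.
* The Wilcoxon test drops zero differences, midranks ties, and uses the
  exact conditional null distribution (dynamic programme over doubled
  ranks) for up to 25 effective pairs, a tie-corrected normal approximation
  with continuity correction above.

## Binarization and component extraction

Probability maps binarize at threshold 0.5 with a *strict* inequality, so
exact-0.5 ties go to background.  Connected components use 26-connectivity
by default — the most permissive choice, least likely to sever the thin
semicircular canals; 6 and 18 are available.  Equal-size component ties
break by the smallest first-voxel index in grid scan order.  An empty stage
output propagates as an all-zero prior channel with a logged warning rather
than aborting: a total miss at one stage is recoverable by later stages.

## The phantom generator

`phantom` renders image/label pairs that pose the same structural problem
as the real anatomy without requiring any external data:

* **Target** — a helical cochlear tube whose spiral radius tapers linearly
  (default 2.5 turns, apex radius 0.35× base) with a mildly narrowing
  lumen; three partial-torus canal arcs in near-orthogonal, slightly tilted
  planes, each passing through the vestibule; and a vestibule ellipsoid at
  the hub.  Connectivity of the union is guaranteed by construction (the
  cochlea's basal point and every arc midpoint lie at the vestibule centre)
  and re-verified on every sample.
* **Surroundings** — a bone block at lower intensity carrying band-passed
  Gaussian noise as texture.  This is an intensity model only; it makes no
  attempt at anatomical bone structure, because only intensity
  confusability matters for exercising the pipeline.
* **Confounders** — spheres rendered at exactly the target intensity,
  placed by rejection sampling (capped at 1000 attempts per blob, then a
  named error) at least `min_distance` from the target, where
  `min_distance` must exceed the Gaussian blur support so that partial
  volume effects can never merge a confounder into the target component.
* **Degradation** — Gaussian blur (partial-volume emulation, σ 0.7 voxel)
  then additive Gaussian noise (σ 0.05 on a 0–1 intensity scale).

Defaults use a 64³ grid at 0.125 mm spacing; the foreground occupies about
0.7% of the volume, a class imbalance comparable to a small bright
structure in CT.  Datasets jitter the geometric parameters independently by
±10% per sample; every sample is a pure function of (spec, seed), with one
generator per sample and no global random state.

What the phantoms do **not** emulate: scanner-specific noise spectra and
artefacts (rings, beam hardening), true cochlear scala separation, ossicles,
anatomical variability beyond parameter jitter, and multi-scanner intensity
distribution shifts.  Tests passing on phantoms therefore demonstrate the
correctness and the 3D-context behaviour of the pipeline, not clinical-grade
accuracy on real micro-CT.

## Scaled-down benchmark conditions

The end-to-end suites train at desk scale: 64³ phantoms, depth-2 networks
with 8 base filters, mini-batch 20, learning rate 3e-3, five epochs per
stage; six easy phantoms (no confounders, low noise) for the learning check
and eight confounder phantoms split 6/2 for the cascade-vs-baseline
comparison, repeated over three seeds.  These sizes keep a full run on one
CPU within minutes while leaving the task non-trivial (thin canals, class
imbalance, intensity-identical confounders).

## Known limitations

* The CPU trainer is practical up to roughly 10⁵-parameter networks and
  64–128³ volumes; the published problem scale (256³, deeper networks)
  calls for a GPU framework, for which the module boundaries here map
  one-to-one.
* Checkpointing on training loss (see above) follows the protocol but is
  not the field's default.
* The slice-axis mapping assumes axis-aligned acquisitions; oblique
  orientations would need resampling to an axis-aligned grid first.
* The phantom's confounders are spheres; real air-cell clusters are more
  irregular, which likely makes the synthetic confusion problem slightly
  easier than the real one.
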