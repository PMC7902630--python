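"""Compute the eight evaluation metrics for a prediction/ground-truth pair.

A fake 'prediction' is made by eroding the ground truth and adding a stray
blob, so every metric is informative.
"""

import numpy as np
from scipy import ndimage

from autocascade import PhantomSpec, generate_phantom, evaluate_pair
from autocascade.volume_io import LabelVolume, Volume

sample = generate_phantom(PhantomSpec(), seed=3)
gt = sample.label

pred_data = ndimage.binary_erosion(gt.data).astype(np.uint8)
pred_data[2:5, 2:5, 2:5] = 1  # spurious detection far from the target
pred = LabelVolume(pred_data, spacing=gt.spacing)

# a surrogate probability map: blurred prediction
prob = Volume(ndimage.gaussian_filter(pred_data.astype(float), 1.0).clip(0, 1),
              spacing=gt.spacing)

rep = evaluate_pair(pred, gt, prob=prob, spacing=gt.spacing)
for name, value in rep.as_dict().items():
    unit = " mm" if name == "hausdorff_mm" else ""
    print(f"{name:>12}: {value:.4f}{unit}")
# dice/jaccard measure overlap, precision the purity of the prediction,
# recall its completeness; hausdorff_mm is the worst surface disagreement
# in millimetres (driven here by the stray blob).
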