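"""Single-orientation baseline vs the auto-context cascade, miniature scale.

Both arms share the architecture, training budget and post-processing; the
only difference is the cascade's three orthogonal-plane stages feeding each
stage the predecessors' masks as extra channels.
"""

from autocascade import CascadeConfig, TrainConfig, generate_dataset
from autocascade.experiment import compare_frameworks
from autocascade.phantom import PhantomSpec

data = generate_dataset(PhantomSpec(), n=8, seed=21)  # 64³, with confounders

cfg = CascadeConfig.build(arch="unet", depth=2, base_filters=8, input_size=64)
tcfg = TrainConfig(learning_rate=3e-3, batch_size=20, max_epochs=5,
                   early_stop_patience=5, seed=0)
report = compare_frameworks(data[:6], data[6:], "unet", cfg, tcfg)  # ~3 min on a CPU

print(report.table[["baseline_mean", "cascade_mean"]].round(3).to_string())
# Higher dice/jaccard/recall for the cascade reflects confounders and misses
# cleaned up by the auto-context stages; hausdorff_mm (lower is better)
# drops when stray detections vanish.  p_value is None below 5 test volumes.
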