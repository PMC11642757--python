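"""Robustness of the inferred embryo composition to mosaic-call artifacts.

Reassigns 0%, 50% and 90% of the published mosaic biopsy proportion evenly
to the euploid and aneuploid classes, refits the posterior at dispersal 1
(reduced sampler sizes), and prints how the inferred embryo types respond.
"""

import numpy as np

from mosaicabc import ABCConfig, PredictiveConfig, published_targets, run_misclassification_sweep

rng = np.random.default_rng(3)
df = run_misclassification_sweep(
    published_targets()["capalbo"],
    rates=(0.0, 0.5, 0.9),
    dispersals=(1.0,),
    abc_config=ABCConfig(n_particles=600, n_embryos_per_trial=200),
    pred_config=PredictiveConfig(500, 200),
    rng=rng,
)
cols = ["misclassification_rate", "meiotic_mean", "mitotic_mean",
        "fully_euploid", "mosaic_embryo", "fully_aneuploid"]
print(df[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print("\nAs more mosaic calls are treated as artifacts, the fitted mitotic")
print("rate shrinks and more embryos are inferred fully euploid; the mosaic")
print("embryo class declines but remains the norm at moderate rates.")
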