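"""Fit the (meiotic, mitotic) error-rate posterior to published PGT-A data.

Runs a reduced-size adaptive PMC ABC fit (600 particles, 200 embryos per
trial) to the published biopsy-class proportions at dispersal 1 and prints
the weighted posterior means with 95% credible intervals.  The full-scale
setting (2000 particles, 1000 embryos per trial) is ABCConfig's default.
"""

import numpy as np

from mosaicabc import ABCConfig, ModelConfig, posterior_summary, published_targets, run_abc

rng = np.random.default_rng(1)
target = published_targets()["capalbo"]
posterior = run_abc(
    target,
    ModelConfig(dispersal=1.0),
    ABCConfig(n_particles=600, n_embryos_per_trial=200),
    rng,
)

print(f"target: {target.label} {np.round(target.as_array(), 3)}")
print(f"stopped after {posterior.n_iterations} iterations; "
      f"final tolerance {posterior.tolerance_history[-1]:.4f}")
print(posterior_summary(posterior).to_string(float_format=lambda x: f"{x:.4f}"))
print("\nmeiotic: probability an embryo starts fully aneuploid (per meiosis);")
print("mitotic: probability a euploid daughter cell turns aneuploid (per mitosis).")
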