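"""Simulate a trial of mosaic embryos and classify their biopsies.

Builds 10,000 blastocyst-stage embryos (256 cells) at a 58% meiotic and
1.5% mitotic error rate with fully dispersed aneuploid cells, takes one
5-cell biopsy per embryo, and prints the class proportions next to the
published clinical proportions they approximate.
"""

import numpy as np

from mosaicabc import ErrorRates, ModelConfig, published_targets, simulate_biopsy_proportions

rng = np.random.default_rng(0)
theta = ErrorRates(meiotic=0.58, mitotic=0.015)
config = ModelConfig(dispersal=1.0)

stats = simulate_biopsy_proportions(theta, config, n_embryos=10_000, rng=rng)
target = published_targets()["capalbo"]

print(f"simulated biopsy classes at theta=({theta.meiotic}, {theta.mitotic}):")
print(f"  euploid {stats.prop_euploid:.3f}  mosaic {stats.prop_mosaic:.3f}"
      f"  aneuploid {stats.prop_aneuploid:.3f}")
print("published clinical proportions (6,766 biopsies):")
print(f"  euploid {target.prop_euploid:.3f}  mosaic {target.prop_mosaic:.3f}"
      f"  aneuploid {target.prop_aneuploid:.3f}")
print("\nEach biopsy samples 5 adjacent cells of 256; classes use the")
print("20%/70% aneuploid-cell thresholds. Differences from the published")
print("triple at this theta are what the ABC fit resolves.")
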