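"""Generate a two-domain phantom benchmark and inspect the style shift.

Domain A plays the labeled source scanner, domain B the unlabeled target
scanner: identical anatomy (nested endo/epi ellipses in a sector cone),
different grayscale style (gamma, speckle shape, texture scale).
"""

import numpy as np

from macs import io as mio
from macs.experiments import source_config, target_config
from macs.phantom import generate_dataset

source = generate_dataset(source_config(n_images=8, seed=11))
target = generate_dataset(target_config(n_images=8, seed=11))

mio.save_dataset(source, "phantoms/domain_a", seed=11)
mio.save_dataset(target, "phantoms/domain_b", seed=11)

mean_a = np.mean([s.image[s.image > 0].mean() for s in source])
mean_b = np.mean([s.image[s.image > 0].mean() for s in target])
area_a = np.mean([s.endo_mask.sum() for s in source])
area_b = np.mean([s.endo_mask.sum() for s in target])

print(f"mean in-cone intensity: domain A {mean_a:.3f}, domain B {mean_b:.3f}")
print(f"mean endo area (px):    domain A {area_a:.1f},  domain B {area_b:.1f}")
print("-> same seed gives identical anatomy (areas match exactly) while the")
print("   gamma-0.5 target domain is systematically brighter: a pure style")
print("   shift, the controlled analogue of a cross-vendor domain gap.")
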