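"""Half-set reconstruction, FSC resolution, and mask-corrected curves.

Splits a simulated data set into gold-standard halves, reconstructs each
half independently, and reports the FSC=0.143 resolution.  Also shows the
soft-mask correction by high-resolution noise substitution: the masked FSC
is corrected for the correlation the mask itself induces.
"""

import numpy as np

from cryofocus.benchmark import make_benchmark_data
from cryofocus.projection import reconstruct
from cryofocus.validation import (
    compute_fsc,
    fsc_noise_substitution,
    resolution_at,
    split_half_sets,
)

data = make_benchmark_data(seed=5, n_per_class=400, box=32)
sim = data["sim"]

halves = split_half_sets(len(sim.particles), seed=5)
vols = []
for h in (1, 2):
    idx = np.flatnonzero(halves == h)
    vols.append(
        reconstruct(
            sim.particles.subset(idx),
            sim.images.data[idx],
            pixel_size=sim.images.pixel_size,
        )
    )

plain = compute_fsc(vols[0], vols[1])
res, crossed = resolution_at(plain, 0.143)
print(f"unmasked FSC=0.143 resolution: {res:.2f} A" + ("" if crossed else " (Nyquist)"))

corrected = fsc_noise_substitution(vols[0], vols[1], data["mask"])
res_m, crossed_m = resolution_at(corrected, 0.143)
print(f"mask-corrected resolution:     {res_m:.2f} A" + ("" if crossed_m else " (Nyquist)"))
# The corrected curve reports the resolution inside the focus region without
# the artificial correlation a tight mask adds.
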