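"""Generate random initial-pressure phantoms.

Builds a handful of geometric absorber scenes plus one vessel-like
phantom, prints their occupancy statistics and writes PNG previews.
A value of 1.0 is full absorbance; the background is 0.
"""

import numpy as np

from sparsepat import io as spio
from sparsepat.phantoms import generate_scene, generate_vessel_scene

rng = np.random.default_rng(0)

for i in range(3):
    scene = generate_scene(rng)
    frac = np.count_nonzero(scene) / scene.size
    print(f"scene {i}: occupied {frac:6.1%} of the grid, peak {scene.max():.3f}")
    spio.save_png(f"scene_{i}.png", scene)

vessels = generate_vessel_scene(rng)
print(f"vessels: occupied {np.count_nonzero(vessels)/vessels.size:6.1%},"
      f" intensities {vessels[vessels > 0].min():.2f}-{vessels.max():.2f}")
spio.save_png("scene_vessels.png", vessels)
# The occupancy numbers show sparse scenes (a few percent of pixels) as in
# small-animal photoacoustic slices; vessel curves are 1-3 px thin.
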