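"""Background-subtracted nuclear intensities and positive-cell counts.

Generates a synthetic brain image with 16 disk-shaped nuclei (the canonical
count for the Pdf+ ventral lateral neurons, 8 per hemisphere) over a noisy
background, measures each nucleus through its ground-truth mask, and counts
marker-positive cells.
"""

import numpy as np

from flyclock.imagequant import count_positive_cells, measure_nuclei, per_brain_mean
from flyclock.simulate import simulate_nucleus_image

implanted = np.linspace(80, 180, 16)
image, masks = simulate_nucleus_image(
    n_nuclei=16, intensities=implanted, background_level=25.0, noise_sd=4.0, seed=6
)

measurements = measure_nuclei(image, masks, brain_id="brain1")
(brain,) = per_brain_mean(measurements)
(counts,) = count_positive_cells(measurements, threshold=25.0)

worst = max(
    abs(m.net_intensity - (implanted[m.cell_id - 1] - 25.0)) for m in measurements
)
print(f"nuclei measured: {brain.n_cells}")
print(f"GFP+ nuclei above threshold: {counts.n_cells}")
print(f"mean net intensity per brain: {brain.mean_net_intensity:.1f}")
print(f"worst deviation from implanted net intensity: {worst:.2f}")
# all 16 nuclei are recovered and each background-subtracted mean sits within
# sampling error of its implanted value.
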