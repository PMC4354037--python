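"""Image pipeline: render a movie, detect clusters, extract corrected traces.

Renders per-flow image stacks for a small simulated run (Gaussian PSFs plus
read noise), detects cluster centres on the averaged image with the
difference-of-Gaussians detector, selects per-spot background pixels, and
checks the background-corrected traces against the simulated ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

from kinflow import imaging as im
from kinflow import simulate as sim

run = sim.make_monotemplate_run(
    seed=31, n_clusters=16, n_flows=8,
    noise=sim.NoiseParams(read_noise_sigma=3.0),
)
layout = sim.SpotLayout.grid(16)
stacks = sim.render_movie(run, layout, seed=32)
print(f"rendered {len(stacks)} stacks of {stacks[0].shape[0]} frames, "
      f"{stacks[0].shape[1]}x{stacks[0].shape[2]} px")

avg = np.mean([im.average_image(s) for s in stacks], axis=0)
spots = im.build_spot_map(avg)
dist, idx = cKDTree(layout.centers).query(spots.centers.astype(float))
print(f"detected {len(spots)}/16 clusters, max centre offset {dist.max():.1f} px")
print(f"background pixels per spot: {sorted({len(b) for b in spots.background_pixels})}")

corrs = []
for f in range(len(stacks)):
    traces = im.extract_all_traces(stacks[f], spots)
    for j, c in enumerate(idx):
        truth = run.traces[c, f] - run.noise.background
        if np.ptp(truth) > 5:
            corrs.append(np.corrcoef(traces[j], truth)[0, 1])
print(f"corrected-trace correlation with simulated truth: "
      f"median {np.median(corrs):.4f}, min {np.min(corrs):.4f}")
print("-> the DoG + Otsu-background chain recovers per-cluster kinetics from")
print("   raw movies; these traces feed the base caller unchanged.")
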