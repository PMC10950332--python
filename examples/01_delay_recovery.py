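"""Simulate one two-colour maturation movie and recover its peak-to-peak delays.

Ten cisternae are rendered with programmed red-minus-green peak delays drawn
from N(31, 24.1^2) seconds, imaged at 5 s intervals, then pushed through the
full detect -> track -> trace -> summarize chain. The printed per-cisterna
deltas are the pipeline's estimates (multiples of the 5 s frame interval);
the summary line is the statistic a two-colour experiment reports: mean +- SD
peak-to-peak duration over n cisternae.
"""

import numpy as np

import cistrack as ct

config, scene = ct.maturation_scene(mean_delta=31.0, sd_delta=24.1, n_cisternae=10, seed=42)
stack, truth = ct.generate_movie(config, scene)
print(f"movie: {stack.shape} (t, c, z, y, x), {config.frame_interval} s frames")

spots = ct.detect_spots_movie(
    stack, config.voxel_size,
    psf_sigma_xy=config.psf_sigma_xy, psf_sigma_z=config.psf_sigma_z,
)
tracks = ct.link_tracks(spots)
print(f"{len(spots)} spots linked into {len(tracks)} tracks")

summary, traces, pairs, log = ct.summarize_maturation(
    tracks, stack, config.voxel_size, config.frame_interval
)
print("\nestimated deltas (s):", np.sort(summary.deltas_s))
print("true deltas      (s):", np.sort(truth.cisternae["delta_true_s"]).round(1))
print(
    f"\npeak-to-peak duration: {summary.mean_delta_s:.1f} +- {summary.sd_delta_s:.1f} s "
    f"(n = {summary.n} cisternae); programmed mean was 31.0 s"
)

start, end = ct.residency_interval(summary.grid_s, summary.mean_curves[:, 0], 0.2)
print(f"green-marker residency (20% of peak): {start:.0f} to {end:.0f} s around time 0")
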