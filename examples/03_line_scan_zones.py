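"""Line-scan profile through a cisterna with segregated marker sub-zones.

A single maturing cisterna is rendered with its green and red marker zones
displaced 0.3 um apart (strongest at the transition midpoint). A line scan
through the cisterna center shows two laterally shifted peaks; the
segregation metrics quantify the displacement in micrometres.
"""

import cistrack as ct

config, scene = ct.maturation_scene(
    mean_delta=30.0, sd_delta=0.1, n_cisternae=1, seed=21, zone_offset_um=0.3
)
stack, truth = ct.generate_movie(config, scene)
cis = scene[0]

mid_t = 0.5 * (cis.kinetics[0].peak_time + cis.kinetics[1].peak_time)
f = int(round(mid_t / config.frame_interval))
z = int(round(cis.trajectory[f, 0] / config.voxel_z))
y, x = cis.trajectory[f, 1], cis.trajectory[f, 2]
ext_x = (config.nx - 1) * config.voxel_xy

profile = ct.profile_along_line(
    stack[f, :, z], (y, max(x - 0.7, 0.0)), (y, min(x + 0.7, ext_x)), config.voxel_xy
)
peak_off, centroid_off = ct.segregation_metrics(profile)
print(f"line scan at t = {f * config.frame_interval:.0f} s (transition midpoint)")
print(f"peak offset:     {peak_off:.2f} um")
print(f"centroid offset: {centroid_off:.2f} um")
print("programmed zone separation was 0.30 um; offsets near it indicate the")
print("green and red markers occupy spatially segregated sub-zones")
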