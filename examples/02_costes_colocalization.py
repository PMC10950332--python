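"""Costes-thresholded Pearson colocalization on ground-truthed phantoms.

Two-channel 3D phantoms share a known fraction rho of their spots. Pearson r
over the whole volume rises with rho; the Costes scan finds the paired
intensity thresholds at which the sub-threshold voxels decorrelate, and the
Welch test compares r between a high- and a low-overlap group of phantoms
(the comparison made between drug-treated and control cells).
"""

import numpy as np

import cistrack as ct

config = ct.preset_config("maturation", n_frames=1, nx=96, ny=96)

print("rho_target   mean Pearson r (5 phantoms)")
groups = {}
for rho in (0.1, 0.5, 0.9):
    rs = [
        ct.pearson_r(*ct.generate_coloc_phantom(config, rho, 100, seed=s)[0])
        for s in range(5)
    ]
    groups[rho] = rs
    print(f"   {rho:.1f}       {np.mean(rs):+.3f}")

stack, _ = ct.generate_coloc_phantom(config, 0.8, 100, seed=1)
res = ct.costes_threshold(stack[0], stack[1])
print(
    f"\nCostes on a rho=0.8 phantom: thresholds A={res.threshold_a:.0f}, "
    f"B={res.threshold_b:.0f} counts (camera offset {config.camera_offset:.0f}); "
    f"r_all={res.r_all:.3f}, r_above={res.r_above:.3f}, r_below={res.r_below:+.4f}"
)
print("(r_below <= 0 at the stop: the excluded voxels are uncorrelated background)")

cmp = ct.welch_t_test(groups[0.9], groups[0.1])
print(
    f"\nWelch test, rho 0.9 vs 0.1 groups: t={cmp.t:.2f}, df={cmp.df:.1f}, p={cmp.p:.2e}"
)
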