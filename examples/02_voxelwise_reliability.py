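"""Voxel-wise ICC maps on simulated volumes with known ground truth.

Generates 80 subjects x 2 occasions of 8x8x8 volumes where every voxel has
between-subject variance 3 and within-subject variance 2 (true ICC(3,1) =
3/5 = 0.6), then estimates the five reliability maps and summarizes them.
"""

from relimap import SimulationSpec, masked_median, simulate_dataset, voxelwise_icc

bundle = simulate_dataset(
    SimulationSpec(n_subjects=80, grid_dims=(8, 8, 8),
                   sigma2_between=3.0, sigma2_within=2.0, seed=7)
)
maps = voxelwise_icc(bundle.volume_set, bundle.brain_mask, icc_type="icc_3")

print(f"true voxel-wise ICC(3,1): {bundle.true_icc3[0, 0, 0]:.2f}")
for name, arr in maps.maps().items():
    print(f"masked median {name}: {masked_median(arr, bundle.brain_mask):.3f}")

# The median estimate sits near 0.6 with BS near 3 and WS near 2; the lower /
# upper maps are the per-voxel 95% F-based confidence bounds. With only 80
# subjects the bounds are wide -- single-voxel ICCs are noisy estimates.
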