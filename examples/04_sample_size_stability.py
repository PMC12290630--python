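"""How many subjects until the median ICC stabilizes?

Simulates 150 subjects with true ICC(3,1) = 0.6, then bootstraps subsamples
(with replacement, paired across occasions) on a grid of sample sizes. The
95% interval of the median ICC across iterations shrinks as n grows.
"""

from relimap import SimulationSpec, StabilityGrid, simulate_dataset, subsample_stability

bundle = simulate_dataset(
    SimulationSpec(n_subjects=150, grid_dims=(6, 6, 6),
                   sigma2_between=3.0, sigma2_within=2.0, seed=11)
)
curve = subsample_stability(
    bundle.volume_set, bundle.brain_mask, icc_type="icc_3",
    grid=StabilityGrid(n_values=(25, 50, 100, 150), n_iterations=50, seed=1),
)

print(curve.summary[["n", "median_icc_mean", "median_icc_lower",
                     "median_icc_upper"]].to_string(index=False))
width = curve.summary["median_icc_upper"] - curve.summary["median_icc_lower"]
print("interval widths:", [f"{w:.3f}" for w in width])

# The mean of the bootstrap medians stays near the true 0.6 at every n, while
# the interval narrows with n -- the practical reading is the smallest n at
# which the interval is tight enough for the question at hand.
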