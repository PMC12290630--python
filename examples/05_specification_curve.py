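"""Specification curve over the analytic-decision multiverse.

Enumerates the 240-pipeline grid (5 smoothing x 4 motion x 3 model x 4
contrast options), fabricates three samples of median-ICC records with
option-dependent effects, and builds the ordered curve with significance
classes and the decision-panel matrix.
"""

import numpy as np
import pandas as pd

from relimap import build_specification_curve, enumerate_pipelines

pipelines = enumerate_pipelines()
print(f"restricted grid: {len(pipelines)} pipelines; "
      f"full motion grid: {len(enumerate_pipelines(full_motion_grid=True))}")

# synthetic effects: implicit-baseline contrasts and larger kernels help
rng = np.random.default_rng(0)
rows = []
for sample in ("sampleA", "sampleB", "sampleC"):
    for p in pipelines:
        base = 0.15
        base += 0.10 if p.contrast.endswith("Base") else 0.0
        base += 0.02 * ("1.5x 2x 2.5x 3x 3.5x".split().index(p.fwhm))
        rows.append({"sample_id": sample, "fwhm": p.fwhm, "motion": p.motion,
                     "model": p.model, "contrast": p.contrast,
                     "statistic": "median_icc",
                     "value": base + rng.normal(0, 0.03)})
curve = build_specification_curve(pd.DataFrame(rows), null_value=0.0)

print(curve.table["significance_class"].value_counts().to_string())
print("lowest pipeline: ", curve.table.iloc[0][["fwhm", "contrast", "estimate"]].tolist())
print("highest pipeline:", curve.table.iloc[-1][["fwhm", "contrast", "estimate"]].tolist())

# Pipelines are ordered by their across-sample mean; the class is gray when
# the 95% t-interval across samples spans 0, blue when wholly above it. The
# panel (curve.panel) is the option-indicator matrix used for the lower panel
# of a specification-curve figure.
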