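"""Along-tract FA profiles: resampling and pointwise group comparison.

Streamlines are arc-length resampled to 100 equidistant nodes; profiles
are compared node-by-node with a one-way ANOVA across the three severity
groups (FDR across nodes, Bonferroni post hoc), reporting contiguous
significant node ranges per contrast.
"""

import numpy as np
import pandas as pd

import wmhtract as wt
from wmhtract.profiles import pointwise_anova

# resampling: a linear FA gradient along a curved streamline
t = np.linspace(0, np.pi, 80)
points = np.column_stack([40 * t / np.pi, 10 * np.sin(t), np.zeros_like(t)])
seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
fa = 0.3 + 0.4 * np.concatenate([[0], np.cumsum(seg)]) / seg.sum()
profile = wt.resample_streamline(points, fa)
print(f"resampled profile: {len(profile)} nodes, "
      f"FA {profile[0]:.2f} -> {profile[-1]:.2f} (linear in arc length)")

# pointwise comparison on generated cohort profiles (severe group carries
# a +0.1 FA offset on nodes 20-40 of the affected tracts)
cfg = wt.SimulationConfig(seed=5)
labels = pd.Series(["sWMH"] * 25 + ["mWMH"] * 30 + ["HC"] * 30,
                   index=[f"S{i:03d}" for i in range(85)])
profs, truth = wt.make_profiles(cfg, labels, tracts=("LTR",))
res = pointwise_anova(profs[profs["tract"] == "LTR"], group_col="subgroup")
print(f"planted effect window: nodes "
      f"{truth.profile_effect_nodes[0]}-{truth.profile_effect_nodes[1]}")
for contrast, ranges in res.ranges.items():
    if ranges:
        print(f"significant nodes {contrast[0]} vs {contrast[1]}: {ranges}")
# the detected ranges should bracket the planted window for the two
# contrasts involving the severe group, and be empty for mWMH vs HC
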