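"""Project lesion probability maps onto the tract atlas.

Lesion maps are thresholded at probability 0.8 and overlaid on each
tract's probability map; the probability-weighted sum over the mask is
the tract-specific hyperintensity volume (mL), normalized by the
tract's total probability mass to a load ratio (%).
"""

import pandas as pd

import wmhtract as wt

cfg = wt.SimulationConfig(seed=1, n_patients=20, n_controls=12,
                          grid_shape=(24, 24, 24))
atlas = wt.make_atlas(cfg)
lesions, truth = wt.make_lesions(cfg, atlas)

masks = {s: wt.binarize_lesion(v, threshold=0.8) for s, v in lesions.items()}
loads = wt.cohort_tract_loads(masks, atlas)

cohort = pd.DataFrame({"subject": sorted(masks)})
cohort["group"] = cohort["subject"].str.startswith("P").map({True: "mTBI",
                                                             False: "HC"})
tests = wt.compare_tract_loads(loads, cohort).sort_values("p_fdr")
print("top tracts by group difference (patient vs control mean load, mL):")
print(tests.head(8)[["tract", "mean_HC", "mean_mTBI", "t", "p_fdr"]]
      .round(4).to_string(index=False))
print("\nthe planted six tracts (thalamic radiation, cingulum cingulate,")
print("corpus callosum) carry the largest mean loads; on this compact grid")
print("lesion blobs also spill into neighbouring tracts, so those show")
print("smaller but real group differences too.")

freq = wt.cohort_probability_map([masks[s] for s in masks if s.startswith("P")])
print(f"\npatient lesion-frequency map: peak voxel frequency "
      f"{freq.values.max():.2f}")
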