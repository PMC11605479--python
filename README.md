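# wmhtract

Tract-specific white-matter-hyperintensity (WMH) burden, dynamic
functional-connectivity states, and their association with cognition —
as a tested, reusable analysis pipeline for mild-TBI-style cohorts.

## The problem

White-matter hyperintensities are the imaging signature of
cerebrovascular injury. Averaged whole-brain WMH volume ignores *where*
lesions fall; lesion load projected onto individual fiber tracts is far
more informative about which connections are disrupted and which
cognitive functions suffer. This package implements the full analysis
chain a tract-specific WMH study needs:

1. **Lesion → tract projection.** A lesion probability map is binarized
   at probability ≥ 0.8 and overlaid on a 20-tract probabilistic atlas.
   The tract-specific WMH volume is the probability-weighted sum

   `V_t = v · Σ_{x ∈ mask} P_t(x)` (reported in mL, `v` = voxel volume),

   and the load ratio normalizes by the tract's total probability mass:
   `L_t = 100 · Σ_{x ∈ mask} P_t(x) / Σ_x P_t(x)` (%).
2. **Severity subgrouping.** Per tract, load is regressed on age, sex
   and education within healthy controls; a subject's z-score is their
   residual in control-SD units. Patients with z > 1.5 on ≥ 2 of the six
   burden-prone tracts (bilateral thalamic radiation, bilateral cingulum
   cingulate, anterior/posterior corpus callosum) form the severe (sWMH)
   subgroup, the rest the mild (mWMH) subgroup.
3. **Tract profiles.** Streamlines are arc-length resampled to 100
   equidistant nodes; node-wise FA is compared across the three groups
   (one-way ANOVA per node, BH-FDR across nodes, Bonferroni post hoc)
   with contiguous significant node ranges per contrast.
4. **Dynamic connectivity states.** ROI time series are scrubbed
   (FD > 1 mm), cut into 50-TR sliding windows (step 1 TR), and each
   window's Fisher-z correlation vector is pooled across subjects.
   k-means over k = 2..6 with silhouette / Calinski–Harabasz /
   Davies–Bouldin selection identifies recurring states; run-length
   encoding of the label stream yields mean dwell time, fractional
   occupancy, and transition counts per subject.
5. **Association models.** Gaussian linear models
   `outcome ~ predictor + age + sex + education` over three families
   (loads→cognition, loads→dynamics, dynamics→cognition) with BH-FDR
   within each family.

Because such patient data are not publicly shareable, the package ships
a first-class synthetic-cohort generator (`wmhtract.synth`) that
emulates every input — tubular tract atlas, lesion fields concentrated
in the six affected tracts, two-state Markov-switching ROI series whose
integrated-state persistence grows with left-thalamic-radiation load,
and a cohort table whose processing-speed score (TMT-A) is linearly
coupled to that load at 65.6 s/mL — while recording the exact ground
truth for every quantity downstream stages estimate.

## Worked example

`examples/05_dynamic_states.py` generates a 20-subject cohort (50 ROIs,
180 volumes at TR 2.5 s), computes 131 sliding windows per subject, and
runs the state analysis:

```
20 subjects x 131 windows (180 volumes, 50-TR window, step 1)

cluster validity by candidate k:
 k  silhouette  calinski_harabasz  davies_bouldin   inertia
 2       0.238            924.959           1.598 73706.279
 3       0.119            595.168           2.470 68562.009
 4       0.082            440.399           2.928 66275.277
 5       0.082            362.698           2.836 64154.565
 6       0.076            309.285           3.051 62671.280

chosen number of states: 2 (silhouette); CH picks 2, DB picks 2

per-subject temporal metrics (first rows):
subject  occupancy_1  occupancy_2  dwell_windows_2  transitions
   P001        68.70        31.30            41.00            1
   P002        58.02        41.98            27.50            2
```

All three validity indices recover the two planted covariance regimes
(the segregated state and the hub-coupled integrated state). Occupancies
sum to 100% per subject; dwell times are mean consecutive-window run
lengths (also reported in seconds).

`examples/06_associations.py` fits the covariate-adjusted association on
an 85-patient cohort:

```
TMT-A on LTR load: slope 69.2 s/mL (95% CI 20.4-118.0), beta 0.31, p 0.006
planted slope: 65.6 s/mL (inside the CI)
```

The other examples walk through lesion projection, severity subgrouping,
tract-profile statistics, and the end-to-end pipeline; each prints the
numbers it computes and what they mean.

## Command line

A thin CLI wraps the library for shell use:

```bash
wmhtract simulate --seed 1 --n-patients 20 --n-controls 12 --out data/
wmhtract lesion-load --lesions data/lesions --atlas data/atlas/atlas.nii.gz \
    --threshold 0.8 --out results/tract_loads.tsv
wmhtract subgroup --loads results/tract_loads.tsv --cohort data/cohort.tsv \
    --z 1.5 --min-tracts 2 --out results/subgroups.tsv
wmhtract dfc --series data/series --window 50 --step 1 --k-range 2 6 \
    --seed 1 --out results/
wmhtract run --config run.yaml       # full pipeline from a YAML config
wmhtract report --results results/ --out report/report.md
```

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 statistical
degeneracy.

## Layout

```
src/wmhtract/      library (synth, lesion, grouping, profiles, dfc,
                   stats, io, pipeline, cli)
examples/          one short narrative script per capability
tests/             pytest suite incl. the acceptance checks
scripts/           acceptance.py
docs/methods.md    model, parameters, and design notes
```
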