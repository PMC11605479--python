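# Methods

This note documents the models, conventions and numerical choices behind
`wmhtract`, and what the synthetic cohorts do and do not emulate.

## Lesion-to-tract projection

A lesion probability map (per-voxel probability of hyperintensity) is
binarized at a threshold of 0.8; the comparison is **inclusive**
(voxel ≥ 0.8 is lesioned) and configurable. For each tract `t` of a
probabilistic atlas sharing the lesion grid, the WMH volume is the sum
of the *tract's* voxel-wise probabilities within the lesion mask, scaled
by voxel volume to millilitres (mL = cm³; voxel volume is derived from
the affine's spatial column norms). The load ratio divides that
probability-weighted sum by the tract's total probability mass over the
whole grid, so full coverage gives exactly 100%. The alternative reading
— summing the *lesion* probabilities within the mask restricted to the
tract support — is available via `weight="lesion"` but off by default,
since only the tract-probability reading is consistent with the
normalization by tract mass. Subjects are assumed already in atlas
space; grid or affine mismatches (beyond 1e-4 on affine entries) are
errors, never silently resampled.

Properties the implementation guarantees (and the tests verify by
brute-force voxel loops): additivity over disjoint masks, monotonicity
under mask growth, and scale equivariance (doubling voxel volume doubles
mL and leaves ratios unchanged).

## Severity subgrouping

For each of the six burden-prone tracts, load (the normalized ratio by
default; raw volumes via config) is regressed on age, sex (binary
indicator) and education **within healthy controls**; every subject's
z-score is (observed − predicted) / SD of control residuals, with the
residual SD using the regression denominator n − p − 1. Patients
exceeding z > 1.5 (strict, configurable) on at least two tracts are
labeled sWMH, the rest mWMH; controls stay HC. Assignment is monotone in
the threshold and invariant to subject/tract order.

## Tract profiles

Each streamline is parameterized by cumulative chord length and its
scalar linearly interpolated at 100 equidistant arc-length fractions;
the tract profile is the unweighted cross-streamline mean per node
(distance-weighted aggregation is deliberately out of scope). Node 1
anchors at a declared start waypoint when given; otherwise endpoint
order is fixed lexicographically so profiles are orientation-stable.
Pointwise statistics: one-way ANOVA per node, BH-FDR across the 100
nodes (the multiple-comparison scheme is not uniquely dictated by
common practice; FDR matches the package's convention elsewhere, and a
cluster-permutation alternative would be a drop-in replacement), then
pairwise pooled-t post hoc tests Bonferroni-corrected by the number of
group pairs at nodes surviving the omnibus, reported as contiguous
significant node ranges per contrast. Under the global null the
family-wise rate of reported ranges sits at the nominal 5% (verified by
simulation).

## Dynamic connectivity states

Frames with framewise displacement strictly above 1 mm are flagged
invalid; subjects whose invalid fraction exceeds a configurable limit
are flagged for exclusion. Windows are rectangular (no taper), length 50
TRs, step 1 TR; window t covers frames [t, t+49]; the count is
T − W + 1 (131 windows for 180 volumes). Correlations within a window
use its valid frames only; windows under 80% valid frames are marked
invalid and become gaps downstream. Pearson r is clamped to
±(1 − 1e−7) and Fisher-z transformed before clustering (configurable
off); zero-variance pairs get r = 0.

k-means (squared Euclidean, multiple seeded restarts) runs on the pooled
valid window vectors for each candidate k in 2..6. Silhouette
(maximize), Calinski–Harabasz (maximize) and Davies–Bouldin (minimize)
are recorded per k; the chosen k follows the silhouette by default.
Pairwise distances for the silhouette are computed once and reused
across candidates; pools above a cap (default 6000 windows) are
subsampled with the run's seed. States are relabeled in descending
pooled occurrence (ties by centroid norm), so labels are deterministic
and label 1 is always the most frequent state.

Temporal metrics come from run-length encoding of each subject's window
label stream. A scrubbed (gap) window **breaks a run and does not count
as a transition** — the chain's continuity across a gap is unknowable,
so bridging it would fabricate dwell time. Mean dwell time is the mean
run length per state, in windows and in seconds (run length × step ×
TR, with TR taken from the data, never a constant). Fractional occupancy
is the percentage of valid windows per state (sums to 100 per subject);
transitions count adjacent label changes within gap-free segments, and
the empirical k×k transition matrix (row-normalized counts) is emitted
alongside the raw count, since "number of transitions" and "transition
probability" are both in circulation. Never-visited states get occupancy
0 and dwell *missing*, not 0.

## Statistical layer

Two-sample comparisons default to Welch's t (pooled available);
categorical variables use the Pearson chi-square without continuity
correction (Yates optional) — on a 40/45 vs 30/22 sex split this
convention gives p = 0.227. Three-level comparisons use one-way ANOVA
with pairwise pooled-t post hoc tests Bonferroni-corrected by the number
of pairs. "Generalized linear regression" is implemented as the
Gaussian identity-link linear model: per-unit slope, t-based 95% CI, and
a standardized coefficient equal to slope × sd(x)/sd(y) (which reduces
to Pearson r without covariates). Multiplicity control is
Benjamini–Hochberg, applied within each of the three association
families separately; association models run on patients only. Missing
rows are dropped listwise with the count reported. Shapiro–Wilk
normality screening is a reported diagnostic only; no automatic
nonparametric fallback is applied.

## The synthetic cohort generator

The generator defines the study conditions all seeded experiments run
under. Defaults: 85 patients / 52 controls; 32³ voxel grid at 2 mm; 50
ROIs (227 supported); 180 volumes at TR 2.5 s; window length 50 TRs;
two latent states.

**Atlas.** Twenty tubular supports (Gaussian radial falloff, σ = 4 mm,
peak 1 on the axis): nine mirrored bilateral pairs plus two central
callosal segments. Grids under 12 voxels per dimension are rejected.

**Lesions.** One Gaussian blob per affected tract per subject, centered
on a cohort-fixed point of the tract axis; blob radius = 8 mm × subject
severity × per-tract jitter (U(0.8, 1.2)). Severity draws are
U(0.4, 1.2) for patients and U(0.3, 1.0) for controls — overlapping
deliberately, so subgrouping is nontrivial — and the first patient is
planted at the severity maximum with maximal jitter, making the
"severe patient exceeds every control" ordering constructive. Peak blob
probability is 0.95 per group (configurable; 0 gives empty lesions).
Ground-truth loads are recorded by direct voxel summation at generation
time. These choices put patient/control left-thalamic-radiation loads
near 0.2–0.45 / 0.1–0.2 mL and cohort marginals (TMT-A means,
standardized β ≈ 0.35–0.5, sWMH fraction ≈ 40%) in the range a real
mild-TBI cohort shows.

**Time series.** A first-order Markov chain over the latent states is
sampled per TR from its stationary initial distribution. State 1 is the
segregated regime (uniform off-diagonal r = 0.1); state 2 the integrated
regime — five ROI blocks with within-block r = 0.6, one hub ("DMN")
block coupled to all others at r = 0.4, background r = 0.1. That
requested matrix is not positive definite; it is repaired by eigenvalue
clipping (floor 1e−3) and diagonal renormalization, which leaves the
realized correlations at ≈ 0.61 / 0.39 / 0.10 (a `strict` flag raises
instead). States beyond 2 are alternative integrated regimes with a
globally synchronized rotating hub block, keeping regimes mutually
well-separated. The baseline stay probability is 0.96 per TR; state-2
persistence is linear in stay-log-odds with slope 2.0 per mL of
left-thalamic-radiation load, clipped to (0.5, 0.99) — the simplest
monotone link. These two values were fixed once, jointly, so that at
default sizes (i) all three validity indices select k = 2 across seeds,
(ii) window-label recovery is reliable, and (iii) the load→occupancy
link is identifiable within 180 volumes; the clip ceiling bounds the
expected occupancy contrast, so group differences in occupancy at 180
volumes are real but modest. FD traces are sub-millimetre noise with a
configurable fraction (default 2%) of planted spikes above 1 mm.

**Ground-truth window labels.** A window's planted state is defined only
when a single latent state occupies at least 80% of its frames
(mirroring the 80%-valid-frame window rule); windows straddling a
transition have no ground-truth state and are excluded from recovery
scoring. With plain majority labels instead, recovery ARI is bounded
near 0.85 at these window/series lengths — not an estimation failure
but a property of blend windows, whose k-means assignment boundary
cannot coincide with a 50% majority cut (Fisher-z path curvature and
centroid pull shift it).

**Cognition table.** TMT-A = 38 + 65.6 s/mL × LTR load + age/education
effects + N(0, 45²); DSC, FDS, BDS and VF carry signed load slopes in
the patients-worse direction with score-scale noise; age/sex/education
margins approximate a mild-TBI cohort (patients younger-educated,
~47% female). Cytokine columns (IL-1β, IL-6, TNF-α elevated most) scale
log-normally with total affected-tract burden. Setting noise to 0 and
covariate effects to 0 makes the planted slopes exactly recoverable.

**What the generator does not emulate:** raw k-space/DWI/BOLD images,
tractography, hemodynamic convolution, spatial autocorrelation of BOLD
noise, scanner drift, or registration error. Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under
known ground truth — not robustness to acquisition artifacts.

## Numerical conventions and degenerate inputs

- All randomness flows from one seed through named child streams
  (CRC-32 of the stream name spawns the child), so identical configs are
  bit-identical and subject counts do not perturb unrelated draws.
- Voxel indices are 0-based; world coordinates via the affine; volumes
  are written RAS+ as float32 NIfTI.
- Ties in k selection go to the smaller k; state relabeling ties break
  by centroid norm.
- Degenerate cases raise typed errors rather than returning NaN:
  zero control residual variance (tolerance 1e−10 relative to scale),
  collinear designs, constant variables, all-identical window vectors,
  all-gap label streams, zero-mass atlas entries.

## Study sizes used by the test and acceptance runs

State-count and recovery checks use 20-subject cohorts (12 patients /
8 controls, 50 ROIs, 180 volumes) over ten seeds; slope-recovery uses
200 replicates at the full 85-patient size on a 16³ grid; calibration
checks use 500 null profile simulations and 100 null association
cohorts. These sizes keep every property estimable with tight
Monte-Carlo error while the whole suite stays fast on a single CPU.

## Known limitations

- The silhouette's preference between k = 2 and k = 3 on three-regime
  cohorts is marginal at the default covariance separation (k-means at
  the planted k recovers the windows essentially perfectly; the model-
  order *selection* is the fragile part). The tests assert the
  selection on a majority of seeds and the recovery on every seed.
- The stay-probability clip at 0.99 bounds the expected state-2
  occupancy contrast between severity subgroups; at 180 volumes the
  occupancy Monte-Carlo noise is of comparable size, so subgroup
  occupancy tests on single cohorts are direction-consistent but not
  highly powered.
- Tract tubes and lesion blobs are geometric idealizations; load ratios
  are comparable across seeds only in distribution, not voxel-for-voxel.
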