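# Methods

This note documents the models, conventions and numerical choices behind
`pedoperm`, in the order data flows through the package.

## Sensor model and units

Recordings are stacks of frames from a regular grid of pressure sensors.
Defaults mirror a capacitive walkway plate: 5 mm sensor pitch (25 mm² per
sensor), 100 Hz sampling, pressures in kPa with a 10 kPa detection
threshold. Values below the threshold are stored as exactly 0 at
construction/read time, so "activated sensor" has a single meaning
everywhere downstream (contact area, averaged pressure, COP weights, the
coverage rule of the cluster tests). The total force of a frame is
Σ pressure × sensor area (10 kPa on one sensor = 0.25 N). Weight
normalization divides by body weight mass × g with g = 9.8 m/s²; force
series are additionally expressed as BW% (×100). The frame-stack file
format is plain text (key/value header + one numeric matrix per frame)
with `%.17g` floats, so serialization is exactly invertible and writing is
byte-deterministic.

Grid convention: row index along the walking progression axis, column
index mediolateral, 0-based. For a right foot the positive column
direction is the lateral side; left feet mirror this, and the foot angle
(angle of the heel→second-toe line against the progression axis) is
sign-flipped for left feet so external rotation is positive bilaterally.

## Stance segmentation

Footprints are separated spatially by 8-connected component analysis of
the time-collapsed activation map; the original protocol identifies stance
regions manually from the visualized images, so an automatic surrogate is
required and spatial separation is the property the two-step midgait
layout guarantees (consecutive heel contacts are a step length apart).
Onset/offset per footprint are the first/last frames with any active
sensor in its region. Stances whose total-force curve is not triphasic are
flagged (`TriphasicError`) and excluded from peak-anchored analyses only.

## Foot standardization

Each stance is mapped to a standard foot grid by a similarity transform
anchored at the manually identified landmarks: rotation about L1 (most
posterior heel point) aligning L1→L2 (tip of the second toe) with the
progression axis, then uniform scaling so |L1L2| = 100 A.U. Pressures (not
per-sensor forces) are resampled by bilinear interpolation, zero outside
the source support, identically for all frames of the stance. The standard
grid is 120 rows × 60 columns at 1 A.U. spacing with L1 at row 10,
mid-column; the 10-row posterior and 10-row distal margins absorb the heel
boundary and toes extending past L2. The grid resolution is a package
choice (the A.U. construction itself fixes only the landmark distance);
`StandardGrid.with_shape` builds coarser grids covering the same extent
for fast simulation studies. Typical adult feet give ≈ 2.3 mm per A.U., so
the standard grid oversamples the 5 mm sensor grid and the regridded total
force (Σ pressure × A.U.-cell area) matches the sensor-grid total well
inside the 2% conservation check used in the tests. Left feet can be
mirrored about the progression axis for pooled analyses; by default sides
are analyzed separately.

## Gait, pressure and temporal parameters

Step length is the progression-axis distance between the two feet's L1
landmarks (the operational "heel contact position"); step duration the
onset-to-onset time; cadence = 60/duration; speed = length/duration.
Contact area counts sensors active in *any* frame of the stance
(area × 0.25 cm²); the per-frame area series is also provided. Peak
pressure is the maximum over sensors and frames; maximum force the peak of
the total-force series.

M-peak detection: the two highest local maxima of the lightly smoothed
(moving average, window 3) force curve that are at least 10% of contact
time apart bracket the valley; Peak 2 is the raw minimum between them,
Peaks 1/3 the raw maxima on either side. Smoothing is used only to
localize extrema — reported values come from the raw series. Intervals 1–4
partition contact time at the three peaks (ms, and % of contact time; the
proportions sum to 100 exactly by construction). Transient-phase indices
are inter-peak midpoints, rounding half toward the earlier frame
(deterministic tie-break).

Time normalization maps frames onset..offset to [0, 1] and resamples each
series (total force BW%, averaged pressure over active sensors, contact
area, COP x/y) to 50 points (100 as a robustness variant) with a natural
cubic spline; force/pressure/area are clipped at 0 to remove spline
undershoot at contact boundaries. COP is the pressure-weighted mean of the
sensor coordinates; frames with no activation inside the stance get COP
linearly interpolated from neighbors and are counted.

## Scalar statistics

Group comparisons use the Welch t statistic with Welch–Satterthwaite
degrees of freedom — the appropriate default for the 68-vs-24 unbalanced
design this package is built around — while Cohen's d uses the pooled SD,
the standard effect-size convention. Both are computed from (n, mean, SD)
summaries; the raw-sample path reduces to summaries first, so the two
agree exactly. No multiple-comparison correction is applied to parameter
tables (exploratory convention; flags at .05/.01). Parameters measured per
foot are averaged across feet before testing. Covariate adjustment fits
OLS of a parameter on sex (male = 0, female = 1), age, BMI, cadence, foot
angle and walking speed, with VIF = 1/(1−R²_j) from auxiliary regressions;
BMI is the sole anthropometric predictor because it folds height and
weight together.

## Cluster permutation inference

Pointwise two-sample t-maps use Welch by default (pooled-variance option
available). A point is testable only if at least 50% of subjects in *each*
group have a nonzero value there; this coverage rule avoids degenerate
variances at footprint margins where only a few subjects make contact. The
rule is computed once from the observed grouping and held fixed across
permutations. COP coordinate series are not activation-gated, so the
pipeline passes coverage 0 for them.

Clusters are contiguous same-sign points with pointwise p below the
cluster-forming threshold (.01); contiguity is 8-connectivity in 2D
(diagonals joined) and index adjacency in 1D. The cluster statistic is the
mass Σ|t| — chosen over max-|t| for sensitivity to spatially extended
effects; a `cluster_stat="max"` switch provides the alternative. The null
is the distribution of the maximum cluster statistic over both signs
across label permutations (1000 by default). Corrected p-values use the
(b+1)/(m+1) estimator, bounded below by 1/(n_perm+1). When the number of
distinct relabelings is at most `n_perm`, all of them are enumerated
instead and p = #{null ≥ observed}/m is exact (the identity relabeling is
included, so p ≥ 1/m); forcing `exhaustive=False` restores sampling with
replacement with a warning. Two-sided testing is implemented as sign-split
cluster formation against the common two-sided max null. Covariate
adjustment inside the permutation test is deliberately out of scope (no
accepted method).

## Synthetic cohort generator

The generator stands in for non-distributable raw data; it aims at
*statistical* realism of the quantities the pipeline measures, not
anatomical fidelity.

**Footprint**: ten smooth super-Gaussian lobes (heel, lateral midfoot,
five metatarsal heads, hallux, second toe, lesser toes) on the standard
grid, warped per subject into sensor coordinates by foot length
(≈ 0.147 × height ± 5 mm), foot angle and plate position, with left feet
mirrored. **Loading**: the total-force curve is a piecewise cubic Hermite
M-wave through (0, f₀), (t₁, 110 BW%), (t₂, 75 BW%), (t₃, ≈108 BW%),
(1, f₀) with zero slope at the interior knots, so the true extrema sit
exactly at the configured peak times; t₁..t₃ derive from the subject's
proportional intervals. The boundary load f₀ = 15% of peak keeps the first
and last frames above the detection threshold, so realized onset = frame 0.
Zone envelopes (heel early, midfoot mid-stance, metatarsals late, toes at
push-off, each with a small floor so the forefoot is in modest contact
from early stance) are renormalized per frame, which moves the COP
heel→forefoot while the frame total tracks the M-wave exactly. Per-sensor
multiplicative log-normal noise (σ = 0.05, mean-corrected) preserves
non-negativity; the 110 BW% valley/peak values and loading shape are
typical of adult self-paced walking. Regional effects are additive offsets
in weight-normalized pressure units on preset masks (calcaneus, second
metatarsal head — disjoint ellipses on the standard grid), ramped with the
force waveform so the full magnitude is present at the loading peak and
the offsets vanish at contact boundaries.

**Cohort structure**: 68 female / 24 male by default; anthropometrics from
per-sex normal distributions truncated at ±3 SD (age 34.5±14.9 /
33.7±14.4 y, height 159.4±4.8 / 172.8±4.9 cm, weight 54.9±7.3 /
70.1±9.1 kg); BMI derived from height and weight. Step length
0.702±0.06 / 0.724±0.063 m, step duration 0.49±0.03 / 0.524±0.048 s, foot
angle 3.04±4.37 / 6.35±3.73°. Proportional intervals per sex
(26.4, 24.0, 24.8, 24.9) ± (3.1, 2.9, 3.6, 2.7) % for females and
(24.3, 20.7, 28.9, 26.1) ± (3.1, 4.4, 6.9, 2.2) % for males, drawn per
subject and renormalized to an exact 100% partition (printed means summing
to 100.1 are accepted and renormalized). Contact time = 1.37 × step
duration (the ratio implied by the interval sums against the step
durations) ± 0.02 s. One valid trial of two consecutive steps per
participant; the whole cohort is a pure function of (config, seed).

**Reduced map simulator** (`simulate_group_maps`): for simulation studies
that need thousands of group comparisons (error-rate calibration, effect
recovery), subjects are drawn directly as standardized weight-normalized
maps: the canonical footprint times independent per-pixel Gaussian
variability (relative SD 0.13), optionally plus a correlated per-zone
log-normal gain and/or log-normal pixel noise. The default —
pixel-independent, symmetric — makes a stated pointwise Cohen's d the
quantity that actually governs detectability, which is what those studies
manipulate; the full recording generator keeps the correlated,
strictly-positive noise model. Effects can be injected additively or as a
fraction of the local mean ("relative"), the latter giving a uniform
pointwise d across a region (`effect_fraction_for_d`).

What the generator does *not* emulate: anatomical foot-shape variation
beyond a similarity transform (no sex-specific morphology, no deformities),
step-to-step variability within a participant (one trial each), cadence
dependence of pressure, and realistic double-support force sharing.
Passing tests therefore demonstrate correctness of the measurement and
inference chain under a known generative model — not clinical validity on
real feet.

## Problem sizes in the validation studies

The packaged studies are sized to run comfortably on one CPU: error-rate
calibration uses 500 null cohorts of 12 vs 12 subjects on a 40×20 standard
grid with 200 permutations; spatial effect recovery uses 50 runs of 30 vs
15 subjects on the full 120×60 grid (200 permutations), with effects sized
to pointwise d = 1.2; temporal direction recovery uses 50 full-size
(68/24) cohorts with both feet generated and averaged per subject;
pipeline invariants use a 4+3-participant cohort. With 200 permutations
the smallest attainable corrected p is 1/201 ≈ 0.005, ample for a .05
cluster threshold.

## Known limitations

- Landmark digitization is upstream of the package (landmarks are inputs);
  no automatic landmark detection is attempted.
- The similarity transform cannot align feet of different shapes; group
  maps compare grid positions, not guaranteed-homologous anatomy.
- Permutation inference assumes exchangeability of subjects under the
  null; covariate imbalance between groups is addressed only in the scalar
  analyses.
- The generator's peak pressures (≈ 300–500 kPa) sit at the lower end of
  typical barefoot walking values because smooth lobes spread load more
  evenly than real bony prominences do.
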