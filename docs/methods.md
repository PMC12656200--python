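# Methods

This note records the models, parameter choices and numerical conventions
behind `canopysense`, and what the synthetic-data tests do and do not show
about field data.

## Canopy structure from upward RGB frames

An upward frame under a street tree contains two pixel populations — bright
sky and dark foliage — that separate best in the blue channel, where foliage
reflectance is lowest. The classical workflow picks the valley between the
two histogram peaks by eye; here it is automated: the 256-bin histogram is
smoothed with an 11-bin moving average, local maxima at least 30 bins apart
are detected, and the threshold is the *raw*-count minimum strictly between
the two tallest peaks, ties resolved to the lowest intensity. The smoothed
curve is used only for peak finding; taking the valley on raw counts keeps
the threshold exact on sparse or quantised histograms. A unimodal histogram
(heavy overcast, frame fully under canopy) raises an error instructing the
caller to pass a manual threshold, which is retained as a first-class path.

Gap analysis divides the mask into a 5×5 grid; when the image dimensions are
not divisible by 5, remainder rows/columns merge into the last cell so every
pixel is counted exactly once. A sub-image that is at least 75 % sky is a
*large gap*, read as a between-crown opening; sky inside non-large-gap cells
is within-crown porosity. From the tallies:

* foliage cover `f_f = 1 − gap_pixels/total`,
* crown cover `f_c = 1 − large_gap_pixels/total`,
* crown porosity `φ = 1 − f_f/f_c`, clamped to `[1e−4, 1−1e−4]` — a fully
  closed crown would otherwise put `ln φ` at −∞; the clamp bounds LAI at
  ≈ 18·f_c, far above anything a street tree produces,
* `LAI = −f_c ln(φ)/k` with extinction coefficient `k = 0.5` (spherical
  leaf-angle distribution),
* zenith clumping index `Ω(0) = (1−φ)·ln(1−f_f)/(ln(φ)·f_f)`, with the
  analytic limit `(1−φ)/(−ln φ)` used when `f_f → 0`,
* effective `LAIe = LAI · Ω(0)`.

Sky is the strict inequality `blue > threshold`, which makes binarisation
deterministic at the threshold bin.

## Water stress from thermal frames

Seen from below, clear sky has an apparent radiometric temperature tens of
degrees below zero while foliage tracks air temperature, so canopy pixels
are those strictly above a 0 °C cutoff (exposed as a flag; warm overcast
skies may need a higher cutoff). Wet and dry reference temperatures — the
fully-transpiring and non-transpiring leaf extremes — are taken as the 5th
and 95th percentiles (linear interpolation between order statistics) of the
canopy pixel distribution, a per-frame stand-in for manual wet/dry leaf
references that cannot be applied from a moving vehicle; at least 20 canopy
pixels are required and a degenerate (constant) distribution is an error.

The raw stress index `(T_canopy − T_wet)/(T_dry − T_wet)` is preserved
unbounded; TWSI is its clip to [0, 1]. The conductance index
`Ig = (T_dry − T_canopy)/(T_canopy − T_wet)` is clipped to `[0, 10]`: the
cap handles `T_canopy → T_wet` (stomata fully open, Ig divergent) and the
floor keeps Ig non-negative when a canopy reads hotter than its dry
reference. Within the open interval the raw index increases and Ig strictly
decreases in `T_canopy`, so the two indices move oppositely by construction.
`CTD = T_canopy − T_air` uses ambient air temperature from the E-nose's
temperature channel, interpolated to the frame timestamp in the pipeline.
Campaign summaries (min/max/mean/SD per metric) use the n−1 SD, with 0
returned for a single frame.

## Geofencing and per-tree fusion

GPS fixes are linearly interpolated per axis onto a uniform 10 Hz grid whose
endpoints coincide with the first and last fix (the last grid point is the
final fix itself when the span is not a multiple of the step). Distances use
the equirectangular approximation — at sub-10 km extents its error is
millimetres, negligible against 10–15 m geofence radii — avoiding a geodesic
dependency.

Geofences are circles centred on the surveyed anchors. The radius is
`min(15 m, d_prev/2, d_next/2)` with `d` the ground distance to the
neighbouring anchors: the half-spacing rule makes adjacent regions disjoint
by construction, so no sample can be attributed to two trees; 15 m reflects
typical avenue-tree spacing and is configurable. Entry/exit times are the
first/last grid timestamps of each contiguous in-region run; an out-and-back
transect therefore produces one interval per pass, and all of a tree's
intervals are pooled into a single mean (the reported window is earliest
entry to latest exit). Streams of different rates (1 Hz E-nose, camera
frames) are aggregated independently against the same windows with no
cross-resampling; a window containing no samples yields a missing value,
never zero.

## Feature scaling and the network

Scaling is fixed-rule rather than data-driven, so a model transfers across
campaigns: voltages/5 (5 V rail), temperature/50, humidity/100; targets TWSI
unchanged, Ig clipped to [0, 1] (values above 1 indicate stomata more open
than the wet reference and saturate), CTD mapped affinely from its
physiological −20..+20 °C range via `(CTD+20)/40`, LAI/5 (street-tree LAI
stays below 5). Out-of-range values clip with a warning; rows with missing
parameters are dropped, not imputed, because per-tree means are already
aggregates. MQ-7 is logged and summarised but excluded from the model input
vector, which is fixed at 10 elements (8 gas channels + temperature +
humidity). The inverse mapping is exact on the clipped domain. The split is
a seeded uniform permutation labelled 70/15/15 (rounded to whole rows).

The network is 10-20-4: logistic-sigmoid hidden layer, identity output.
Weights initialise uniformly in [−0.5, 0.5] from a seeded generator.
Training is Levenberg–Marquardt with an analytic residual Jacobian: each
epoch solves `(JᵀJ + μI)Δ = Jᵀe` and accepts the step only if training SSE
decreases, dividing μ by 10 on acceptance and multiplying by 10 on
rejection (μ₀ = 10⁻³, cap 10¹⁰). A step is therefore descent by
construction. Stopping: epoch cap, μ overflow, or 6 consecutive validation
MSE increases, returning the best-validation weights — a standard early-stop
count for LM fitting tools. The hidden width 20 was selected by a trimming
sweep over {5, 10, 15, 20} and is a flag. Reported R is the Pearson
correlation of flattened predictions against flattened targets (one pooled
value per stage, matching how a single R per stage is conventionally
reported); per-output R values are logged alongside. A second, untouched
hold-out set can be passed for an additional-test stage. With a fixed seed
the whole procedure is bit-deterministic.

## Statistics

PCA runs on the correlation matrix (z-scored columns) because the fused
table mixes volts, °C, hPa and unitless indices; a constant column is an
error naming the column. Loadings are orthonormal eigenvectors ordered by
eigenvalue, with the sign fixed so each component's largest-magnitude
loading is positive (plot orientation is otherwise arbitrary, which would
make regression tests flaky). Explained percentages sum to 100 over all
components; scores·loadingsᵀ reconstructs the standardised matrix when all
components are kept. The correlation matrix is pairwise-complete Pearson R
with two-sided p-values from `t = R√((n−2)/(1−R²))`; pairs with fewer than
3 complete observations or zero variance are missing, and the CSV export
stars cells at α = 0.05.

## Synthetic data: what it emulates, and what it does not

The generators provide ground-truthed stand-ins for the field inputs, and
every dataset they emit is deterministic given its seed.

**Canopy scenes.** A scene is planned per 5×5 grid cell: a subset of cells
is designated between-crown sky (their planned sky fractions sit ≥ 0.78,
safely above the 0.75 large-gap cutoff), and the remaining cells are filled
with overlapping jittered elliptical blobs, then adjusted with small disks —
holes punched in foliage or foliage dabs on sky — until each cell's sky
count matches its plan (within ~0.1 % of the cell). Cell-wise planning is
used because grid crown cover is *discontinuous* in blob area: every cell
that crosses the 75 % cutoff jumps f_c by ≈ 0.03, so free placement of
crowns cannot reliably realise a cover target to ±0.02, while per-cell
budgets with margins on both sides of the cutoff can. Realised f_f/f_c/φ
are measured by running the package's gap analysis on the final noise-free
mask; this is the ground truth the recovery tests compare against.
Rendering paints sky/canopy colours separated mainly in blue (220 vs 60)
with per-pixel Gaussian noise (σ = 10), so the imaging chain must genuinely
re-segment the scene through histogram thresholding. Not emulated: mixed
pixels at leaf edges, sun glint, overcast low-contrast histograms, motion
blur — so passing recovery says the algorithm chain is correct, not that
field segmentation error is sub-percent.

**Thermal scenes** place sky at −30 °C (σ = 0.5) and canopy pixels at
Gaussian(20, 2) °C over a known mask; recovery of the canopy mean is checked
against the 2σ/√n sampling bound. No emissivity or atmospheric effects.

**Transects** put collinear anchors 30 m apart and drive past at 5.6 m/s
(the ~12-min traversal speed of a 5 km avenue), 1 Hz fixes, optional
Gaussian GPS jitter; pass times are known in closed form, so geofence
windows have kinematic truth.

**Linked datasets** draw a latent per-tree state — LAI uniform in
[0.3, 4.8], a stress level in [0.35, 0.95] used directly as TWSI — and
derive Ig and CTD through the same index relations the thermal module uses
(fixed references T_wet = 15, T_dry = 30 °C; ambient air uniform in
[16, 24] °C). Each gas channel is a seeded smooth monotone function (linear,
square-root or square, random sign on the stress term) of the latent state
plus Gaussian voltage noise, echoing the field pattern of sensor responses
rising with leaf area and varying with stomatal conductance. All
coefficients are recorded. Because the targets are smooth functions of a
low-dimensional latent state that the ten inputs determine, the network's
held-out R is a genuine recovery measure: ≥ 0.95 noiseless, and still high
at 0.05 V noise. Field data carry cross-sensitivities, drift and
confounders absent here, so field R (≈ 0.81–0.87 in comparable settings) is
expected to be lower than the synthetic figure.

## Problem sizes

Defaults used by the test suite and the acceptance script: 400×400 scenes
for the 4×3×3 recovery sweep, a 20-tree transect, a 20-tree end-to-end
campaign at 160×160 frames, and n = 500 linked trees for the network —
sizes at which every check completes in seconds while leaving each
estimator's error regime unchanged.

## Known limitations

* The valley detector assumes a bimodal blue histogram; heavy overcast may
  require the manual threshold path.
* Percentile wet/dry references are relative to the frame's own temperature
  spread; absolute stress levels between frames with very different spreads
  are not strictly comparable.
* Geofences are circles; street medians or staggered plantings with
  irregular geometry may need per-tree radii.
* Baseline correction for the gas channels exists but is off by default;
  raw voltages are analysed, so between-campaign sensor drift is untreated.
* The ANN is a point predictor with no uncertainty quantification.
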