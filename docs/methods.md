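# Methods

`organoidquant` implements the quantitative analysis stack of organoid
drug-response experiments: microscopy-based live/dead quantification,
event-based growth analytics, dose-response and drug-combination
pharmacology, and the recovery assays that surround them.  Because the raw
experimental data (confocal stacks, plate reads, movies) are not
redistributable, every analysis stage is exercised against a synthetic-data
generator that produces ground-truthed stand-ins for each modality.  This
note records the models, the concrete numerical definitions chosen where
the underlying procedures were described only qualitatively, and what the
synthetic data do and do not establish.

## Synthetic data generator (`synthgen`)

**Image stacks.**  Nuclei of H2B-reporter-labelled cells are modelled as
xy-isotropic ellipsoids whose z semi-axis is shrunk by
`pixel_size_um / z_step_um`, mirroring the anisotropic sampling of confocal
z-stacks (defaults: 1 µm pixels, 2 µm z-steps over a 96×96×12 voxel
volume).  Intensity inside a blob follows a Gaussian profile floored at
0.75 of the peak; the peak sits at `snr` times the mean background and the
background carries additive Gaussian noise (level 100, sd 10 in arbitrary
units).  The floor guarantees that a threshold at the midpoint of the
background/foreground gap recovers the exact truth voxel set whenever
`snr > 1` and noise is small relative to the gap — a deliberate property
that lets segmentation accuracy be scored against truth rather than against
another segmentation.

A dead cell is rendered as `fragments_per_dead` small blobs (apoptotic
nuclear fragments) scattered within one nucleus diameter of the death site;
an optional propidium-iodide channel marks exactly the fragment voxels.
Objects are placed by rejection sampling (at most 1000 retries, loud
failure on overcrowding) and each placed object reserves its
26-neighbourhood-dilated voxel set, so rendered objects are *separated*,
not merely disjoint: connected components of the foreground map one-to-one
onto ground-truth objects.  Defaults — live-nucleus radius 5 px (±15%),
fragment radius 1.8 px, 4 fragments per dead cell — are free parameters of
the generator, not calibrated to any particular optics.

**Time lapses** replay an explicit event schedule: a mitosis replaces the
parent blob with two daughters of `2^(-1/3)` times its radius (volume
conservation) placed beside it; an apoptosis replaces the blob with
fragments at the death site.  An event takes effect at the first frame
whose timestamp covers it, and the returned event log equals the realized
schedule, so true alive counts obey
`N(t) = N(0) + mitoses(≤t) − apoptoses(≤t)` by construction.

**Plates.**  Raw well signals are drawn from the normalized
four-parameter-logistic surface (below): monotherapy wells at the 4PL
viability, combination wells at the Bliss-independent product of the two
monotherapy viabilities minus an optional injected excess (floored at 0),
vehicle wells at full viability.  Raw signal = plateau + v·(vehicle −
plateau), multiplied by lognormal noise parameterized by its coefficient of
variation — multiplicative noise matches the proportional error structure
of luminescence/fluorescence assays, in contrast to the additive photon
background of the imaging model.  Two log-spaced concentration presets
ship with the package: a 14-point grid spanning 5 nM–5 µM (full combination
matrices) and a 22-point grid spanning 5 nM–20 µM (wide single-pass
screens), plus a 9-point 5 nM–20 µM variant.

**Kinetics.**  Resazurin (alamarBlue) conversion is modelled as
RFU(t) = background + viability·slope·min(t, t_sat) + Gaussian noise:
linear reduction while substrate is abundant, hard saturation afterwards.
Default reads every 15 min over 2 h.

All generators are pure functions of (parameters, seed); no global RNG
state is touched.

## Image quantification (`imaging`)

The live/dead workflow follows four steps: (1) threshold the H2B channel —
foreground is intensity ≥ T (the inclusive convention is fixed for
determinism); (2) label connected particles, either per z-slice
(connectivity 8 by default, 4 available) or volumetrically (26, with 6
available); (3) classify each particle by size — dead iff its pixel count
falls below the cutoff, with the boundary counting as alive.  The default
cutoff is *half the median particle size of a vehicle (healthy) reference*,
on the reasoning that apoptotic fragments are far smaller than half a
nucleus; the cutoff is always exposed and recorded.  (4) integrate alive
and dead pixel areas over the slices forming the lower half of the
organoid's own z-extent (bottom-anchored `floor(n/2)` slices, at least
one), because image quality degrades with depth; the analyzed z-range is
recorded in the output.  Alive + dead always partitions the thresholded
foreground — this identity is asserted, not assumed.

The organoid z-extent is taken as the z-support of the thresholded mask.
Manual curation of particle classes is intentionally out of scope; the
size rule is the implementation.

**Depth-coded projection.**  Per xy pixel the projection takes the maximum
over z and colours it by the z-index of that maximum (ties to the lowest
z, matching `argmax`); an optional four-quadrant layout merges the
projection with a transmitted-light image.

**Ramped-threshold optimum.**  For candidate thresholds T the scan records
surface area(T) (pixels ≥ T) and mean(T) (mean intensity of those pixels).
Both curves are min–max normalized over the grid and the optimum maximizes
`score(T) = norm_mean(T) − norm_area(T)` — the concrete reading adopted
here of "highest mean signal with the most confined surface area", with
"most confined" read as *smallest area*.  Ties resolve to the lowest T and
thresholds selecting an empty surface are excluded; a constant image is an
error.  The score is simple enough that a brute-force re-evaluation serves
as an exact oracle in the tests.

**PI/H2B death ratio.**  Cell death is the ratio of PI-positive to
H2B-positive pixel counts pooled over the whole field (all organoids)
*before* division — a pooled ratio, not a mean of per-organoid ratios, so
no per-organoid error bar exists.  The PI mask is deliberately not
intersected with the H2B mask, so the ratio can marginally exceed 1 on
pathological input.  Thresholds may be fixed or derived per channel by the
ramped scan.

## Event analytics (`events`)

Event logs (time, mitosis/apoptosis, organoid) are sorted by time with
apoptosis ordered before mitosis at exact ties (an arbitrary but fixed
convention) and cumulated into a relative cell-count trajectory from a
starting count n0; a log whose running count would go negative is rejected
as inconsistent.  Rates are counted in half-open windows [kw, (k+1)w) and
divided by the number of organoids observed.  Growth speed is the OLS slope
(cells/hour) of the step trajectory sampled at its change points plus the
window endpoints; the default windows are the first and second half of the
recording, the natural split for arrest-then-release experiments where
regrowth resumes only ~20–24 h after drug withdrawal.

## Dose-response and combinations (`doseresponse`)

**Normalization.**  v% = 100·(raw − B)/(V − B) with V the vehicle-well mean
and B the multi-drug plateau.  B defaults to the mean of the k = 3
highest-total-concentration wells; because screens determine the plateau
per cell line and day (often manually), `baseline_rule` also accepts an
explicit plateau signal, which is what the exactness tests use.  Replicate
wells at the same dose pair are averaged after normalization and values are
not clipped.

**4PL.**  The normalized variable-slope logistic
`y(x) = 100 / (1 + 10^((x − log10 IC50)·h))`, x = log10 molar
concentration, asymptotes fixed at 100/0, h > 0 for a descending curve.
Fitting is least squares with multi-start initialization (5 midpoints × 3
slopes) and box bounds; the results object carries estimates, standard
errors from the covariance, RSS and an honest convergence flag.  ΔIC50
between two lines is the difference of log10 IC50 (positive = first line
more resistant).

**Bliss.**  With fractional inhibitions fA, fB from the monotherapy
row/column (clamped to [0,1]), expected = fA + fB − fA·fB and the score is
observed − expected; monotherapy cells score 0 by construction.  This is
the standard Bliss-independence excess — the definition adopted here since
only the model family, not a formula, is conventionally stated.
Heat-map smoothing is a window×window moving average (odd window, default
3, shrinking at edges; window 1 is the identity), applied after Bliss
scoring when both are requested.

**Curve extraction.**  Monotherapy curves are the zero-concentration
row/column of a full matrix.  Fixed-ratio combination curves take the
cells where log10(conc_B) = log10(conc_A) + offset (offset 0 = equimolar;
negative offsets express designs where drug B runs some decades below drug
A); combination IC50s are reported on the reference drug-A axis with the
offset recorded, since the midpoint of a fixed-ratio curve accounts for
both drugs.

## Recovery assays (`recovery`)

**alamarBlue viability.**  The linear range is the longest read window
anchored at t = 0 whose OLS fit has R² ≥ 0.99 (minimum 3 reads; a noisy
flat series falls back to the minimal window) — the concrete rule adopted
for "within the linear range of the assay".  Viability is RFU at the end
of that window minus the t = 0 background read, normalized as
100·treated/vehicle.  A perfectly flat series counts as R² = 1 (a line
fits exactly), so zero-viability wells resolve without special-casing.

**Tumor volumes.**  V = D·d²/2 from the major/minor caliper axes; pairs
are canonicalized by swapping so entry order cannot matter.  Percent change
is relative to each animal's day-0 baseline; per-day group means and
standard deviations are attached.

**Cell cycle.**  EdU ≥ threshold ⇒ S phase regardless of DNA content (the
pulse marks replicating cells even at near-4N DNA); otherwise DNA ≤ the 2N
gate ⇒ G1 and DNA ≥ the 4N gate ⇒ G2; cells between the DNA gates remain
unassigned and are reported rather than forced.  Auto-gating from a
reference sample puts the EdU threshold at the Otsu split of log EdU and
the DNA gates at 1.4× / 1.7× the 2N histogram peak of EdU-dim cells.
Distributions are compared by chi-square on the 2×3 phase-count table
without continuity correction.

## Pipelines (`pipeline`, `cli`)

Two end-to-end demonstrations run the stack on generated data from a single
JSON-serializable `RunConfig` (unknown keys rejected; every parameter and
derived default echoed into `manifest.json`).  The drug & release pipeline
re-images the *same* simulated organoids at every timepoint (a paired
design: one persistent placement transformed by the scenario's events,
12 organoids per condition by default) and normalizes each series to its
pre-treatment alive signal.  It classifies particles volumetrically so that
whole objects rather than individual sphere cross-sections receive a label;
the per-slice mode remains available through the imaging API.  The plate
pipeline produces normalized matrices, monotherapy/diagonal fits, a ΔIC50
table across lines and smoothed Bliss maps.  All numeric outputs are
byte-reproducible for a fixed config and seed; figures (PNG) are optional
and excluded from the reproducibility contract.

## Problem sizes and numerical choices

Tests and the acceptance script use 96×96×12 voxel stacks with 20 live and
5 dead nuclei (21 stacks across snr ∈ {3, 5, 10}), 14×14 dose matrices,
100 simulated plates for the noisy IC50 recovery, 100 random logs for the
trajectory oracle, and n = 5000 cells for cell-cycle recovery — sizes at
which every recovery property concentrates well while a full run stays in
the tens of seconds.  Floating-point ties in the threshold scan and the
trajectory sort are broken deterministically (lowest threshold; apoptosis
first); all randomness flows from explicit integer seeds.

## What the synthetic data do not show

The generator omits PSF blur, depth-dependent attenuation, out-of-focus
haze, stage drift, organoid lumen/crypt morphology and touching nuclei;
classifier performance on it is therefore an upper bound, demonstrating
correctness of the pipeline's logic rather than robustness to real optics.
Plate noise is i.i.d. lognormal with no edge or drift effects, so the IC50
error figures exclude plate-layout biases.  Event logs are taken as given
(the corresponding experiments mark events manually); no detection from
pixels is attempted.  Only Bliss independence is implemented — Loewe, ZIP
and other synergy models are out of scope, as are survival analysis and
compensation of real cytometry data.
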