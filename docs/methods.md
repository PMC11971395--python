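# Methods

This note records the models, estimators, numerical choices and known
limitations of the axoasym pipelines, in the order data flows through
them.

## Synthetic data model

The generators define the conditions under which every pipeline is
validated; they emulate the *structure* of the real inputs, not their
optics.

**Fluorescence cells.** A cell image is flat background + a Gaussian
kinetoplast blob (sd 2 px) + a flagellar line signal rendered as a 1-px-sd
Gaussian ridge whose amplitude follows a logistic ramp in arclength,
centred at the onset distance with steepness κ (default 1.5 px⁻¹), from
background (100 AU) to plateau (3000 AU), defaults matching the onset QC
gates' intensity scale.  Line and blob are max-composited so the plateau
value is attained exactly on the ridge.  No point-spread function and no
structured autofluorescence are modelled — the background is flat, an
explicit choice since the real background structure is unspecified;
consequently the onset tests validate geometry and fitting, not
deconvolution.  Noise is additive Gaussian (Poisson noise deliberately
omitted: the statistics exercised — sigmoid least squares, rank tests —
do not depend on the noise law at the tested signal-to-noise).

**Beats.** The tangent angle is a pure travelling wave
θ(s, t) = a·sin(2πft + 2πws) for tip-to-base propagation (crests move
from s = 1 to s = 0; sign flipped for base-to-tip; phase constant φ₀ = 0).
Shapes are obtained by integrating (cos θ, sin θ) at uniform arclength
steps ds = L/(n−1), θ evaluated at segment midpoints, base at the origin,
body axis = +x.  This midpoint construction makes the segment angles of
the generated shape *exactly* the generating wave, so the tangent-angle
round trip has an analytic oracle, and it conserves per-frame arclength
exactly even under angle noise (noise is added to θ before integration).
Defaults: f = 28 Hz, a = 0.5 rad, w = 1.5, L = 20 μm, 200 fps, 0.5 s,
50 points — a wild-type-like tip-to-base beat at the frame rate of
high-speed beat videos.

**Axonemes.** The density template holds nine doublet Gaussian blobs
(sd 2 px, amplitude 1.5) at 40° spacing on a ring (radius 28 px in a
96×96 image), one ODA blob per doublet at 1.25× the ring radius, offset
+10° from its doublet, amplitude 1.0 scaled by the per-doublet occupancy,
and optional central-pair density rendered as a rotationally symmetric
annulus (radius 0.18×, sd 0.06× ring radius).  The annulus (rather than
two discrete central microtubules) keeps the uniform-occupancy template
exactly invariant under 40° rotation, which is the property ninefold
averaging exploits; after rotational averaging a real central pair would
in any case appear as such an annulus.  All geometry constants live in
one module-level block (`AXONEME_GEOMETRY`) so region masks (e.g. the ODA
footprint, thresholded at 5% of the blob amplitude) are derivable in
tests without duplicating numbers.  Tilt is modelled as anisotropic
scaling by the axis ratio b/a followed by in-plane rotation — the
projection model the perspective correction inverts.

**Tracks.** Correlated random walks at fixed step speed v/fps with
Gaussian heading increments (sd `turn_sd` per step).  Mean speed is
exactly v for every track regardless of turning, which gives motility
statistics an exact oracle.

What passing these tests does *not* show: robustness to tracing errors,
uneven illumination, out-of-focus frames, or segmentation mistakes — the
generators do not produce them.

## Fluorescence profiles

Background subtraction is scalar: the median of pixels below the Otsu
threshold (robust when the cell occupies a minority of the field); a
constant-offset override exists in the CLI config.  Intensity is sampled
by bilinear interpolation at 1-px arclength steps along the trace,
averaged across a 3-px perpendicular linewidth (an ImageJ-style line
profile; the linewidth is a configurable default, not a measured
property).  Profiles are per-cell max-normalized and linearly resampled
onto a fixed 100-point grid on [0, 1].  Clustering is agglomerative with
average linkage (UPGMA) on Euclidean distance between profile rows, via
`scipy.cluster.hierarchy.linkage`; scipy's deterministic tie-breaking is
accepted as-is (merge heights — the quantity with an external oracle —
are unaffected on tie-free data).  Both per-cell rows and per-protein
mean rows can be clustered; neither is privileged by the API.

## Onset detection

"Circles of increasing radius" are implemented as nested discs — the
maximum over all pixels within distance r — which makes the radial
profile monotone non-decreasing, the property the sigmoid model assumes
(an annulus mode exists behind a flag but is not the default for this
reason).  Defaults dr = 0.5 px, r_max = 40 px.  The four-parameter
logistic is fitted by Levenberg–Marquardt with the amplitude and slope
log-parameterized (enforcing M ≥ b, κ > 0) and a derivative-free
initialization: b, M from the profile extremes, r₅₀ from the
half-maximum crossing, κ = 4/(r₇₅ − r₂₅).  A three-parameter (b = 0)
variant is obtainable by fixing the baseline, but the free-baseline form
is the default since radial max profiles rarely start at zero.  Fit
failure and zero-variance profiles map to the `poor_fit` QC reason.  QC
gates are strict inequalities — midpoint within (0, r_max), slope
> 0.7 px⁻¹ (a point-spread-function-scale sharpness), maximum > 1000 AU,
R² > 0.95 — and the slope threshold is applied to κ in per-pixel units.
Only QC-passing cells contribute measurements; summaries report
mean ± s.e.m. and n.

## Beat metrics

Frames are resampled to N = 50 equal arclength points, optionally
smoothed with cubic smoothing splines (first along arclength per frame,
then along time per point; the spline residual budgets default to 0, the
interpolating limit, and are surfaced in output metadata — appropriate
budgets are of order (number of samples)×(noise variance)).  Tangent
angles come from central differences (one-sided at the ends), unwrapped
along arclength, with frames held on a common 2π branch over time.  The
cell-body axis defaults to the base tangent of the time-averaged shape
(so it co-rotates with the cell, making metrics invariant to rigid
rotation of the video); a fixed laboratory axis can be passed instead.

*Dominant frequency*: per-s time series are mean-detrended (no window —
a Hann window is available but unnecessary for near-single-frequency
beats at these durations), their DFT power spectra averaged along s, and
the argmax over positive frequencies returned at resolution fps/T.
A static field yields a missing value and the cell is excluded.

*Angular amplitude*: two estimators are provided.  `angular_amplitude`
is the literal max-over-s of the min–max range of θ over the video.
The pipeline metric, `beat_cycle_amplitude`, is the range over one beat
cycle of the dominant-frequency reconstruction: per s, θ is fitted to
A·sin(2πf_dom·t) + B·cos(2πf_dom·t) + c, the squared amplitude
A² + B² is corrected for its additive noise bias (4σ̂²/T, σ̂² from the
fit residuals), the amplitude profile is smoothed over 5 arclength
samples (the physical profile is smooth; this suppresses the upward bias
of a max over noisy per-s estimates), and 2·max_s √(A²+B²) is reported.
The two coincide for a densely sampled noiseless sinusoid, but at 200 fps
a 40 Hz beat has only 5 frames per cycle — the raw range then
systematically undershoots 2a by ~5% while angle noise inflates it — so
the cycle-reconstruction estimator is the reported one for screened
(sinusoidal) beats.

*Waves per flagellum*: the complex Fourier coefficient at the dominant
bin is taken per s; the waves count is |total unwrapped phase change
across s| / 2π.  A travelling wave with w wavelengths per flagellum
yields w; a standing wave yields 0.  The estimate is flagged
low-confidence when the coefficient magnitude sits below the per-s noise
floor (median magnitude over the other bins) for more than half of the
arclength positions.

*Screens*: digitisation consistency requires the coefficient of
variation of per-frame flagellum length ≤ 0.05 (the screen is stated
practice; the cut-off is this package's default).  Sinusoidality pools
per-s single-tone fits into an aggregate R² = 1 − ΣSS_res/ΣSS_tot and
requires ≥ 0.5 by default; both thresholds are configuration and echoed
into output metadata.

*Segments*: the same operations restricted to s < 0.5 (proximal) and
s ≥ 0.5 (distal); a uniform travelling wave with w = 1.5 gives ≈ 0.75
waves per half.

*Signal-speed helper*: for tip-to-base waveforms at frequency f over a
flagellum of length L, the beat period is 1000/f ms and a base-to-tip
initiation signal must travel f·L μm/s; at 40 Hz and 25 μm that is
25 ms and 1000 μm/s.

## EM averaging and difference maps

The ellipse through the nine doublet centres is fitted by direct
least-squares conic fitting (`skimage.measure.EllipseModel`).
Perspective correction is a pure anisotropic scaling in the ellipse's
principal frame mapping it to a circle of radius √(ab) — area-preserving,
and exactly the inverse of the tilted-section model (a tilted circle
images as an ellipse); no shear or projective terms are assumed.  Ratios
b/a < 0.3 trigger a warning (grazing sections are unreliable).

Ninefold averaging is the pixel-wise mean over rotations by k·40° about
the sub-pixel ring centre.  Rotations use prefiltered cubic-spline
interpolation: cubic interpolation is near-variance-preserving on pixel
noise (measured ≈ 0.92 of the ideal σ/3 for the mean of nine rotations,
where bilinear attenuates to ≈ 0.73·σ/3) and more faithful on structure.
Pure translations and the perspective warp use bilinear interpolation.

Rotational averages are mutually aligned to an iteratively refined mean
(3 iterations): translation from the FFT cross-correlation peak with
quadratic sub-pixel interpolation, and in-plane rotation searched over
[0°, 40°) — the full space under ninefold symmetry — coarsely at 2° then
locally at 0.5°.  Rotation search is enabled by default (translation-only
mode exists).  Because alignment is mutual, the common frame is arbitrary;
round-trip accuracy is therefore asserted on relative transforms.  Images
whose best normalized correlation falls below 0.1 are flagged and
excluded from the reference and the group mean.

Difference maps are parental mean − mutant mean, so positive values mark
electron density lost in the mutant.  Per pixel inside the axoneme mask
(a disc of 1.4× the ring radius, configurable), the two aligned stacks
are compared with a two-sided Mann–Whitney U test — a vectorised normal
approximation with tie and continuity corrections, verified against
scipy per-pixel and against exhaustive enumeration of U's null
distribution at small n.  Correction for multiplicity over the mask
pixels is Bonferroni by default (Holm optionally); with n = 25 per group
the smallest attainable corrected p is well below α = 0.05, and a warning
reports the attainable floor when group sizes make significance
impossible.  Null calibration on i.i.d. noise stacks keeps the
family-wise error at or below α.  The method is sensitive to
proximal–distal (radial/ring) differences only; doublet-to-doublet
asymmetries are averaged away by construction.

## Motility

Speed, velocity and directionality use timestamps directly (irregular
sampling supported; durations are never inferred from a frame rate).
Directionality is displacement / path length ∈ [0, 1], undefined (missing)
for a static track.  mean_velocity ≤ mean_speed for every track, with
equality only for collinear monotone motion.  Cell lines are compared on
per-replicate means with a two-tailed Student's t-test; normalization to
a reference line divides per-replicate group means by the reference mean
and reports mean ± SD across replicates.  A minimum-duration track filter
is available but off by default.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on synthetic data
at desk scale: beat grids of 24 conditions × 100 frames × 50 points;
onset cohorts of 10–20 cells on 128×128 images; EM groups of 25
cross-sections on 96×96 grids with 50-repeat null calibrations; 10⁴
random tracks for metric inequalities.  These sizes were chosen to give
the estimators stable statistics while keeping the full validation run
in the tens of seconds.

## Known limitations

* No optical PSF, 3-D geometry or hydrodynamics anywhere; generators are
  structural emulations.
* Flagellum tracing, kinetoplast detection, particle tracking and beat
  classification are consumed as inputs, never computed.
* The radial-max onset model assumes the flagellum is the brightest
  object near the kinetoplast; competing bright structures inside r_max
  would corrupt the profile.
* The alignment correlation threshold (0.1) and axoneme mask factor
  (1.4) are pragmatic defaults, configurable per run.
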