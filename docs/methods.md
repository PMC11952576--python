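# Methods

This note documents the models behind `optarray`: what is simulated, how it
is analyzed, the numerical choices that matter, and what the synthetic
study can and cannot say about real recordings.

## Head and probe geometry

The head is two concentric spherical caps (default brain radius 80 mm,
scalp optode surface at 93 mm) extending to a polar angle of 100 degrees —
slightly past the equatorial "ear line", as lateral cortex does. Scalp
*vertices* sit 3 mm below the optode surface (mid-scalp), so the nearest
scalp-to-brain distance is 10 mm for the default 13 mm standoff. Region
labels (`dlPFC_left`, `dlPFC_right`, `mPFC`, `other`) are painted by
angular sector over the frontal band; they stand in for atlas anatomy and
exist so activation patches and ROIs have named targets. The mesh is a
UV-style triangulation (14 rings x 56 vertices, 785 brain vertices),
mirror-symmetric so left/right label counts match; per-vertex areas are
one-third of the adjacent triangle areas.

Probe layouts are defined flat and draped onto the scalp sphere row by row
using exact spherical circle-circle intersections, the way a flexible cap
accommodates curvature: each new optode is placed at exactly its nominal
distance from its two supporting neighbors, so *channel* separations stay
nominal and the unavoidable curvature strain lands on unconstrained
diagonals. The triangular HD lattice is built outward from its middle row,
halving accumulated strain; lattice pairs that still drift outside the
+-1.5 mm class tolerance are simply not enumerated as channels. Defaults
give 52 x 30 mm sparse channels (17 sources, 16 detectors) and
128 x 19 mm + 92 x 33 mm HD channels, each array plus 8 x 8 mm
short-separation detectors; the HD span (304 mm) matches the sparse span
(300 mm) so the fields of view agree.

## Forward model

Sensitivities use the Rytov adjoint product of semi-infinite diffusion
Green's functions with bulk optical properties mu_a = 0.01 /mm,
mu_s' = 1.0 /mm at both wavelengths (760/850 nm). The curved boundary is
handled through the planar image identity d_img^2 = d^2 + 4 h1 h2 (h =
radial depth below the extrapolated boundary at R + 2D), which is
symmetric in its arguments so source-detector reciprocity holds exactly.
Optodes are placed one transport mean free path below the surface. Vertex
volume elements are vertex area x a 3 mm slab.

Rows are calibrated in two compartments: brain columns are scaled so the
summed brain sensitivity x volume equals the channel's Beer-Lambert
pathlength (separation x partial-pathlength factor, PPF = 1 by
convention), and scalp columns so the scalp partial pathlength is 1.5 x
that. The brain calibration makes the generative projection and the
channel-space Beer-Lambert inversion mutually consistent (a spatially
uniform cortical change is recovered exactly — the basis of the noise-free
recovery check); the separate scalp calibration keeps the relative
superficial contamination of a channel comparable across separations, as
it is physically, instead of inheriting the raw brain fraction (which
ranges from ~4% at 19 mm to ~30% at 33 mm and would inflate scalp signal
on short channels by an order of magnitude). Short-separation channels,
which sense essentially no brain, are calibrated on their total path. The
ratio 1.5 > 1 encodes that the scalp is always the more sensitive
compartment. Raw (uncalibrated) sensitivities remain available
(`normalize="none"`) and are linear in the volume elements.

## Synthetic study conditions

The generator reproduces the study design it emulates: 17 subjects, each
"wearing" both arrays for one run of 20 s rest plus 18 x 18 s blocks
(9 per condition, order randomized, inter-block rest uniform on 10-15 s);
sampling 24.4 Hz (sparse) and 17.5 Hz (HD). Per subject one ground truth
is drawn and applied through both arrays' forward models with independent
measurement noise; events are shared within subject.

Activation is top-hat patches around region centroids: lateral (both
dlPFC) HbO +1.0 uM incongruent / +0.5 uM congruent, medial (mPFC) -0.5 /
-0.25 uM, each with HbR at -0.3 x HbO. The source study does not report
effect sizes in uM; 1 uM peak HbO is a typical robust single-condition
prefrontal response, and the 2:1 condition ratio encodes the
cognitive-load contrast the statistics must detect. Patch radii (40 mm
lateral, 25 mm medial) make the activation broad relative to a single
channel's footprint, as executive-network activation is; the block time
course is the 18 s boxcar convolved with a peak-normalized double-gamma
kernel (peak 6 s, undershoot 16 s), so amplitudes read directly as peak
uM. Per-subject gain is lognormal-ish (normal, sd 0.25, clipped) and
cardiac rate jitters by 0.1 Hz.

Scalp vertices carry only systemic physiology — cardiac (1.1 Hz, 0.15 uM),
respiration (0.25 Hz, 0.10 uM), Mayer waves (0.1 Hz, 0.25 uM) and slow
drift (0.4 uM) sharing one spatial gain pattern — so short-separation
channels are a faithful superficial reference. Measurement noise is
specified as a white spectral density per separation class (OD/sqrt(Hz),
scaled by sqrt(fs/2): both arrays use the same detector hardware, so they
share a noise *density*, not a per-sample amplitude) plus 1/f noise;
densities grow with separation and land raw-intensity SNR in the 40-60
range. Motion spikes (0.3/min, 1-3 s, ~0.25 OD) and baseline steps
(0.15/min, ~0.08 OD) hit random 40% channel subsets; a Poisson number of
peripheral (superior, hair-prone) channels per HD recording is forced
below the pruning floor (mean 8, vs 0.3 for sparse), mirroring the
direction of the reported retention difference.

What this does **not** emulate: skull/CSF layering, subject anatomy,
trial-level (3 s) response substructure, serially correlated physiological
brain noise, task-correlated motion, or behavioral performance. Passing
tests therefore validate the *analysis chain* under controlled truth, not
the field performance of any instrument.

## Processing chain

Pruning: a channel is dropped when either wavelength has mean raw
intensity < 0.001 or SNR (mean/sd of raw intensity) < 5. OD is
-ln(I / temporal mean I); with this convention each channel's baseline
constant is arbitrary, and every downstream statistic uses within-window
differences. SplineSG motion correction flags samples where a 0.5 s
moving-window SD exceeds 3 x its median — computed jointly over the two
wavelengths of a channel, because motion is achromatic and
wavelength-unbalanced correction would unmix into large spurious
concentration steps — then subtracts a smoothing spline (csaps p = 0.99)
inside flagged segments, re-anchors segment levels sequentially on 1 s
neighboring-baseline means, and finally replaces residual spikes (>4
robust SD from an order-3, 10 s Savitzky-Golay baseline). The low-pass is
an order-3 zero-phase Butterworth at 0.5 Hz. Beer-Lambert inversion uses
pathlength = separation x PPF (PPF = 1, matching the generator). Block
rejection is automated (the original step was manual): a block is
rejected when >50% of unpruned channels show a within-block HbO
peak-to-peak excursion above 15 uM; subjects with fewer than 5 surviving
blocks in either condition are excluded.

## GLM

Per condition, one column per Gaussian center stepped 1 s across the
inclusive -2..23 s window (26 columns); "1 s width" is taken as the
Gaussian standard deviation (the convention of the toolchain this chain
mirrors) — at sigma = 1 s the basis reproduces smooth responses to <0.1%,
whereas sigma = FWHM/2.355 would leave ~5% inter-basis ripple. Nuisance
columns: the short-separation channel best correlated with the target
(per chromophore, ties to the lowest index) and Legendre drift polynomials
of order 0..3. Estimation is OLS (LAPACK least squares, minimum-norm on
rank deficiency), grouped by chosen SS channel for a single multi-RHS
factorization per group. The HRF is the basis expansion of the condition
coefficients only; block statistics use the concentration series with the
fitted nuisance (SS + drift) removed.

A known property of the windowed design: the response to an 18 s block
lasts ~58 s, so its tail extends past the 23 s window edge and overlaps
neighboring windows under the 10-15 s jitter, biasing estimated
amplitudes by ~1-2%. The noise-free recovery validation therefore isolates
the estimator (60 s rests, window extended to cover the full response),
where recovery is exact to <0.1%; the group-level check runs the study
protocol proper and reads the HRF at the channels geometrically covering
the injected patch (post-hoc max-selection would add noise-maximum bias).

## Image reconstruction

Per wavelength, channel OD (from the estimated HRFs or per-block deltas,
converted back through the same Beer-Lambert tables) is inverted with
spatially variant Tikhonov regularization; both alphas are 0.001. As
printed in the source description, the L equation is dimensionally
inconsistent (diag(AA^T) is channel-indexed while L must be
vertex-indexed); this package implements the standard spatially variant
form L_ii = sqrt((A^T A)_ii + lambda_spatial) and reads the measurement
lambda as the scalar alpha_meas x max(diag(A_hat A_hat^T)) so that
lambda I is well formed. The solve is a Cholesky factorization of
(A_hat A_hat^T + lambda I), batched over right-hand sides; chromophores
are unmixed per vertex through the 2 x 2 extinction system. Brain+scalp
mode is the default (superficial signal needs somewhere to go); brain-only
mode drops the scalp columns.

Localization and resolution are the intensity-weighted center of mass and
spread, with intensity = |HbO| (metrics on signed images are ill-defined;
a positive-part rule is available). In the point-activation study the
metrics are evaluated on the PSF's half-maximum support: summed over ~800
vertices, sub-1% reconstruction ripple otherwise dominates the weighting
while carrying no localization information — the same reason the
reference sensitivity and activation maps mask sub-threshold vertices.

Under the fixed alpha_meas the HD system (220 rows) has many singular
modes near the regularization floor, which amplify block-delta noise in
vertex space; HD image-space t-statistics therefore run *lower* than
sparse ones even though HD localizes far better. This mirrors the source
finding that the image-space statistical comparison between arrays was
equivocal while localization clearly favored HD.

## Statistics

Block deltas are mean(7..18 s) - mean(-2..0 s) per block; t is mean/SE
across blocks (zero-SE cases flagged as undefined, never infinite).
Group maps use across-subject means and SEs of subject block-average
deltas with per-channel contributing-n, masked at the two-tailed critical
t for the full cohort (2.12 at n = 17). Channel ROIs are the long channels
whose midpoints project onto dlPFC labels (left/right disjoint by
construction); image ROIs are HD-sensitivity-defined vertex sets
(threshold 0.01 x max summed sensitivity, then at-or-above the stage-1
mean) shared by both arrays. Array comparisons are paired Student's
t-tests on per-subject ROI-extreme statistics (highest t for HbO, lowest
for HbR, ties to the lowest index; image space uses the mean of the 25
most extreme ROI vertices); condition contrasts are paired t-tests of
incongruent vs congruent within array. Subjects missing either array are
dropped pairwise.

## Determinism and problem sizes

Every stochastic step derives from one master seed through spawned seed
sequences; reruns are bit-identical. Default problem sizes — 785 + 785
vertices, 60/228 channels, ~10,000-14,000 samples per run, 17 subjects —
keep a full cohort analysis at a few minutes on one CPU while leaving all
operating characteristics (overlap density, conditioning, pruning rates)
in the regimes the comparison exercises.

## Known limitations

* The diffusion surrogate has no skull/CSF layering; absolute
  sensitivities and depth profiles are idealized, and only the relative
  sparse-vs-HD structure should be interpreted.
* The two-compartment pathlength calibration fixes the scalp/brain
  sensitivity ratio at 1.5 for all long channels; real ratios vary with
  separation.
* Image-space t-statistics depend strongly on the fixed regularization
  scale; no attempt is made to tune alpha per array (deliberately — the
  comparison applies one method to both).
* The automated block-rejection surrogate replaces a manual judgment; its
  thresholds are config, not science.
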