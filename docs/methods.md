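# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `retfdc`.

## Pipeline overview

An analysis run maps an OD-centred fundus photograph (plus a manual
optic-disc annotation: centre and diameter in pixels) to per-zone circular
fractal dimensions and, over a cohort, to a rank-test report:

1. **Preprocess** — inverted green channel (vessels bright), square crop of
   side `roi_factor × D_OD` (default 4) centred on the disc, area-averaged
   downsampling to `target_side` (default 400 px).  Coordinates are 0-based
   pixel-centre with half-open extents throughout; annotation geometry is
   rescaled with the image.
2. **Enhance** — Gabor wavelet bank + two-class Gaussian mixture →
   0–255 posterior vessel image.
3. **Scan** — concentric circle profiles, zone labels A/B/C.
4. **Estimate** — per-circle Higuchi FD, zone/combination means (FDC);
   optional whole-image comparators (spectral slope, box counting).
5. **Compare** — Kruskal–Wallis + Mann–Whitney CI per method × zone.

Every stage is deterministic given the run configuration and master seed;
per-image random streams are derived from the seed and a CRC of the subject
id, so cohort outputs are independent of processing order.

## Vessel enhancement

The analysing wavelet is ψ(x) = exp(i k₀·x) exp(−|Ax|²/2) with
A = diag(ε^(−1/2), 1): a complex carrier under an anisotropic Gaussian,
elongated along the filter axis by ε and oscillating across it.  Defaults
follow the matched-filter literature for retinal vessels: scales
{4, 5, 6, 7, 8}, 18 orientations (10° steps over [0°, 180°)), ε = 4,
k₀ = (0, 3).  The transform is evaluated in the frequency domain with
periodic borders; kernels are L1 scale-normalised (spatial form a⁻²ψ(x/a))
so responses are comparable across scales before the later z-normalisation
makes the convention immaterial.  Numerics: the kernel spectrum is real and
compactly supported; tails below 1e−30 are flushed to zero (subnormal
float32 values would stall the FFT) and the row-sparse support is exploited
by splitting the 2D inverse transform into a reduced row pass and a full
column pass.  Responses are computed in single precision; the modulus is
used.

Per scale, the pixelwise maximum over orientations is the feature map; the
inverted-green intensity is appended as an extra feature by default
(`include_intensity_feature`).  Features are z-normalised over the circular
region of interest (radius 2 D_OD), dropping any zero-variance feature with
a warning.

The posterior is an **unsupervised** two-component full-covariance Gaussian
mixture fitted per image by EM (k-means initialisation, ≤100 iterations,
tolerance 1e−6, fixed seed) on a deterministic subsample of 8192 pixels and
evaluated on all pixels (direct Cholesky + log-sum-exp computation of
responsibilities).  The vessel class is, by construction, the component
with the higher mean response at the coarsest scale; the posterior
probability is mapped to integers 0–255.  A supervised classifier trained
on labelled vessel pixels would match the original enhancement recipe more
closely, but no labelled data are assumed here; the mixture keeps the
class-conditional-density semantics without external training data.  If the
fit degenerates (vanishing component weight or numerical failure) the module
falls back to a 2–98 percentile stretch of the coarsest-scale response, with
a warning.

## Circular scanning and zones

Scan radii are integer pixel steps from ⌈R_OD⌉ + 1 (one pixel outside the
disc boundary; a fractional disc radius is rounded up) to 2 D_OD from the
centre — the edge of the 4 D_OD region of interest.  For D_OD = 100 px that
is radii 51..200, i.e. 150 circles, 50 per zone.  Zones are concentric
annuli by margin offset in units of D_OD — A: (0, 0.5], B: (0.5, 1.0],
C: (1.0, 1.5] — half-open, closed on the right, partitioning the circle
set.

Each circle is sampled by bilinear interpolation at equal angular steps of
roughly one pixel of arc, counter-clockwise from angle 0.  The sample count
is `4·round(πr/2)` — the nearest multiple of four to 2πr — so that a 90°
rotation of the image maps sample positions exactly onto sample positions
and each profile undergoes an exact circular shift of N/4.  Bilinear (not
nearest-neighbour) interpolation avoids staircase artefacts that would
inflate the 1D FD; the fixed start angle and direction make outputs
bit-reproducible even though the FD does not depend on them.

## Higuchi FD and the FDC aggregate

For an open series, curve lengths follow the classical construction
(offsets m = 1..k, delays k = 1..k_max) and FD is minus the least-squares
slope of log L(k) on log k.  Defaults: k_max = 8 with all delays in the
fit.  Circle profiles hold ~320–1250 samples, so k_max ≪ N as the length
regression requires; k_max is exposed as a parameter.  Implementation note:
for each delay the offsets' increment sets partition the lag-k difference
array by residue class, so the k curve lengths are computed from one
grouped sum — algebraically identical to the loop form (and tested against
a literal transcription to 1e−12).

Estimates for bounded series lie in [1, 2]; finite-sample estimates
marginally outside are clamped with a warning.  A constant series has zero
curve length and raises an error; constant circle profiles are skipped by
the aggregator and counted.

**Periodic variant for circles.**  A scan circle is a closed path: the
angle at which it is cut into a 1D series is arbitrary.  The open-series
estimator is not invariant to that cut (moving the seam perturbs per-circle
FD by up to ~1e−2 at these lengths), so `fdc` uses a periodic form in which
the normalised length at delay k aggregates all N wraparound lag-k
increments: L(k) = mean_p |X((p+k) mod N) − X(p)| · (N−1)/k².  It differs
from the open form only by O(k/N) boundary terms and is exactly invariant
to circular shifts — hence zone FDC is stable under image rotation to
machine precision.  `higuchi_fd` keeps the open form as its default for
ordinary (non-circular) series.

FDC of a zone combination (A, B, C, AB, AC, BC, ABC) is the arithmetic mean
of per-circle FDs over all circles in the constituent zones; with equal
circle counts per zone, FDC_AB = (FDC_A + FDC_B)/2 exactly.

## Comparators

**Spectral (Fourier) measure.**  The 2D FFT magnitude is averaged over
annuli of integer radial frequency and regressed, log magnitude on log
frequency, over a fit band of 4 cycles/image to 0.45 × Nyquist (below 4
cycles the annuli hold too few coefficients; above 0.45 × Nyquist the
corners make annuli incomplete).  The absolute slope is reported.  No
slope→dimension calibration is imposed; a user-supplied affine map
(offset, scale) is accepted for those who use one.  On images constructed
with radial power spectrum ∝ f^(−β), the fitted magnitude slope is −β/2.

**Box counting.**  Requires a binary structure: the posterior is
thresholded (Otsu by default, or a fixed threshold) and skeletonised by
default, following common practice for vascular box counting; both
switches are exposed since binarisation quality is this comparator's known
weakness.  Box sides are powers of two from 2 to a quarter of the
(power-of-two padded) image side, grid anchored at the origin; FD is the
least-squares slope of log N(s) against log(1/s).  A single foreground
pixel yields FD 0 with a warning.  All three estimators use unweighted
ordinary least squares.

## Rank statistics

The Kruskal–Wallis statistic uses midranks and the tie correction
1 − Σ(t³−t)/(N³−N); per-group z-scores standardise the average rank,
z_j = (R̄_j − (N+1)/2)/√((N+1)(N−n_j)/(12 n_j)); p comes from the χ²
approximation with (groups − 1) degrees of freedom (adequate at the group
sizes considered; tests document the exact-vs-asymptotic gap at very small
n).  If all pooled values are identical, H = 0 and p = 1 with a warning.

The Mann–Whitney CI for the median difference uses the m·n pairwise
differences case − control: the Hodges–Lehmann point estimate is their
median and the CI endpoints are the k-th smallest/largest difference with k
the largest integer such that P(U ≤ k−1) ≤ α/2.  The null U distribution is
computed exactly (rank-sum counting by dynamic programming, cached) for
m·n ≤ 10,000, otherwise by the normal approximation with continuity
correction; the achieved confidence of the exact rank is reported.  The
report applies no multiple-testing correction across the seven zone
combinations by default; a Holm-adjusted column is available via a flag.

## Synthetic data

The phantom generator emulates the acquisition geometry the method
assumes: an OD-centred greyscale frame (default 400 px, D_OD = 100 px, so
the 4 D_OD ROI fills the frame; `image_size ≥ 4 × od_diameter` is
enforced), a bright disc with a soft sigmoidal edge, a mild illumination
gradient and vignetting, additive Gaussian sensor noise (σ = 0.05 on a
[0, 1] scale), and dark vessels as in the green channel.

Vessels grow as branching random walks: `n_trunks` = 6 primary vessels
seeded exactly on the OD boundary at roughly even angles, stepping 1 px at
a time with direction = 0.15 × pull-toward-radial + Gaussian heading jitter
(σ = 6°/step).  At each step a bifurcation occurs with probability
`branch_prob`; children deviate ±20°–40° (uniform) and their half-width
shrinks by `width_decay` = 0.7 from the trunk's `width0` = 3 px, growth
terminating below 0.4 px half-width or at the frame edge.  Centrelines are
rendered as tubes with Gaussian cross-section via a Euclidean distance
transform to the rasterised centreline (profile exp(−d²/2σ²), σ = half
width / 1.2, truncated at 3.5σ); vessel depth is max-combined at crossings
and subtracted from the background with `contrast` = 0.35.

Case/control cohorts differ **only** in complexity parameters: the default
pair halves the bifurcation probability in cases (0.05 vs 0.10), modelling
rarefaction while holding contrast, noise, calibre and trunk count fixed —
so any group difference the pipeline detects is attributable to branching
complexity, the quantity FDC claims to measure.  All random streams derive
from one master seed via `numpy.random.SeedSequence` spawning.

Fixture generators with analytically known answers back the estimator
tests: fractional Brownian motion by exact circulant embedding
(Davies–Harte; Cholesky fallback at small n), whose graph has dimension
2 − H and increment variance k^(2H); Sierpinski rasters with 3^order
foreground pixels and similarity dimension log 3/log 2; and random-phase
images with radial power spectrum ∝ f^(−β).

**What the phantoms do not capture:** photographic colour and texture,
pathology (haemorrhages, exudates), arteriole/venule distinction, vessel
curvature statistics of real retinas, OD rim detail, and realistic
illumination fields.  Absolute FDC values on phantoms (~1.2–1.4) are
consequently lower than on real fundus photographs (~1.98): the posterior
of a phantom is much cleaner than that of a photograph.  Passing tests
therefore establish correctness and sensitivity of the *method* —
monotone response to branching complexity, calibration of the statistics —
not clinical effect sizes.

## Test and validation sizes

Validation uses problem sizes chosen to keep the full suite fast while
leaving no estimator property unexercised: series of length 1000–4096 with
10–20 seeds for the 1D estimator; 128–256 px fixtures for the 2D
estimators; 200 replicate null tables (n = 20+20) for type-I error; 500
shift-model replicates (n = 40/39) for CI coverage; and 20 replicate image
cohorts at the clinical group sizes (40 cases vs 39 controls, 400×400) for
end-to-end discrimination.  `scripts/acceptance.py` reruns the same
computations at 5 cohort replicates.

## Known limitations

- The enhancement posterior is unsupervised; images whose feature
  distribution is not well described by two Gaussian classes can yield
  noisy posteriors (the percentile fallback guards only hard failures).
- FDC is blind to vessel type (artery vs vein) and to calibre as such.
- The spectral comparator reports a raw slope, not a calibrated dimension.
- Box counting inherits the usual sensitivity to thresholding and
  skeletonisation choices.
- The OD annotation is an input; no automatic disc detection is provided.
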