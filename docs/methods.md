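# Methods

## The measurement

`smdol` estimates the degree of labeling (DOL) of a protein tag — the
fraction of tag molecules that actually carry their fluorescent
substrate — by single-molecule colocalization in dual-channel,
diffraction-limited TIRF images. A membrane-anchored probe carries a
reference fluorophore (eGFP-like, present on essentially every copy) and
the tag of interest; every reference localization marks one probe, and
the fraction of reference localizations with a matched target-channel
localization measures labeling completeness. Four signal classes exist
in such data: specifically labeled probes (both channels), probes
without a matured reference, unlabeled probes (reference only), and
unspecific target binding. The pipeline quantifies the first and last
classes per cell.

The chain per experiment (one labeling condition, several cells):

1. average the recorded frames per channel;
2. segment the cell footprint from the reference channel;
3. detect and fit single-molecule localizations in both channels,
   filter by PSF width, keep in-mask localizations;
4. estimate the chromatic affine transform per cell, pool the estimates
   that pass quality gates into one global transform;
5. compute the colocalization-distance curve, pooled over cells, and
   read off the optimal cutoff T;
6. convert each cell's colocalization fraction into a DOL through a
   density-dependent recall calibration derived from simulations;
7. report per-cell DOL and unspecific label density, and the
   experiment's median ± s.d.

## Colocalization statistics

For a tolerance t, the specific colocalization fraction is
F_c(t) = (number of one-to-one reference–target pairs with distance
Δd ≤ t) / (number of reference localizations), and F_r(t) is the same
quantity after rotating the target localizations by 90° about the frame
centre — a null that destroys correspondence while preserving density.
The cutoff T is the smallest tolerance maximising z(t) = F_c(t) −
F_r(t); per-image pair counts are pooled across an experiment's cells
before the argmax (a count-weighted aggregate, not a mean of
fractions). Normalising both fractions by the reference count makes
F_c(T) directly the degree of colocalization (DOC) used downstream; the
alternative normalisation (pairs at the largest tolerance) is available
via `ColocSettings.normalization`, and per-image cutoffs via
`cutoff_scope`.

Matching is the exact optimal one-to-one assignment: among all pairings
that use only distances within tolerance, maximise the pair count, then
minimise the total distance (Hungarian algorithm; forbidden pairs carry
a cost larger than any achievable total, so cardinality dominates). An
ascending-distance greedy rule is simpler but provably disagrees with
this optimum on a noticeable fraction of random configurations.

## Degree-of-labeling correction

At finite emitter density the pipeline misses a density-dependent
fraction of colocalization events (overlapping PSFs, merged detections,
assignment near the cutoff). The recall — measured specific
colocalization divided by the true labeled fraction — falls
approximately linearly with density over the working range, so the
correction is a straight line fitted on simulated data processed with
exactly the same settings as real data:

    DOL = specific colocalization / (cf_slope · ρ_measured + cf_offset)

with ρ_measured = reference localizations per µm² of cell mask (the
quantity also available on real data). Two details matter:

- The numerator is the *specific* colocalization, DOC minus the cell's
  own measured random-colocalization fraction F_r(T) (from the rotated
  null). Chance matches inflate DOC in proportion to the number of
  *unlabeled* references times the target density, so conditions with
  low and high labeling would otherwise be corrected inconsistently.
  The same specific quantity is used when fitting the calibration line,
  so the two stages cancel each other's chance component.
- Calibration cells are scored against their *realized* labeled
  fraction (the simulation's ground truth), not the nominal labeling
  probability, and the regression weights each cell by √(reference
  count). Both choices remove small-sample binomial noise that would
  otherwise propagate into the fitted intercept and bias every
  corrected value by several percent.

A calibration is stamped with a hash of the analysis settings; applying
it under different settings warns, because the correction factors are
fitter-specific by construction. The corrected DOL is clipped to
[0, 1.5] with a warning above 1.

## Spot detection and fitting

Detection: difference-of-Gaussians band-pass (1 px / 2 px), threshold
at 4 robust noise SDs, local maxima with a 3-px non-maximum suppression
(window-wide suppression would merge resolvable emitters a few px
apart; duplicates from overlapping windows are removed after fitting
instead). The noise SD is estimated from deviations *below* the median
only: a plain MAD inflates with emitter coverage at 0.5 emitters/µm²
and would raise the threshold exactly where dim emitters are most at
risk.

Fitting: pixel-integrated (erf) symmetric Gaussian plus constant
background over a 9×9 px window, all windows of an image fitted
simultaneously by a batched Levenberg–Marquardt loop. Residuals are
weighted by an inverse per-pixel noise model (background variance from
the window border plus the shot term of the signal, scaled by the
number of averaged frames). The pixel-integrated model and the noise
weighting are not cosmetic: with a point-sampled unweighted model, the
multi-emitter selection systematically split bright single molecules,
silently corrupting the colocalization denominator.

Windows whose single fit looks contaminated (width > 1.15× the image's
modal width, or weighted residual > 2× the median) are re-fitted with
shared-width multi-emitter models (up to 3, the usual multi-emitter
fitting cap). Each added emitter must pass an extra-sum-of-squares
F-test at the 0.1% level (critical value 6.2 ≈ F(3, 70) at 0.999) —
strict on purpose: a false split turns one molecule into two, while a
missed split is absorbed by the density correction. Model components
closer than 1 px are rejected as sub-resolution ghosts; fitted
positions are converted to nm exactly once here (pixel centre at
(index + 0.5)·pixel size). A photometric floor (fitted peak ≥ 3 noise
SDs) removes noise-cluster fits, and duplicates within 1 px keep the
brighter record.

PSF-width filter: localizations with fitted sigma outside ±50% of the
modal width are removed; the mode comes from a histogram with bin width
5% of the median (a histogram, not a KDE, for determinism).

## Registration

Per cell, mutual-nearest-neighbour pairs feed an iterative
closest-point affine estimate. Matching is annealed coarse-to-fine
(starting radius 25 px, shrinking to the configured 500 nm) because the
quality gates admit transforms that displace far-from-centre points by
microns; each fit is trimmed once of residual outliers (> 3× median).
Coordinates are centred before the least-squares solve; decomposition
into shift/rotation/scales assumes zero shear and round-trips within
1e-6 for shear-free transforms.

Quality gates follow the field's standard thresholds: at least 50
emitters in both channels, shift ≤ 3 px, |rotation| ≤ 5°, scale
deviation ≤ 5%; exclusion is strict (a result exactly at a threshold
passes; a 1e-9 guard keeps boundary cases from floating-point
round-off). Accepted per-cell transforms are averaged on the decomposed
parameters and recomposed. If no cell passes (sparse conditions never
reach 50 emitters per image), one estimate from localizations pooled
across all cells is tried under the same gates before falling back to
the identity with a warning; the fallback is recorded as an
informational flag but does not exclude cells, because the data-driven
cutoff T widens to absorb an uncorrected chromatic shift.

## Segmentation

Background subtraction (Gaussian at 3× the high sigma), DoG band-pass
with defaults low = 4 px / high = 64 px, Otsu threshold, closing
(distance-transform implementation, radius 8 px), hole filling, removal
of components below 20 µm². The pass-band deliberately includes the
cell-body scale: the automatic threshold keys on the diffuse cellular
fluorescence with single molecules riding on top, so the footprint is
found even when only a handful of probes are present. A contrast guard
(foreground must separate from background by ≥ 4 robust SDs) makes
noise-only images report "no cell found" instead of an Otsu split of
pure noise. DOC and density are ratios over the same mask, so moderate
over- or under-segmentation does not bias them.

## The synthetic-data generator

The generator emulates the study conditions end to end so that every
stage is testable against ground truth:

- irregular, simply connected cell footprint (star-convex
  random-Fourier boundary) covering 35% of a 256×256 px frame at
  160 nm pixel pitch;
- membrane probes placed uniformly in the footprint at 0.01–1 /µm²
  (Poisson count), each carrying the target label with probability
  equal to the true DOL; unspecific target-only emitters uniform over
  the frame (default 0.03/µm²);
- target-channel photophysics with unitless mean on/off dwell times
  0.025/0.01 (per-frame visibility = duty cycle 0.714), a
  whole-acquisition bleaching probability of 0.2, and 350 emitted
  photons/s; the reference channel renders with duty 1 and no bleaching
  (a nearly background-free, photostable reference);
- pixel-integrated Gaussian PSFs (σ 140 nm reference / 170 nm target,
  reflecting the emission wavelengths), camera model with Poisson shot
  noise, gain, offset, read noise and quantum efficiency, 15 frames
  averaged (within the 10–20 typical for such acquisitions);
- background 5 detected photons/px/frame plus 3 diffuse photons inside
  the cell in the reference channel (out-of-focus and membrane-proximal
  fluorescence — the feature segmentation keys on);
- a chromatic affine offset applied to target coordinates: (110, −70)
  nm shift, 0.15° rotation, 1.002 isotropic scale — sub-pixel and
  within the registration gates, as for a reasonably aligned two-camera
  or split-view system.

Blinking is modelled as an independent per-frame Bernoulli rather than
a correlated telegraph process: frames are averaged downstream, so
temporal correlation is immaterial to the averaged image. The bleaching
constant is unitless in its source; here its timescale is pinned to the
whole acquisition (per-frame hazard = constant / n_frames). What the
generator does not emulate — and what passing tests therefore do not
establish for real data — includes non-Gaussian/astigmatic PSFs, stage
drift, sCMOS pixel-dependent noise, structured (vesicular) background,
probe clustering or aggregation, and day-to-day variation in chromatic
aberration.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds; per-cell seeds are
  spawned deterministically from a master seed. Every operation is a
  pure function of (inputs, seed).
- Tolerance grid for T: 0–500 nm in 10 nm steps (about twice the
  diffraction limit, since aberrations can push T beyond it); argmax
  ties resolve to the smallest t, which minimises random matches.
- Localization tables always carry nm; masks are 8-bit TIFF (0/255);
  CSV writers use fixed 6-decimal formatting so identical inputs give
  byte-identical files and round-trips are lossless to 1e-3 nm.
- Flat or contrast-free images yield "no cell found" flags; empty
  localization sets propagate as empty (never silently as zeros);
  summaries over zero unflagged cells raise.
- Cells with failed segmentation or fewer than 20 reference
  localizations are flagged and excluded from summaries; the summary
  headline is median ± s.d. with the mean also reported.

## Validation and problem sizes

The central property is parameter recovery: across true DOL
{0.1, 0.3, 0.5, 0.7, 0.9} × probe density {0.05, 0.2, 0.5}/µm², 20
simulated cells per condition at 256×256 px, the median recovered DOL
stays within 0.05 of truth in every condition (the recall calibration
uses 6 replicate cells at 5 densities). Supporting checks: a null
experiment with unrelated target signal shows z(t) within binomial
noise of zero; the matcher agrees with exhaustive assignment on 1,000
random instances; known chromatic transforms are recovered to 0.1 px /
0.1° / 0.005 scale under 10 nm jitter; unspecific density is recovered
within Poisson error; and the PSF-width filter retains 80 ± 3% of an
80/20 width mixture. These sizes keep the whole validation suite at a
few minutes on a single core while leaving the statistical bounds
meaningful.

## Known limitations

- The recall line is calibrated at one labeling fraction (0.5); its
  density slope is assumed labeling-independent. The chance-match
  subtraction removes the leading labeling-dependent term, but a small
  residual bias (~0.03–0.05) remains at the most extreme corner
  (DOL 0.9 at 0.5/µm²), where target-channel crowding differs most
  from the calibration condition.
- Emitters closer than ~1.5 px (240 nm) are generally reported as one
  localization; the density correction absorbs the average effect, not
  per-cell fluctuations.
- The affine model cannot represent non-linear (field-dependent)
  chromatic distortion; the registration QC gates bound, but do not
  remove, such residuals.
- The reference dark fraction (immature eGFP) defaults to 0; a nonzero
  value lowers the reference count but not the DOL estimate, which is
  conditioned on detected references.
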