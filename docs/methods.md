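# Methods

## Scope and data model

`rosettrack` processes directories of time-stamped top-view RGB frames of a
pot flat (JPEG/PNG, 8-bit per channel), a per-flat pot-coordinate CSV, a
per-plant stage-annotation CSV (times of developmental stages 1.04 and 1.10),
and a genotype assignment table. All channel intensities are 8-bit values
divided by 255; every model constant is interpreted on that [0, 1] scale.
Timestamps are parsed from a configurable filename pattern
(`YYYYmmdd-HHMMSS` by default) with EXIF `DateTimeOriginal` as fallback, so
synthetic fixtures are self-contained. Day index k is the calendar-date rank
inside the analysis window, starting at 1; ties in time break by filename.

## Detection model

The color filter and threshold equations and all their coefficients are
given in the README. Decisions the equations leave open, and how this
implementation resolves them:

- **RB mixture weights.** The red/blue mean entering the filter is weighted
  0.5/0.5 by default. The weighting is exposed in `FilterParams.rb_weights`
  (config keys `rb_weight_red`/`rb_weight_blue`); results with strongly
  blue-reflective scenes may be sensitive to this choice.
- **Blue-weight clamping.** D = 0.35(50000 − A)/50000 goes negative past
  50,000 px. Since the correction exists only because pot edges contaminate
  small plants, D is clamped to [0, 0.35].
- **Raw filter scale.** Filtered intensities are not clipped to [0, 1];
  thresholds operate on the raw affine scale.
- **Boundary convention.** Pixels with filtered intensity ≥ T are foreground
  (the model's statement sets pixels *below* T to background).
- **Watershed semantics.** The original tooling's `tolerance`/`extension`
  are mapped to (h-maxima depth on the Euclidean distance map, seed-merge
  dilation radius) over scikit-image/scipy primitives. This is an
  approximation of the original implementation, validated by the property
  that labeling coincides exactly with plain connected components whenever
  objects are separated by background gaps wider than the extension — not by
  bit-compatibility. Foreground objects are 8-connected.
- **Perimeter** is the boundary-pixel count (object pixels with a
  4-neighbour outside the object; image border counts as outside). The
  area/perimeter ≥ 1.5 noise clause only needs a consistent definition.
- **Radius** is the maximum distance from the unweighted mask centroid to a
  boundary-pixel center, plus 0.5 px, so that a rasterized disk's circular
  area covers its own pixel count and compactness of a disk sits just below
  1 (≈ 0.95 at r = 20, approaching 1 with size). Configurable via
  `radius_padding`. For degenerate masks below the pruning scale (~30 px)
  the padded radius can undershoot and compactness may exceed 1; such
  objects never survive pruning.
- **Noon re-processing.** The noon frame's pass-1 area (offset-free filter,
  noon threshold) feeds the daily state; the frame is then re-processed with
  the intra-day formulas alongside its siblings so the trait series has one
  definition per frame.
- **Empty noon detection** records A_k = 0 with a warning rather than
  carrying the previous area forward — visible in QC instead of silently
  masked (`carry_forward_on_empty` flips this). Missing days are allowed;
  the noon anchor is the most recent available day's area.

## Threshold calibration

The original coefficients were tuned manually against visual overlays. The
calibrator makes that procedure quantitative: a staged grid search that fits
the intercept C1 on early-stage frames (smallest area anchors, default the
lowest quartile), then the area coefficient C3 with C1 fixed, then the light
coefficient C2 with both fixed, sweeping the stages to convergence (max 5
sweeps). The objective is the mean per-frame pixel symmetric difference
between the threshold mask and a ground-truth mask, normalized by truth
area; ties take the first-best point in grid order, making the result
deterministic. Seasons present in the training set get separate C1 fits.

## Day/night separation

Frames are scored by mean (G − R). Classification always takes an explicit
operator cutoff (the original procedure also fixed it by inspection); a
companion `suggest_cutoff` proposes the midpoint of the two cluster means
under the variance-minimizing two-class split of the scores (Otsu-style,
exact over splits) and raises "no bimodality" on near-constant series.

## Developmental-time normalization

Relative time is the linear map sending a plant's stage-1.04 anchor to 0 and
its stage-1.10 anchor to 1. Stage anchors are *inputs* (CSV): visual staging
of leaves is out of scope, and the generator provides true anchors for
synthetic plants. Only noon frames enter curve fitting. The spline is a
cubic smoothing spline with stiffness chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); with exactly four points (the
minimum accepted) an interpolating cubic spline is used instead, and that
variant is also selectable (`spline = interpolating`). Curves are resampled
on a uniform grid of M = 101 relative times; grid points outside a plant's
observed range are left missing — no extrapolation. Duplicate abscissae are
averaged before fitting.

## Quantitative genetics

Heritability at each grid point comes from a one-way random-effects model
fitted by REML (`statsmodels` MixedLM, genotype random intercept);
variance components are truncated at zero before forming
H² = σ²G/(σ²G + σ²E). The boundary case of zero within-genotype variance,
where iterative REML cannot converge, is detected and returns H² = 1 with
σ²E = 0. The model contains genotype only — no flat or shelf terms. The
estimator is invariant to affine rescaling of the trait.

The variance partition is a multifactorial OLS ANOVA with all two- and
three-way interactions of environment, development (categorical stage) and
genotype, using sequential (type I) sums of squares in that term order —
on balanced designs sequential and marginal SS coincide, but the choice is
material for unbalanced data and is therefore fixed and documented. Percent
variance per term is SS_term / SS_total × 100, so terms plus residual sum
to 100 by construction; p-values come from the F tests.

## Synthetic scenes: what they emulate and what they do not

The generator renders flats with: soil of near-equal green and red (slightly
green-tinted at ~G − R ≈ 0.08 at full brightness, consistent with a camera
color space tuned toward green), bright perlite speckles and darker
vermiculite patches, blue pot-edge grid lines, rosettes drawn as unions of
rotated elliptical leaves placed at golden-angle increments with fixed
per-plant angular jitter (leaf identity is stable across frames), a diurnal
brightness curve peaking at midday with a configurable floor at the day
edges, a seasonal brightness multiplier (summer ≈ +8%), and dim,
green-shifted night frames emulating green LED illumination (mean G − R ≈
0.02 versus ≥ 0.055 in daylight, so the two populations are separable by the
suggested cutoff). Frames are written as JPEG quality 95 with 4:4:4
subsampling, so chroma smear does not dominate the area error of small
rosettes. Rendering is deterministic given the seed; per-frame sensor noise
uses child seeds keyed by frame index.

Rosette area follows a per-plant logistic curve; the drawn leaf union is
rescaled (exact geometric scaling plus one correction pass) to track the
target area within ~2%. Leaf count grows linearly in time; stage truth
T1.04/T1.10 is defined from the leaf count crossing 4 and 10 (a proxy for
the 10-px leaf-length criterion; T1.04 = start of the crossing day, T1.10 =
end of its crossing day). Growth rates are `base_rate + g + e` with genotype
and residual effects drawn to hit a target heritability exactly in variance;
leaf-initiation speed scales with the rate. Default study conditions follow
the original designs where stated: 6×6-pot flats, 20-minute frame intervals,
a 5-accession × 5-replicate training design, a 1,000-px day-one area prior,
mature rosettes large enough (default asymptote 30,000 px, pot 256 px) to
exercise both noise-pruning branches and the blue-weight clamp. Where no
value was stated (logistic rate 0.75/day with 6% total CV, 1.3 leaves/day,
colors above), values were chosen once as chamber-realistic and are exposed
in `SceneSpec`/`GrowthModel`.

Limits: leaves are ellipses — no twisting, overlap modeling, or diurnal
hyponasty; night frames carry no usable signal by design; illumination is
spatially uniform, so the per-plant positional reflectance variation the
threshold model also absorbs in real chambers is not exercised. Passing
tests therefore demonstrate that the implementation realizes the model
faithfully and recovers truth under the model's own assumptions, not that
the published coefficients are optimal for any particular chamber.

## Problem sizes used in the shipped tests

End-to-end checks run on 3×3-pot flats (192-px pots, 6 days at 2-h
intervals, asymptote 12,000 px) — large enough for rosettes ≥ 500 px, both
day/night classes, and ≥ 4 noon points inside every stage window. The
integration run uses 5 days at 10 frames/day. The `[simulate]` config
section likewise defaults to a small demo scene (3×3 pots); the full-scale
chamber emulation (6×6 pots, 256-px pots, 30,000-px asymptote, 20-minute
intervals) lives in the `SceneSpec`/`GrowthModel` library defaults.
Heritability recovery uses 100
Monte-Carlo populations at 50 genotypes × 10 replicates (and the 5 × 5
training scale), on the generator's true trait values, isolating the
estimator from segmentation noise. These sizes are the package's own test
design and are all configurable.

## Workflow

Stages (`simulate`, `preprocess`, `detect`, `normalize`, `genetics`; `traits`
is an alias of `detect`, since per-frame detection and trait extraction are
one loop) read and write under a base directory and record a manifest entry:
an identity hash over the stage's config sections plus the upstream stage's
output hash, and the list of outputs. Re-runs skip stages whose identity is
unchanged and whose outputs exist; changing a parameter re-runs exactly the
stages downstream of it; `--force` overrides. The config file is plain
key-value with sections; unknown sections or keys are rejected, and the
defaults reproduce the published constants exactly.
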