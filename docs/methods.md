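# Methods

## Input model and coordinate conventions

The atomic observation is one vowel token's midsagittal tongue contour,
given as 11 ordered landmarks ("knots") in mm: knot 1 at the vallecula
(posterior), knots 2–3 on the tongue root, knots 5–7 on the tongue dorsum,
knot 11 on the tongue tip, with two of the eleven knots packed into the
tip/blade region and the other nine spaced evenly along the surface.
Coordinates are assumed occlusal-plane rotated: x increases anteriorly,
y superiorly, with a per-speaker arbitrary origin.  `rotate_to_occlusal`
applies the rigid rotation by the negative of a supplied occlusal angle
(counter-clockwise positive, about the coordinate origin); the acquisition
software's own sign convention is not knowable from the data, so the angle
is taken as given and this convention is documented rather than guessed.
All downstream measures are translation-sensitive unless stated otherwise;
within-speaker z-scoring removes the origin where cross-speaker statistics
need it.  Inputs are assumed already reduced to one frame per token (the
acoustic-midpoint frame); tables carrying extra landmark points (hyoid,
mandible, short tendon) can simply omit them, since no measure uses them.

## The dense contour

x(t) and y(t) are interpolated independently by natural cubic splines
against a shared monotone parameter t = cumulative chord length of the 11
knots, then evaluated on a 100-point grid that always contains the 11 knot
parameters (the remaining 89 points are spread across the ten inter-knot
segments proportionally to chord length, largest-remainder rounding).
Chord-length parameterization is used rather than knot index because the
two extra tip/blade knots crowd the anterior end; an index parameterization
would artificially slow the curve there.  Interpolation (not smoothing
approximation) guarantees the curve passes through every knot, so the
knot-coordinate measures and the contour-derived measures refer to the same
surface.  Coincident consecutive knots (zero chord) are a hard error.

## Measures

* **HP** — the dense-contour point with maximal y; ties break to the most
  posterior point.  A config switch (`hp_knot_range`) can restrict the
  search to a knot-index window (e.g. dorsum-only); the default searches
  the whole contour, which is also what the evaluation strands use.
* **HV** — the dense-contour point with maximal perpendicular distance to
  the chord AB (A = knot 1, B = knot 11).  The triangle quantities AB, AD,
  DB, HVD are all chord-relative, hence invariant under rigid motion.
  A chord shorter than 1e-6 mm is a hard error (degenerate contour).
* **TCP = HVD/AB, TC = AD/DB.**  If HVD < 1e-6 mm (flat contour) then
  TCP = 0 and TC = NaN with a degeneracy flag; an apex exactly at the tip
  (DB = 0) gives TC = +inf with the flag.  NaN/inf TC tokens are dropped
  pairwise downstream with a logged count, so the 64-combination
  bookkeeping is unaffected.  The two curvature-ratio names are sometimes
  swapped in the literature; `TongueMeasureExtractor(name_aliases=...)`
  relabels columns without touching the math.
* **MCI** — the contour is resampled at 100 points equally spaced in
  cumulative arc length (natural splines of x and y against arc length),
  derivatives are estimated by central finite differences (one-sided at the
  ends), signed curvature κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2}, and |κ| is
  integrated by the trapezoid rule.  The result is the total absolute
  turning in radians: a circular arc of subtended angle θ gives MCI → θ
  (within 2% at 100 points for θ ∈ [π/6, π]), a straight line gives 0.
  MCI, TCP and TC are invariant under rigid motion and uniform scaling;
  HP_Y is deliberately not (it is bound to the occlusal frame).

## Ordination baseline and Procrustes ranking

Per speaker, each token contributes a 22-dim vector (11 x's then 11 y's);
pairwise Euclidean distances feed a 2-D MDS.  The default variant is
non-metric (Kruskal stress-1): SMACOF with one start at the classical
(principal-coordinate) solution plus 20 random starts, keeping the lowest
final stress-1.  Stress-1 is computed in-package by isotonic regression of
configuration distances on input dissimilarities, so the classical variant
(available by config) is summarized on the same scale.  Because non-metric
solutions carry arbitrary scale, the retained configuration is least-squares
rescaled onto the input distances and then PCA-rotated so MDS1 carries the
larger variance.  Fitting is deterministic given the seed; in practice the
classical start nearly always wins, so the random-start count mainly guards
against degenerate classical solutions.

Each measure pair forms a tokens × 2 physical configuration per speaker
(raw mm — the superimposition absorbs scale), which is fitted to that
speaker's MDS coordinates by ordinary Procrustes analysis via the standard
SVD solution.  Defaults: symmetric normalization ON (both configurations
centered and scaled to unit root-sum-of-squares, so the residual ss lies in
[0, 1] and is symmetric in its arguments) and reflections allowed (MDS axes
have arbitrary orientation).  A speaker with fewer than 3 valid tokens for
a pair is skipped for that pair with a log message.  The 64 pairs are
ranked by ss averaged over speakers.

## Speaker-held-out classification and the error model

Measures are z-scored within speaker (sample sd, n−1 denominator;
zero-variance cells emit zeros with a warning).  Per replicate,
⌊0.75·S⌋ speakers are drawn without replacement for training and the rest
test; a Fisher/Gaussian linear discriminant with empirical class priors is
fitted on the two scaled measures and evaluated on the pooled held-out
trials; 100 replicates by default.  The same split sequence is reused for
every measure pair (common random numbers), so ranking differences are not
split-noise artifacts.  A replicate whose training speakers miss a vowel
class is re-drawn (at most 10 times, logged).  Accuracy is correct trials
over total trials per replicate, averaged over replicates.

Per-trial errors feed a Bernoulli mixed-effects logistic regression with
one fixed-effect cell per vowel × position-measure and per vowel ×
height/shape-measure combination (no separate intercept) and random
intercepts for speaker and for the resampling replicate ("trial" — the
replicate interpretation is configurable by column name, since token-level
grouping is the other defensible reading).  The model is fitted by
variational Bayes (statsmodels `BinomialBayesMixedGLM`); the weak normal
prior on the fixed effects acts as a mild ridge, which also handles
complete separation gracefully.  Simulation shows an injected +1.0 log-odds
cell effect is recovered within ±0.2 at 20,000 trials; VB shrinks the
random-intercept sds somewhat, which is a known property of the
approximation and does not bias the fixed-effect contrasts of interest.
In the full pipeline the model is fitted on the pooled per-trial records of
all 64 pairs, subsampled (seeded) to at most 200,000 trials — the pooled
records can run to millions of rows, far beyond what the coefficients need.

## Correlation analysis

All values (measures and formants) are within-speaker scaled and reduced to
by-speaker by-item means ("item" = the five word types), which damps
token-level autocorrelation; at 40 speakers × 5 items this yields up to 200
rows per variable.  Pearson coefficients are pairwise-complete (NaN TC rows
drop per pair, with per-cell n reported).  Raw coefficients are reported;
no significance tests and hence no multiple-testing correction.  Measure ×
formant tables (16 rows each for F1 and F2) are ranked by |r|.

## The synthetic cohort

The generator emulates the study design (40 speakers × 5 lax vowels × 4–6
repetitions) with deliberately minimal geometry — rich enough to produce
the qualitative phenomena the evaluation must face, simple enough for
closed-form latents:

* **Surface** — a vertically flattened circle segment (radius 35 mm,
  flatten 0.55, posterior→anterior), plus a Gaussian radial bump of height
  `degree_mm` (the constriction) at arc location θc, plus a root-advancement
  shear on the posterior third, plus whole-body advancement of
  8 mm/rad × (1.5 − θc).  The five default vowels have strictly ordered
  constriction locations (bid most anterior … bod most posterior) spanning
  θc ∈ [1.20, 1.80] rad — lax vowels are articulatorily close — with
  constriction degrees 8.0/6.0/1.2/4.5/6.5 mm (bad nearly flat).
* **Coda coarticulation** — a second, anterior ridge of random per-token
  height (mean 1.2, sd 0.8 mm, at 93% of the arc) mimics tongue-tip raising
  into a following /d/; combined with the flat low vowel this destabilizes
  the highest-point measures exactly the way real flat tongue shapes do.
* **Noise** — per-speaker similarity transform (scale 0.85–1.15,
  translation ±8 mm), per-token probe-rotation jitter (sd 2°, about the
  contour centroid), per-token articulation jitter on θc (sd 0.10 rad) and
  degree (sd 0.5 mm), and per-knot Gaussian landmark noise (sd 1.0 mm,
  inflated up to 1.6× toward the vallecula, where ultrasound imaging is
  poorest).  Defaults were chosen once so that held-out LDA accuracy of the
  best pair lands between chance and ceiling (~0.5–0.8), keeping the
  rankings informative.
* **Formants** — F2 = 2450 − 700·θc + N(0, 60) Hz (front vowels high F2)
  and F1 = 1900 − 60·h + N(0, 40) Hz, where h is the noiseless canonical
  apex height in mm (high vowels low F1); F2 is floored just above F1,
  since adjacent resonances cannot cross.

Every latent is recorded per token in a ground-truth table, and identical
config + seed reproduces the dataset bit for bit.

What the cohort does *not* emulate: biomechanics and muscle synergies,
token-level formant nonlinearities (back-cavity effects in low vowels),
carrier-phrase or repetition-order effects, DLC tracking failures beyond
i.i.d. landmark noise, and real anatomical diversity beyond similarity
transforms.  Passing end-to-end tests therefore shows the pipeline recovers
known structure under realistic noise magnitudes — not that any particular
measure ranking will transfer to real data.

## Numerical choices and degenerate inputs

Tolerances: flat-contour threshold 1e-6 mm; degenerate-chord threshold
1e-6 mm; rigid-motion assertions at 1e-9 mm; MCI invariance at 1e-3
(finite-difference discretization).  Ties in argmax searches break to the
most posterior point.  MDS needs ≥ 5 tokens and ≥ 3 distinct
configurations; Procrustes needs ≥ 3 points and a non-degenerate source.
Sorting is stable (mergesort) everywhere a ranking is emitted, so equal
values keep a deterministic order.

## Problem sizes used in the checked runs

The test suite exercises the full 40-speaker default cohort for the
end-to-end recoveries, with 2 random MDS starts plus the classical start
(the classical start dominates; see above) and short classification sweeps
(3–30 replicates) for bookkeeping and ranking checks; calibration tests use
100 replicates.  `scripts/acceptance.py` runs the default cohort with 8
random MDS starts, the full 100-replicate LDA sweep over all 64 pairs, and
the 20,000-trial error-model recovery.

## Reproducing the published stress summary

`tonguespace.pipeline.reproduce_stress_summary(path)` runs the per-speaker
MDS stress summary (median, upper quartile) on an externally supplied
landmark export in the canonical long dialect, under the declared defaults.
Pointed at the deposited measurements of a comparable 40-speaker ultrasound
study it reproduces that study's stress summary; the bundled tests exercise
the harness on a synthetic export, since no external data ship with the
package.

## Known limitations

* The non-metric stress depends mildly on SMACOF settings (starts,
  convergence threshold); the classical variant is exposed for sensitivity
  checks.
* The VB mixed model understates random-intercept variances; if exact ML
  random-effect estimates matter, export the per-trial CSV and fit
  externally.
* The measure battery is midsagittal-only: no area functions, no
  /i/–/o/ tangent normalizations, no polar dorsum angles, and no dynamic
  (time-varying) measures — tokens are single-frame by assumption.
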