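# tonguespace

Quantifying midsagittal lingual articulation of vowels from landmark tongue
contours.

Ultrasound tongue imaging yields rich midsagittal contours that must be
reduced to a handful of numbers before vowels can be compared across tokens
and speakers — but the field has never agreed on *which* numbers.
`tonguespace` implements a systematic evaluation of 16 candidate measures of
tongue **position**, **height** and **shape**, extracted from 11 anatomical
landmarks ("knots") tracked along the tongue surface (knot 1 = vallecula,
knots 2–3 = tongue root, knots 5–7 = tongue dorsum, knot 11 = tongue tip).
It is aimed at articulatory phoneticians working with DeepLabCut-style
landmark exports of ultrasound (or EMA/MRI) vowel data.

## The measures

Position (8): `K2_X … K7_X` (knot x-coordinates), `HP_X`, `HV_X`.
Height/shape (8): `K5_Y, K6_Y, K7_Y`, `HP_Y`, `HV_Y`, `TCP`, `TC`, `MCI`.

Knot coordinates are read off the occlusal-rotated landmarks.  The rest come
from a 100-point smoothed contour (natural cubic splines of x(t), y(t)
against cumulative chord length, interpolating every knot):

- **HP** (highest point): the contour point with maximal y.
- **HV** (highest vertex): the point farthest from the chord AB joining
  vallecula (A) and tongue tip (B).  With D the foot of the perpendicular
  from HV onto AB:  **TCP = HVD/AB** and **TC = AD/DB**.
- **MCI** (Modified Curvature Index): ∫|κ(s)| ds over the contour — the
  total absolute turning in radians, computed at 100 arc-length-equispaced
  points with central finite differences and trapezoid integration.

## The evaluation

Three strands, each run over all 8 × 8 = 64 position × height/shape pairs:

1. **Ordination baseline** — per speaker, the 22-dim knot vectors are
   reduced to 2-D by non-metric MDS (Kruskal stress-1, SMACOF with a
   classical start), PCA-rotated; each measure pair is superimposed onto
   this reference vowel space by ordinary Procrustes analysis (rotation,
   uniform scale, translation, symmetric normalization) and ranked by the
   residual sum of squares averaged over speakers.
2. **Speaker-held-out classification** — linear discriminant analysis on
   within-speaker z-scored measure pairs, trained on 75% of the speakers
   and tested on the held-out 25%, resampled 100× with common random
   numbers across pairs; per-trial errors feed a Bernoulli mixed-effects
   logistic regression (vowel × measure fixed-effect cells, random
   intercepts for speaker and replicate).
3. **Correlation structure** — within-speaker-scaled, by-speaker by-item
   mean Pearson correlations among measures and against F1/F2.

A synthetic articulatory cohort generator (40 speakers × 5 lax vowels
*bid/bed/bad/bod/bud* × 4–6 repetitions, with known constriction-location,
constriction-degree and root-advancement latents, speaker anatomy and
landmark noise) provides ground truth for testing every stage end to end.

## Worked example

```python
import tonguespace as ts

dataset, truth = ts.generate_cohort(ts.CohortConfig(seed=1))
measures = ts.extract_measures_table(dataset)

ordinations = ts.ordinate_dataset(dataset, random_state=2, n_init=8)
print(ts.stress_summary(ordinations))
# {'n_speakers': 40, 'median': 0.0660..., 'upper_quartile': 0.0787...}

sweep = ts.combo_sweep(measures, ordinations)
print(sweep.head(3)[["position", "height_shape", "mean_ss"]])
#   position height_shape   mean_ss
# 0     K7_X           TC  0.230331
# 1     K7_X          TCP  0.234293
# 2     K7_X         K6_Y  0.251141
```

The stress summary says two MDS dimensions represent each speaker's lingual
vowel contrasts well (stress ≈ 0.05 is conventionally "good"); the sweep
says that, on this cohort, the anterior-dorsum x-coordinate paired with a
curvature measure best reproduces the abstract vowel-space geometry —
smaller `mean_ss` means a closer Procrustes match.  The classification
strand works the same way:

```python
scaled = ts.scale_within_speaker(measures, ts.MEASURE_COLUMNS)
acc, trials = ts.sweep_accuracy(scaled, n_reps=100, seed=3)
print(acc.head(1))          # best pair, mean held-out accuracy ~0.78
```

From a shell, the same pipeline is available as `tonguespace simulate`,
`measures`, `ordinate`, `sweep-procrustes`, `sweep-lda`, `correlate` and
`run-all` (see `tonguespace --help`); `run-all` writes every table plus a
JSON manifest of seeds and token counts for exact reruns.

Real data are read with `ts.read_contours(path, dialect="long"|"wide")`
(long: one row per knot, columns `speaker, token, vowel, repetition, knot,
x, y`; wide: `x1..x11, y1..y11` per row), with strict validation of knot
indices, coordinates and vowel labels.

## Documentation

See `docs/methods.md` for the model and procedure details, the synthetic
cohort's generative assumptions, numerical choices, and known limitations.
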