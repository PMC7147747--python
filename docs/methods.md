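# Methods

This note records the models, conventions and open design choices behind
`drscreen`, and what the synthetic generators do and do not establish.

## Scope

The package implements the decision layer of a DR screening pipeline:
preprocessing, grade remapping and splitting, quality curation, decision
policies over softmax probabilities, metrics, and experiment
orchestration. Training a grading or quality CNN is deliberately out of
scope; both enter only through their outputs (probability vectors;
adequacy scores), for which the synthetic generators provide controllable
stand-ins.

## Contrast enhancement

`enhance_contrast` computes `α·I + β·G(ρ)∗I + γ` in double precision,
then rounds half-up and clips to [0, 255]. The formula leaves several
conventions open; the ones fixed here are:

* ρ is the Gaussian **standard deviation in pixels on the resized
  image**; the kernel is truncated at 4ρ.
* The blur (and the whole formula) is applied **independently per RGB
  channel**, not on luminance.
* Boundary handling is **reflection**, which avoids the dark vignette a
  zero-padded blur would smear inward from the fundus border.
* Rounding is half-up before clipping so outputs are bit-reproducible
  across runs and platforms.

Defaults α=3, β=−3, γ=128, ρ=14, target 600×600. Because α+β=0, the
output of any locally smooth image sits near γ; a spatially constant
image maps exactly to γ.

Cropping (`crop_fundus`) takes the tight bounding box of pixels whose
channel mean exceeds a threshold (default 10/255); no circle fitting is
attempted. A frame with no qualifying pixel is returned unchanged with a
warning flag rather than an error. Resizing is bilinear; interpolation
choice is a convention, not a claim.

## Grade schemes and splitting

Schemes are ordered least→most severe with a designated fallback class
(default: the least severe). Label maps must be total, surjective and
severity-preserving; the two shipped presets collapse the Kaggle EyePACS
grades to {Healthy, Non-referable DR, Referable DR} (counts 65,300 /
19,400 / 4,000 of 88,700) and {Healthy, Diseased} (65,300 / 23,400).
Numeric aliases 0–4 (the Kaggle encoding) are accepted for the source
grades.

Splits are seeded and default to **stratified**, because at 4.5%
prevalence of the most severe class an unstratified 15% test set is
noisy; set sizes use largest-remainder rounding with ties broken in
(train, validation, test) order. The same spec and inputs always produce
the identical partition.

## Decision policies

* **Argmax** breaks exact ties toward the more severe grade — the
  conservative screening choice.
* **Cascading thresholds** are defined for every class except the
  fallback; classes are scanned most-severe-first and the first class
  whose probability meets its threshold wins. Degenerate settings behave
  as expected: all thresholds > 1 gives the constant fallback, all 0
  gives the most severe class always.
* **Margin max** is formalized as: return the most-preferred class whose
  probability is within the margin of the global maximum. This
  reproduces the canonical worked example ((0.30, 0.45, 0.25), margin
  0.2, boosting Healthy → Healthy) and extends to boosting either end of
  the severity scale. The preference order built by
  `MarginMaxPolicy.boosting(cls, ...)` puts the boosted class first and
  the rest by increasing severity-distance from it (ties toward the more
  severe): boosting Healthy yields ascending severity — so outside the
  margin the rule reduces exactly to the argmax — and boosting the most
  severe class yields descending severity. Margin 0 reproduces argmax on
  tie-free vectors; margin 1 returns the boosted class always.

Probability vectors must be non-negative; sums within 1e-6 of one are
accepted, within 1e-3 renormalized with a warning, beyond that rejected.

## Metrics

One-vs-rest reduction per class c: TP = cm[c,c], FN = row − TP,
FP = column − TP, TN = remainder, then the four ratios and F1. **Any zero
denominator yields NaN** (an "undefined" flag in reports) so that small
synthetic sets with absent classes never raise. Accuracy is
trace/total, which equals the prevalence-weighted mean of per-class
sensitivities. In the binary case sensitivity(c0) ≡ specificity(c1) and
PPV(c0) ≡ NPV(c1); published screening tables sometimes print a class's
"specificity" equal to its PPV, which contradicts the standard
true-negative-rate definition — this package follows the definitions, so
its specificity column will differ from such tables. Reports print at 4
decimal places.

## Quality scoring and curation

The baseline scorer is a weighted mean (defaults 0.4 / 0.3 / 0.3) of
three gradability proxies, each in [0, 1]:

* fundus-area fraction: share of pixels above the background threshold;
* sharpness: variance of a discrete Laplacian on the green channel,
  divided by a saturation constant (default 500, the variance level
  treated as fully sharp) and clipped;
* global contrast: interquartile range of pixel intensity / 255.

The weights and saturation constant are toolkit choices, tuned to order
degraded versions of an image below the original (blur, under-exposure
and field-of-view truncation each strictly lower the score on the
synthetic fixtures); the score is not calibrated to expert gradability
judgements, which is why the scorer sits behind a registry where a
learned model can replace it. Curation itself is exact arithmetic:
adequate iff score ≥ threshold; the rejection rate is reported as the
exact ratio rejected/total.

## Synthetic generators

**Probability records.** True grades are drawn from a prevalence vector;
conditional on the grade, the probability vector is Dirichlet with a
per-grade concentration. The class-conditional mean is α/Σα and the
marginal variances follow the Dirichlet, which the statistical-contract
tests check at n = 10⁵ within three standard errors. The shipped
three-class preset uses the screening-set prevalence (0.7362, 0.2187,
0.0451) and concentrations chosen once so plain argmax lands in the
qualitative regime of a real screening CNN — Healthy sensitivity ≈ 0.97,
disease-grade sensitivities ≈ 0.5–0.6 — no numeric agreement with any
published table is claimed or asserted.

**Images.** A centred, radially shaded warm disc on black, with dark
Bézier "vessels", then exposure scaling, Gaussian blur and additive
noise. This supports the geometry (cropping recovers the disc bounding
box), the enhancement invariants, and the quality-score orderings. It
does **not** emulate lesions, optic-disc/macula anatomy, calibration of
a real CNN, or real-image quality statistics — so passing tests show the
pipeline's arithmetic and orderings are right, not that any particular
clinical performance would be achieved on real data.

Both generators are pure functions of their configuration including the
seed.

## Experiment sizes

Tests and the acceptance script run synthetic experiments at
n = 10,000–100,000 records and images of 64–600 px — sizes chosen so the
statistical contracts have three-standard-error resolution while the
whole suite completes in seconds on one CPU.

## Known limitations

* The baseline quality scorer is a heuristic; its absolute scores carry
  no clinical meaning, only its orderings are tested.
* The cascading/margin-max operating points that suit a given program
  depend on the classifier's calibration; the `sweep` operation searches
  a grid against a stated objective (e.g. sensitivity ≥ 0.85) and
  maximizes the same class's specificity among qualifying points,
  preferring the least aggressive parameter on ties — it does not learn
  thresholds.
* ROC/AUC reporting is intentionally absent; the package evaluates
  operating points, not ranking quality.
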