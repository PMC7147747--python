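# drscreen

A decision-rule toolkit for diabetic-retinopathy (DR) screening pipelines.
It covers everything around a DR grading classifier except the classifier
itself: fundus-image preprocessing, remapping clinical grades to screening
schemes, quality-based test-set curation, post-hoc decision policies that
boost sensitivity toward a chosen grade, and the full one-vs-rest
screening-metric suite — with seeded synthetic generators so the whole
pipeline runs and is testable at desk scale, without image archives or a
trained network.

## Who it is for

Groups building or auditing automated DR screening: the classifier's
softmax probabilities come from wherever you like (a CNN, a vendor API, a
simulation); `drscreen` handles the screening-specific decision layer and
its evaluation.

## The methods

**Contrast enhancement.** Fundus photographs are cropped to the retinal
disc, resized to a fixed square (default 600×600), and illumination-
flattened per RGB channel:

    I_c = α·I + β·G(ρ)∗I + γ        (defaults α=3, β=−3, γ=128, ρ=14)

where G(ρ)∗I is Gaussian blur with standard deviation ρ pixels. With
α+β=0 this removes the local mean and re-centres on mid-grey, suppressing
lighting variation while amplifying vessel and lesion contrast.

**Grade remapping.** The Kaggle EyePACS five grades (No/Mild/Moderate/
Severe/Proliferative DR) collapse onto screening schemes via shipped
presets: `kaggle5to3` → {Healthy, Non-referable DR, Referable DR} and
`kaggle5to2` → {Healthy, Diseased}. Splitting into train/validation/test
(default 70/15/15) is seeded, stratified and largest-remainder rounded.

**Decision policies.** Given a probability vector p over grades ordered
by severity:

* *argmax* — the classifier default; ties break toward the more severe
  grade.
* *cascading thresholds* (~, t₁, …) — scan grades from most to least
  severe; the first grade with p ≥ its threshold wins, regardless of less
  severe grades; otherwise the fallback "~" grade. Boosts sensitivity of
  the severe end.
* *margin max* (m) — the most-preferred grade whose probability lies
  within margin m of max(p) wins; boosting Healthy with m=0.2 turns
  (0.30, 0.45, 0.25) into a Healthy call even though Non-referable is the
  maximum. Boosts sensitivity of the preferred grade and, in the binary
  scheme, identically the specificity of the other.

**Metrics.** K×K confusion matrix, then one-vs-rest per class:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN), F1 = 2·PPV·Se/(PPV+Se), plus overall accuracy.
Zero denominators yield an undefined flag, never an exception.

**Quality curation.** A pluggable scorer maps each image to an adequacy
score in [0, 1]; thresholding splits a test set into "curated" (adequate)
and rejected subsets, and experiments re-evaluate identical policies on
both. A heuristic baseline scorer (fundus-area fraction, Laplacian-
variance sharpness, interquartile contrast) is included; a learned scorer
can be registered in its place.

## Worked example

```python
from drscreen import (THREE_CLASS, MarginMaxPolicy, CascadingPolicy,
                      gen_prob_records, screening_preset, run_comparison)

records = gen_prob_records(screening_preset(10_000, seed=42))
policies = [
    MarginMaxPolicy.boosting("Healthy", 0.4, THREE_CLASS),
    CascadingPolicy.uniform(0.3, THREE_CLASS),
]
print(run_comparison(records, policies, THREE_CLASS).to_text())
```

prints (abridged):

```
        Original  Margin Max (0.4) preferring Healthy  Cascading Thresholds (~, 0.3, 0.3)
accuracy                     0.8740  0.7818  0.7741
sensitivity Healthy          0.9746  0.9997  0.7909
sensitivity Referable DR     0.4867  0.1018  0.7611
specificity Referable DR     0.9829  0.9996  0.9508
npv Healthy                  0.9084  0.9966  0.6026
```

Reading it: on 10,000 synthetic screening records (73.6% Healthy, 21.9%
Non-referable, 4.5% Referable), margin-max boosting Healthy lifts Healthy
sensitivity from 0.9746 to 0.9997 and the Healthy NPV to 0.9966 — almost
no diseased eye is called Healthy — at the cost of overall accuracy.
Cascading thresholds (~, 0.3, 0.3) pulls Referable sensitivity from
0.4867 up to 0.7611 instead. The same trade-offs are available from the
command line (`drscreen compare`, `drscreen sweep`, `drscreen
curation-experiment`; see `drscreen --help`).

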