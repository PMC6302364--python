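# triagekit

Selective classification with a refusal budget, for workflows — such as
cancer-registry coding of electronic pathology reports — where a machine
classifier labels the easy items automatically and routes the hard ones to a
human expert.

## The problem and the rule

A classifier that must label every item can do no better than the Bayes
classifier, whose misclassification probability (the Bayes risk) may still
exceed what the application tolerates. A **triage rule** `T` maps each item
to a class label or to a "no classification" token, refusing at most a
fraction ε of items; refusals are not penalized, because a human handles
them. Writing `D` for the set of items the rule labels, the loss is the
*joint* misclassification mass

    L(T) = P[Y ≠ T(X), X ∈ D],    subject to  P[X ∈ D] ≥ 1 − ε.

The loss-minimizing rule has a simple form: label an item exactly when its
winning-class conditional probability `max_k p(a_k | x)` exceeds a threshold
`b` — the largest value keeping coverage at least `1 − ε` — and on the
labeled set emit the Bayes label (ties to the lowest class index). For two
classes this is equivalently a likelihood-ratio band: refuse iff
`1/b' ≤ p(1|x)/p(0|x) ≤ b'` with `b' = b/(1−b)`. The joint loss is
monotone decreasing in ε, so any budget ε > 0 beats the Bayes risk.

In practice the true conditionals are unknown; one thresholds the per-row
maximum of the soft-max scores of an upstream classifier instead. Whenever
the soft-max converges to a *monotone increasing transform* of the true
conditionals (M-consistency), thresholding scores recovers the same decision
set as thresholding the truth.

`triagekit` provides:

- `triagekit.core` — the oracle side: `bayes_classify`, `optimal_triage`
  (fit + decide at budget ε), `triage_loss` (joint loss / precision /
  coverage), and `binary_ratio_band`.
- `triagekit.softmax` — the empirical side: `fit_threshold`, `apply_triage`,
  `precision_coverage_curve`, `threshold_for_precision` (invert the curve
  for a target precision), `class_error_by_count`, and `min_count_filter`
  (refuse classes with too few training examples).
- `triagekit.synthetic` — 1-D Gaussian-mixture generators with exact
  posteriors, exact Bayes risk, and exact population triage risk
  (`sample`, `exact_bayes_risk`, `exact_triage_risk`, `corrupt_scores`).
- `triagekit.io` / the `triagekit` CLI — score-table parsing, rule
  serialization, and `fit` / `apply` / `curve` subcommands.

## Worked example

```python
import numpy as np
from triagekit import (
    two_class_symmetric, exact_bayes_risk, exact_triage_risk,
    sample, corrupt_scores, fit_threshold, apply_triage, triage_loss,
)

model = two_class_symmetric()          # equal priors, means ±1, unit variance
print(round(exact_bayes_risk(model), 4))
b, loss, cov = exact_triage_risk(model, epsilon=0.2)
print(round(b, 4), round(loss, 4), round(cov, 4))

s = sample(model, 10_000, seed=1)      # features, labels, exact posteriors
scores = corrupt_scores(s, ("power", 2.0))   # M-consistent soft-max stand-in
rule = fit_threshold(scores, epsilon=0.2)
result = apply_triage(scores, rule)
out = triage_loss(result, s.true_labels)
print(round(out.joint_loss, 4), round(out.precision, 4), round(out.coverage, 4))
```

prints

```
0.1587
0.6957 0.0788 0.8
0.0795 0.9006 0.8
```

Reading: the Bayes classifier errs on 15.87% of items, but a rule refusing
the 20% of items with the lowest winning-class probability errs on only
7.88% of all items (a precision of about 90% on the 80% it labels); the rule
fitted to monotonically transformed scores on a finite sample of 10,000
lands within Monte-Carlo error of the population values.

From the shell, with a CSV whose header names an id column, one score column
per class, and optionally a `truth` column:

```sh
triagekit fit scores.csv --epsilon 0.2 --rule-out rule.json
triagekit apply scores.csv rule.json --out decisions.csv
triagekit curve scores.csv --out curve.csv
```

`decisions.csv` holds one row per item with the emitted label or the literal
token `REFUSE`; `curve.csv` tabulates precision against the fraction
classified.

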