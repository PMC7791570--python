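# riskitems

Diagnostic accuracy of **individual risk-scale items** for predicting repeat
self-harm within 6 months of a hospital presentation.

People who present to emergency departments after self-harm are at high risk
of repetition, and clinicians widely use risk scales — the Manchester
Self-Harm Rule (MSHR), ReACT Self-Harm Rule, SAD PERSONS and Modified SAD
PERSONS scales, and items from the Barratt Impulsiveness Scale (BIS) — to
stratify that risk. This package implements, as a tested and reusable
pipeline, the head-to-head evaluation of the *items* of those scales against
clinician and patient global ratings: scale scoring, dual and global
diagnostic-accuracy statistics, construction of a new scale from
top-performing items, and a classification-tree sensitivity analysis. Because
patient-level data from such cohorts cannot be shared, the package ships a
synthetic-cohort generator that emulates the relevant statistical structure,
plus a deterministic 483-episode reference cohort whose 2×2 tables are
integer-exact reconstructions of published marginals.

It is aimed at biostatisticians and mental-health services researchers who
want to reproduce, stress-test or extend this style of item-level
diagnostic-accuracy analysis.

## Statistics implemented

For a binary item cross-classified against the repetition outcome
(TP/FP/FN/TN after listwise exclusion of episodes missing that item):

- sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV, NPV,
  LR+ = sens/(1−spec), LR− = (1−sens)/spec, each with 95% CIs
  (Wilson score by default; Clopper–Pearson and Wald selectable; Simel log
  method for likelihood ratios);
- AUC by the Mann–Whitney identity
  AUC = P(X₁ > X₀) + ½·P(X₁ = X₀) for scores X₁, X₀ drawn from the
  outcome-positive/negative classes (equals the trapezoidal area under the
  empirical ROC; for a binary item it reduces to (sens + spec)/2), with a
  Hanley–McNeil interval;
- ordinal Barratt responses (1–4) recoded to binary: 3–4 → 1, designated
  reverse-scored items reflected (r → 5 − r) first;
- 1–10 clinician/patient global ratings dichotomised at the midpoint
  (1–5 low, ≥6 high);
- optimal cutpoints for an additive scale by the Liu criterion
  (maximise sens × spec) or Youden's J (sens + spec − 1), by exhaustive
  threshold search;
- CART: greedy recursive binary partitioning with the Gini impurity
  1 − p² − (1 − p)², no pruning, no stopping rules, no misclassification
  costs.

## Worked example

```python
import riskitems as ri

table = ri.fixture_cohort()            # deterministic 483-episode cohort
tab = ri.two_by_two(table["lifetime_history_self_harm"], table["outcome"])
acc = ri.dual_statistics(tab)
print(tab)
print(f"sens {100*acc.sensitivity:.1f}%  spec {100*acc.specificity:.1f}%")

tab2 = ri.two_by_two(table["prior_psychiatric_treatment"], table["outcome"])
print(f"prior psychiatric treatment AUC {ri.binary_auc(tab2):.2f}")

items = ["lifetime_history_self_harm", "prior_psychiatric_treatment",
         "prev_attempt_or_psych_care", "benzodiazepines", "rational_thinking_loss"]
tree = ri.fit_tree(table, items, params=ri.CartParams(max_depth=1))
cart_acc, cart_auc = ri.tree_accuracy(tree, table)
print(f"CART root: {tree.split_item}  "
      f"sens {100*cart_acc.sensitivity:.1f}%  spec {100*cart_acc.specificity:.1f}%  "
      f"AUC {cart_auc.auc:.2f}")
```

prints

```
TwoByTwo(tp=134, fp=225, fn=11, tn=113, n_excluded=0)
sens 92.4%  spec 33.4%
prior psychiatric treatment AUC 0.65
CART root: prior_psychiatric_treatment  sens 85.5%  spec 45.3%  AUC 0.65
```

The first item ("lifetime history of self-harm") is highly sensitive but
unspecific: it flags 359 of 483 episodes as high risk and still misses 11 of
the 145 repeats. The best single splitting variable for the classification
tree is "prior psychiatric treatment", whose item-level accuracy
(sens 85.5%, spec 45.3%, AUC 0.65) no pooled-item tree or composite scale
meaningfully improves on — the core negative finding this analysis style
demonstrates.

There is also a CLI for the same pipeline:

```bash
riskitems simulate --n 483 --seed 1 --out cohort.csv
riskitems report --input cohort.csv --outdir results/
```

which writes tidy tables (`item_repetition.csv`, `auc.csv`,
`dual_statistics.csv`, `flow_counts.csv`), the constructed scale as YAML, the
fitted tree as JSON, and a `summary.json`.

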