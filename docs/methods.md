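# Methods

## Study design being emulated

The package reproduces an item-level diagnostic-accuracy analysis of
self-harm risk scales in a hospital cohort: consecutive presentations for
self-harm (each treated as an independent index episode), a binary reference
standard of hospital-treated repeat self-harm within 6 months, and as index
tests the individual items of five instruments (MSHR, ReACT, SAD PERSONS,
Modified SAD PERSONS, Barratt Impulsiveness Scale) plus single-question 1–10
clinician and patient ratings. The study scale is 483 episodes with a 30%
repetition rate.

Because episode-level data of this kind are not shareable, every analysis
here runs on synthetic cohorts. Two kinds are provided.

### The deterministic reference cohort

`fixture_cohort()` returns a fixed 483-row table with 145 outcome-positive
episodes and binary item columns whose 2×2 tables are the unique integer
solutions to the published counts and accuracy statistics, for example:

| item | (TP, FP, FN, TN) | implies |
|---|---|---|
| lifetime history of self-harm | (134, 225, 11, 113) | sens 92.4%, spec 33.4%, 359 positive |
| prior psychiatric treatment | (124, 185, 21, 153) | sens 85.5%, spec 45.3%, AUC 0.65 |
| previous attempt or psychiatric care | (124, 186, 21, 152) | sens 85.5%, spec 45.0%, AUC 0.65 |
| benzodiazepine use | (29, 28, 116, 310) | sens 20.0%, spec 91.7% |
| rational-thinking loss | (4, 7, 141, 331) | sens 2.8%, spec 97.9% |

Marginal counts per item are exact; the *joint* arrangement of items across
episodes is a fixed pseudorandom interleaving (the published aggregates do
not constrain it). Statistics that depend only on per-item 2×2 tables — all
dual statistics, binary AUCs, and the root split of the classification
tree — are therefore exact; deeper tree structure depends on the
unconstrained joint arrangement and is not a reconstruction. ReACT item
counts are not reconstructed: the published 32.5% sensitivity for "cutting"
is not an integer multiple of 1/145, so that item's analysed denominator is
unknowable from the aggregates.

A `prior_psychiatric_history` column (310/483, the demographic count) is
kept distinct from the MSHR item `prior_psychiatric_treatment` (309
positive, the integer solution to that item's published accuracy); the
aggregates do not determine whether they were the same variable.

### The stochastic generator

`generate_cohort(CohortConfig(...))` draws the outcome as
Bernoulli(prevalence) per episode and each binary item conditionally on the
outcome, P(item=1 | repeat) = sensitivity and P(item=1 | no repeat) =
1 − specificity. Ordinal Barratt items (1–4) and Likert ratings (1–10) are
drawn from per-class categorical distributions; the shipped rating
distributions are discretised normals calibrated so the binormal AUC matches
the published global-rating accuracy (clinician 0.74, patient 0.71, both at
sd 2.2–2.25 rating points). Missingness is completely at random per cell at
1 − completeness, with completeness floored at 92% (the minimum observed in
the source data) unless explicitly overridden; the outcome is never missing.
Defaults are n = 483 and prevalence 0.30.

Where the source prints an item's sensitivity/specificity, the default specs
use those values verbatim. Where only the item's AUC is printed, the binary
identity AUC = (sens + spec)/2 pins the sum; the split was chosen once on
construct plausibility (e.g. "stated future intent" as a low-sensitivity,
high-specificity item) and frozen. Remaining items use unremarkable
mid-range values.

**Items are conditionally independent given the outcome by default.** The
real instruments overlap heavily (several items are near-duplicates across
scales), so real item vectors are strongly positively correlated. An
optional single-factor Gaussian-copula knob (`item_correlation`) induces
exchangeable latent correlation for sensitivity analyses, but no published
inter-item correlations exist to calibrate it, so it is off by default. The
consequences are discussed under Limitations.

## Scoring rules

- **Any-item scales** (MSHR, ReACT): high risk iff any item is positive. An
  episode whose observed items are all negative but with at least one item
  missing cannot be ruled low and is scored missing.
- **Banded scales** (SAD PERSONS ≤4 / 5–6 / ≥7; Modified SAD PERSONS with
  weights 2 on depression–hopelessness, rational-thinking loss,
  organised/serious attempt and stated future intent, bands ≤5 / 6–8 / ≥9):
  weighted total mapped to low/medium/high. The source's appendix tables were
  not available; these defaults follow the cited instruments and live
  entirely in `data/scales.yaml` — supply your own file to change them.
- **Barratt recoding**: 3–4 → 1 after reflecting reverse-scored items
  (r → 5 − r), so 1 always codes high impulsiveness. The alternative literal
  reading (applying the 1–2 → 0 rule to the raw response of reverse items)
  is available as `convention="raw"`; it makes the reverse flag a no-op,
  which is why it is not the default.
- **Global ratings**: 1–5 low, ≥6 high (the midpoint cutoff previously
  selected for these ratings by Youden's J).
- **Missing data**: listwise per analysed item/scale, never globally — an
  episode missing one Barratt item still contributes to every other
  analysis.

## Scale construction

One item per source scale, ranked by AUC. The instruments' psychiatric-care
items (SAD PERSONS "previous psychiatric care", Modified SAD PERSONS
"previous suicide attempts or psychiatric care", MSHR "prior psychiatric
treatment") are an equivalence class: once one is selected, the other
scales fall through to their next-best item. SAD PERSONS "previous suicide
attempt" and ReACT "self-harm in the last year" are *related but distinct*
constructs (lifetime attempt vs past-year self-harm) and are both
selectable by default — this reading yields the five-item composition the
procedure is meant to produce; the stricter equivalence is available by
merging `RELATED_ITEM_MAP` into the duplicate map. Ties are broken by a
configured deterministic item order (alphabetical by default), making the
selection invariant to table row order.

The selected items form an equal-weight additive score. The cutoff maximises
sens × spec (Liu) by exhaustive search over achievable thresholds, ties to
the lowest cutoff; Youden's J is available. Following the original design,
derivation uses the full sample and "validation" a 50% simple random
subsample of the same sample — a non-standard, optimistic design reproduced
as stated; `disjoint=True` gives a proper holdout and `stratified=True`
preserves the outcome rate in the subsample.

## Classification tree

All pooled binary (or binarised) items; at each node the split maximising
the weighted Gini decrease, computed on the rows observed for that item
(listwise per split; no surrogate splits). No pruning, stopping rules or
misclassification costs; recursion ends at purity, at no admissible
improving split, or at optional depth/size limits. Ties between
equal-decrease items keep the earliest item in candidate order.

Leaves (and internal nodes, for rows that stop early at a missing split
variable) are classified high risk when their positive fraction is at least
the training prevalence, ties high — the standard risk-stratification
reading of a tree grown on a 30% event rate. Plain majority voting
(`classify="majority"`) is available but labels every leaf low risk at this
prevalence. The tree's ROC score for an episode is its terminal node's
positive fraction, so a depth-1 tree's AUC equals the root item's binary
AUC.

## Numerical choices

- Proportion CIs: Wilson score default (well-behaved at the extreme
  proportions these items produce); Clopper–Pearson and Wald selectable.
  Intervals are produced by `statsmodels`; the test suite checks Wilson
  endpoints against an independent root-finding oracle at 1e-6 and its
  empirical coverage at the study size (10⁴ replicates, within [0.93,
  0.97]).
- AUC: midrank Mann–Whitney (exact half-credit for ties); Hanley–McNeil
  interval clipped to [0, 1]. Verified against an O(n²) all-pairs oracle.
- Likelihood-ratio CIs: Simel log method; undefined statistics (zero
  denominators) are reported as NaN, never raised.
- Reporting precision: percentages to 1 decimal place, AUC to 2.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration implies
  byte-identical outputs.

## Problem sizes used in the checks

Fixture-based checks run at the study size (n = 483) and are deterministic.
Law-of-large-numbers checks on the generator use n = 10⁵ (three binomial
standard deviations); the interval-coverage check uses 10⁴ replicates; the
constructed-scale simulation uses 100 replicates at n = 483; oracle
equivalence uses 200 (AUC), 80 (cutoffs) and 50 (tree splits) random
instances.

## Limitations

- **Conditional independence inflates composite accuracy.** With the five
  constructed-scale items at their published discriminations, the mean
  separation of the equal-weight sum is Σ(2·AUCᵢ − 1) = 1.10 regardless of
  how each item's sens/spec sum is split, while per-class SDs are at most
  ≈1.12 under independence — so the simulated composite reaches AUC ≈ 0.77,
  necessarily exceeding its best constituent (0.65), whereas the published
  composite (AUC 0.56, 95% CI 0.52–0.60) was *worse* than its best item.
  That gap is the signature of strong positive inter-item correlation in
  the real data and is reported as measured (see the acceptance outputs),
  not tuned away. Passing simulation checks therefore validate the
  machinery, not the claim that independent-item cohorts mimic real ones.
- The fixture's joint item arrangement, and hence any statistic of item
  *combinations* on it (deep trees, composite scores), is one arbitrary
  member of the set consistent with the published aggregates.
- Repeat presenters are not modelled: episodes are independent rows, as in
  the source design, so within-person clustering of both items and outcome
  is absent.
- Time-to-repetition is out of scope; the outcome is binary at 6 months.
- The default band tables and item lists follow the cited instruments, not
  a verified appendix; analyses sensitive to banding should supply their
  own `scales.yaml`.
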