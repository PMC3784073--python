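# Methods

## Model and assumptions

The package implements a two-stage Bayes approach to biomarker selection.
Both stages operate on categorical attributes, so continuous inputs are
discretized first; all probability tables are estimated by smoothed
counting, which is what makes the whole pipeline linear-time in the number
of candidate features and cheap enough to wrap a search around.

**Naïve Bayes filter.** Stage one assumes attributes are independent given
the class and exploits that assumption *per feature*: each feature is
scored by the cross-validated accuracy of an NB classifier that sees only
that feature. This is deliberately a univariate filter — it cannot credit
feature combinations — and the framework relies on stage two to model
dependence among the survivors.

**Hidden Naïve Bayes.** Stage two relaxes independence without paying for
structure learning (learning an optimal Bayesian network is NP-hard).
Every attribute receives one *hidden parent*: a convex mixture of the
pairwise conditionals `P(a_i | a_j, c)` over all other retained
attributes, weighted by normalized conditional mutual information
`I(A_i; A_j | C)`. The model therefore captures all pairwise
class-conditional dependencies in a single aggregated parent per
attribute, at quadratic (not exponential) cost in the panel size. It does
not capture higher-order interactions, and a weight row built from CMI
reflects estimated dependence — on small samples, smoothing noise spreads
weight over genuinely independent attributes.

**Backward elimination.** The elimination order is fixed by the filter
ranking (always drop the current lowest-ranked feature); subsets are never
re-ranked. This is a linear sweep over panel sizes m…1, not a
combinatorial search, and it can miss panels whose value is purely
synergistic. The reported panel is the smallest subset attaining the
maximum cross-validated accuracy.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_bins` (B) | 10 | equal-width bins per continuous feature |
| `threshold` | 0.75 | minimum single-feature NB CV accuracy to pass the filter |
| `cap` (m) | 40 | maximum panel size handed to HNB |
| `alpha` | 1.0 | Laplace pseudocount on every probability table |
| `cv_folds` (k) | 10 | stratified CV folds for ranking and elimination |
| `holdout_fraction` | 0.10 | blind set reserved before any selection |

The defaults are the framework's standard operating point; `threshold`
and `cap` trade panel size against downstream cost, and `alpha = 1`
prevents zero probabilities in the sparse tables that 10-bin
discretization of a few hundred samples inevitably produces. If no
feature reaches the threshold the filter keeps the top `cap` features and
records a warning rather than returning an empty panel.

## Numerical and protocol choices

- **Binning conventions.** Intervals are left-closed/right-open with the
  last bin closed; values outside the training range clamp to the extreme
  bins; a zero-range feature maps everything to bin 0. Edges are fit on
  the training split only (never on blind samples). Within the training
  split the same edges are reused across CV folds: the module contracts
  pass an already-binned dataset into ranking and elimination, and the
  residual fold-level leakage of bin *edges* (not labels) is second
  order. Missing values are rejected with a pointer to the offending cell.
- **Log base.** CMI is reported in nats. The base cancels in the weight
  normalization, so it affects reported CMI values only.
- **CMI estimation.** The joint `P(a_i, a_j, c)` is the smoothed cell
  frequency; its own marginals feed the CMI sum, so the estimate is
  nonnegative up to round-off and is clipped at 0. `0·log(0/x)` is 0.
- **Degenerate weight rows.** An all-zero CMI row has no usable hidden
  parent; prediction substitutes the univariate conditional `P(a_i | c)`.
  With one feature, or all-zero CMI, HNB therefore reduces *exactly* to
  plain NB (a tested invariant).
- **Ranking scheme.** The default score is single-feature NB accuracy
  under stratified CV, the quantity the 0.75 filter threshold refers to;
  resubstitution scoring and a faster scheme ranking by the sample-mean
  best-class NB factor `max_c P(c)P(a_i|c)` are provided as alternatives.
  Ties in ranking break by ascending feature index; argmax ties in
  prediction break toward the smallest class index.
- **Elimination by restriction.** Pairwise CPTs and CMI are per-pair
  quantities, so a model restricted to a feature subset (with weight rows
  renormalized over the subset) is identical to a model refit on that
  subset. Elimination fits one full HNB per fold and scores all nested
  subsets by restriction; a test asserts the equivalence to refitting at
  1e-12.
- **Fold protocol.** One stratified fold partition per elimination run,
  shared by every subset size, so accuracy differences between sizes are
  not confounded by fold noise. All tables are re-estimated on each
  training fold. The blind holdout is drawn before discretization and
  touched exactly once.
- **Positive class.** Sensitivity/specificity/AUC take the lexically
  greater label as the positive ("case") designation unless the caller
  overrides it; the report echoes the designation. AUC is the
  Mann–Whitney probability that a random positive outranks a random
  negative, ties counted 1/2.

## Synthetic data

The generators provide ground truth the real datasets cannot:

- **Gaussian expression mode** — null genes are standard normal in both
  classes; planted genes are shifted by `effect` SDs in cases. Default
  `effect = 2.0` with 200 samples puts planted single-gene accuracies
  around 0.8–0.9: some features clear the 0.75 filter threshold and most
  nulls do not, so both sides of the criterion are exercised.
- **Genotype mode** — 0/1/2 minor-allele counts drawn under Hardy–Weinberg
  equilibrium per class; planted SNPs differ in allele frequency by
  `effect` between classes (symmetric around 0.5).
- **Dependent chains** — children copy a uniform parent with fidelity `f`,
  otherwise resample uniformly among the other V−1 categories, giving the
  closed-form `I = log V + f log f + (1−f) log((1−f)/(V−1))` per pair
  (0 at `f = 1/V`, `log V` at `f = 1`) against which the CMI estimator is
  validated.

These fixtures emulate effect structure, not real-data pathology: no batch
effects, dye bias, heavy-tailed intensities, missing values, or linkage
disequilibrium between SNPs. Passing tests demonstrate that the machinery
recovers known structure under clean conditions, not that a given clinical
dataset will yield a six-gene panel.

The panel-resampling experiment draws 20-marker panels with replacement
from the top-40 and lower ranking strata and scores each by HNB 10-fold CV
accuracy, reproducing the stratum-separation evidence for the filter at a
few hundred draws instead of the 10^5–10^6 used at full scale.

## Problem sizes

The validation suite and `scripts/acceptance.py` use 200 samples with up
to 1000 features (10 planted), CMI fixtures at n = 10 000, and 100–200
resampled panels per stratum — sizes chosen so the full validation runs in
about a minute while leaving every statistical check comfortably powered.

## Known limitations

- Multi-class input is accepted by the classifiers, but
  sensitivity/specificity/AUC are reported for binary tasks only.
- The filter threshold/cap and the elimination sweep assume the filter
  ranking is roughly aligned with marginal usefulness; purely epistatic
  markers (no marginal signal) will not pass stage one.
- Pairwise tables are dense arrays of shape F²·V²·|C|; with the default
  cap (F ≤ 40, V = 10) this is a few megabytes, but very large panels or
  cardinalities would need a sparse representation.
- ARFF support covers numeric and nominal attributes (read via
  scipy.io.arff, written by a minimal in-package writer); string and date
  attributes are out of scope.
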