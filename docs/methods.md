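# Methods

## The attribution model

A fitted classifier f maps a sample x ∈ ℝᴺ of metabolite abundances to a
class-1 probability (or a log-odds margin for boosted ensembles). Treating
the N feature *values* as players in a cooperative game whose payout is the
model output, the Shapley value of feature i is

φᵢ = Σ_{S ⊆ F\{i}} |S|! (N−|S|−1)! / N! · [val(S∪{i}) − val(S)],

where val(S) is the expected model output when only the coalition S of
feature values is known. It is the unique attribution satisfying

- **symmetry** — features with identical marginal contributions receive
  identical values;
- **dummy** — a feature that never changes any marginal contribution
  receives exactly zero;
- **local accuracy / efficiency** — val(∅) + Σᵢ φᵢ = f(x).

### The tree value function

For a tree ensemble, `metashap` uses the *path-dependent conditional
expectation*: walking a tree for coalition S, a node splitting on a feature
in S follows x's branch; any other node averages both subtrees weighted by
their training **cover** (the training-weighted number of samples routed
through each child). The decision paths of missing features are thereby
ignored rather than re-sampled, and no background dataset is needed — the
covers recorded at training time carry all the distributional information.
An *interventional* variant that marginalises missing features over an
explicit background sample set is provided
(`shapley.interventional_value_fn`); it defines a different, also exact,
game and generally yields different numbers. The path-dependent game is the
package default because it is self-contained and matches how tree
explanation is usually done in this field.

### Two routes, one answer

`shapley_bruteforce` evaluates val on all 2ᴺ coalitions and applies the
definition directly. It is the oracle: slow (O(TL·2ᴺ)), obviously correct,
and refused above N = 20 without an explicit override.

`tree_shap` computes the same numbers in O(T·L·D²) per sample. Down each
root-to-leaf path it maintains one entry per *unique* path feature holding
(i) the fraction of cover flowing through when the feature is missing,
(ii) an indicator of whether x follows the path, and (iii) a weight vector
that tracks, for every coalition cardinality simultaneously, the summed
Shapley kernel mass of coalitions drawn from the path features. Entries are
pushed on descent (extend) and popped (unwind) both when a feature repeats
on a path and when a leaf's contributions are distributed. Equality with
the brute-force oracle (≤ 1e-8; in practice ~1e-16) is asserted over random
ensembles in the test suite, and a work counter on each attribution makes
the polynomial bound T(2L−1)(D+2)² checkable rather than asserted.

Per-tree additivity means ensemble attributions are cover-weighted sums of
single-tree attributions. For **margin-output** ensembles (ingested
gradient boosting / XGBoost) attributions are therefore computed on the
additive log-odds scale; applying the logistic link first would define a
non-additive game that no per-tree algorithm could decompose. Probability
ensembles (bagged forests, the package's reference trainer) have identity
link, so their attributions are directly on the probability scale.

### Base value

The attribution's base value is val(∅), the cover-weighted mean leaf value —
the quantity local accuracy is guaranteed against. The empirical mean
prediction over the explained set is a *different* number (it depends on
which samples are explained) and is reported alongside
(`ShapMatrix.mean_model_output`) because waterfall-style displays are often
annotated with it.

## Models

**PLS-DA.** NIPALS PLS1 with X-deflation on the autoscaled matrix and a
centered 0/1 response (inner tolerance 1e-12, cap 500 iterations — a single
response converges in one pass). The per-component model is collapsed to
Ŷ = X·B_PLS + intercept; scores ≥ 0.5 classify positive (the boundary is
assigned to the positive class; the discriminant rule defines only the
strict inequalities, so a deterministic convention is required).
Requesting more components than the rank of the centered training matrix is
an error that reports the achievable rank. VIP uses Wold's formula
VIPⱼ = √(p·Σₐ SSYₐ(w_{ja}/‖wₐ‖)² / Σₐ SSYₐ) with SSYₐ the response variance
explained by component a; ΣVIP² = p holds to 1e-8 by construction.

**Reference forest.** Bagged CART: per tree a bootstrap resample, greedy
best Gini split over a per-node seeded random feature subset (default
√p), candidate thresholds at midpoints of consecutive distinct values,
ties broken by lowest feature index then lowest threshold, leaf value =
positive-class fraction, tree weight 1/T. Node cover is the bootstrap
routing count and the split's cover-weighted Gini decrease is recorded so
Gini importance (normalized to sum 1) needs no re-routing. Routing is
"left iff x ≤ threshold" everywhere; a fixed convention keeps tests
bit-stable. Forest output is the averaged leaf probability rather than a
majority vote — attribution needs a continuous output, and averaging is
what the common implementations expose.

**Ingestion.** Tree ensembles round-trip through a JSON document of node
arrays including cover; validation enforces rooted binary structure,
cover[parent] = cover[left] + cover[right], and finite leaf values.
The scikit-learn adapter reproduces `predict_proba` to 1e-10; the XGBoost
adapter parses the booster's own full-precision JSON model, maps XGBoost's
"left on x < t" rule onto this package's "x ≤ t" via nextafter(t, −∞), and
rebuilds internal covers bottom-up from the leaf hessians because the
stored per-node sums are float32-rounded. Training of boosted models is
out of scope; they enter only through ingestion.

## Preprocessing

Volcano selection computes log2FC from raw group arithmetic means (a
pseudo-count of half the feature's smallest positive value is added to
both means when either is zero) and the p-value from a pooled-variance
(Student's) two-sample t-test on log2 abundances — the fold change lives on
the raw scale, the test on the log scale where abundances are closer to
normal. Features are kept iff |log2FC| > 0.5 AND p < 0.05, both strict, no
multiple-testing correction (a Benjamini–Hochberg option exists but is off
by default, matching the conventional raw-p volcano). Features with zero
pooled variance get p = 1 unconditionally — a constant measurement is
treated as a degenerate artifact rather than evidence. Whether the t-test
should run on raw or logged values is genuinely open; logged is the
package's choice and the fold-change scale is configurable at the call
site.

Log + autoscale fits the per-feature mean and sd (ddof = 1) on the training
partition only; held-out data are transformed with training statistics, so
explanations of the test set never leak test information. Zero-variance
training features are dropped with a warning. The log base (default 10) is
provably irrelevant: changing base rescales each logged feature linearly,
which unit-variance scaling absorbs (asserted to 1e-10 in the tests).

## Pipeline

Stratified train/test split (test size = nearest integer to n/6 by
default; 184 samples → 31 held out), largest-remainder per-class
allocation, recorded seed. Hyperparameters are tuned by exhaustive grid
search (a one-parameter grid is a linear search) under stratified k-fold
CV scored by rank-based (Mann–Whitney, midrank ties) ROC AUC; score ties
prefer the simpler model (fewer components/trees, shallower), then grid
order. Stratification and a recorded seed are defaults because the test
sets here are small enough for split noise to dominate otherwise. Nothing
downstream of the split reads test labels before the evaluation stage.

Error analysis reports confusion counts and the four rates as percentages
of the **total** test size — TP + TN + FP + FN = 100% — the convention of
confusion matrices annotated with overall percentages, with each sample's
waterfall decomposition attached to its outcome group.

## Synthetic data

Per-feature natural-log abundances are Gaussian: log Xᵢⱼ = μ + σZᵢⱼ +
1[yᵢ=1]·effectⱼ·log 2, with Z equicorrelated within configured blocks
(Gaussian copula) and independent elsewhere. The log2 fold change of group
geometric means therefore equals the configured effect in expectation, and
with equal group variances the arithmetic-mean fold change used by the
volcano matches it too. Labels are assigned by exact count
(round(n·balance)) and shuffled, so no draw leaves a class empty. Defaults:
μ = 7 (abundances ~1100), σ = 1.0 (~131% CV).

The **urine-sex-like preset** mirrors a urine sex-classification cohort at
desk scale: 184 samples × 184 features, 101/83 class balance, a dominant
+2.0 log2-effect marker (testosterone-glucuronide-like), an
opposite-direction −1.5 marker (p-anisic-acid-like), and a +0.8 helper
correlated with the main marker (ρ = 0.6) for dependence/interaction
demonstrations. The preset uses σ = 0.5 (~53% CV, typical of targeted
urine assays); the emulated marker is a near-binary sex discriminator, so
strong separability is the realistic condition.

What the generator does *not* emulate: batch effects, missingness
mechanisms, instrument drift, heavy-tailed contamination, or realistic
metabolite-network correlation structure. Passing recovery tests therefore
show that the pipeline finds strong planted multiplicative effects under
log-normal noise — not that it is robust to the full messiness of real
acquisitions.

Known behaviour worth noting: in a few percent of recovery replicates the
−1.5 marker's mean |SHAP| edges out the +2.0 marker's. This is expected —
the correlated helper shares Shapley credit with the main marker (symmetry
acting on correlated splits), while the opposite-direction marker keeps
its credit undivided.

## Numerical choices and limitations

- Tolerances: oracle equivalence and local accuracy 1e-8; symmetry 1e-12;
  per-tree additivity 1e-10; PLS/OLS closed forms 1e-10 (full-rank 1e-8);
  brute-force guard N ≤ 20.
- Problem sizes in tests and the acceptance script (50 random ensembles ×
  4 samples for the oracle check; 100 recovery replicates with 100-tree
  forests; 500-feature/50-tree/depth-6 scalability run) were chosen as the
  smallest sizes at which each property is convincingly exercised.
- Degenerate inputs: empty coalitions on zero-cover internal nodes, tables
  with <2 samples per class, single-class AUC, sub-rank PLS requests and
  malformed tree documents all raise with specific messages rather than
  returning silently wrong numbers.
- Kernel SHAP, SHAP interaction values, PLS2/multi-class, nested CV and
  boosting training are deliberately out of scope.
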