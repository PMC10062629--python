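# Methods

## Problem setting

The package implements a listwise learning-to-rank model for query-grouped
data with graded relevance (document retrieval, drug-response ranking). A
query q holds n_q documents with feature vectors x ∈ R^p and integer grades
y ∈ {0, …, ŷ}. The goal is a scoring rule whose induced ordering of each
query's documents maximises ranking metrics such as NDCG@k.

## Ground Truth Deviation targets

Instead of regressing a scalar grade, each document gets a K-vector target
θ_d = ξ_I · (ξ_D ∘ ξ_Φ), built on the ideally sorted list (grades
descending, ties kept in original order):

- **Swap-NDCG** λ_di: the NDCG of the ideal list after exchanging document
  d with the document at position i, computed in closed form
  λ_di = 1 + [(y_d − y_{π_i})/log(1+i) + (y_{π_i} − y_d)/log(1+π_d⁻¹)]/Φ_I.
  Gain is G(s) = s and discount 1/log(1+s); λ is invariant to the log base
  because the swap delta and the ideal DCG rescale identically.
- **Position deviation** ρ_di = α / cosh(min(β h, βh/2)) with
  h = π_d⁻¹ − i: an asymmetric bell with peak α at h = 0. The `min` places
  the slower decay (rate β/2) on positive offsets, so a document scored for
  a rank above its ideal slot is penalised less than one scored below it.
  The published rendering of this formula is typographically ambiguous
  (α adjacent to |cosh(·)|); the division reading is used because the
  product reading is unbounded, minimised rather than maximised at h = 0,
  and inconsistent with a bell-shaped score that peaks at α.
- **Document importance** ξ_I = log(ŷ y_d + 1)/log(ŷ² + 1) ∈ [0, 1],
  increasing in the grade, 0 at y_d = 0 and 1 at y_d = ŷ. Again the
  increasing reading of an ambiguous rendering is chosen: a decreasing
  alternative would contradict "emphasis on highly relevant documents".

The per-position vectors are truncated to the first K positions; when a
query has fewer than K documents the last element is repeated (ξ_I is a
per-document scalar and needs no padding). Queries whose grades are all
zero have no ideal ordering: they get zero target matrices, are flagged
degenerate, are kept as zero-target rows during training, and are excluded
from all metric averages (with the exclusion count reported).

Defaults: K = 5 (a low K focuses the model on the top of the list),
α = 10, β = 2, ŷ = 2, log base 2, AP binarisation threshold 1 (grades ≥ 1
count as relevant).

## Distributionally robust training

The scoring map is linear, f(x) = B′x with B ∈ R^{p×K}. Training minimises
the worst-case expected residual r-norm over a Wasserstein ball of radius
ε around the empirical distribution of (x, θ), which reduces to

    min_B  (1/N) Σ_{q,d} ‖θ_d^q − B′x_d^q‖_r + ε ‖B̃′‖_s,
    B̃ = (−B′, I_K),  1/r + 1/s = 1,

with ‖·‖_s the induced matrix norm. Supported orders are r ∈ {1, 2, ∞};
for the default r = 2 the regulariser is the spectral norm
√(1 + σ_max(B)²), which is tighter than the Frobenius-based relaxation
√(1 + ‖B‖_F²) (asserted in tests). ε = 0 recovers plain empirical risk
minimisation. Because √(1 + σ²) is flat at σ = 0, the optimum at large ε
approaches but never exactly reaches B = 0; its scale is ≈ (residual
slope)/ε.

### Solver

The problem is convex and nonsmooth. The default solver is plain
subgradient descent from B = 0 (the regulariser's minimiser) with
normalised diminishing steps step0/√(t+1) and best-iterate tracking;
step0 defaults to a data-driven scale (initial objective over mean squared
feature norm). For r = 2 a quasi-Newton polish then refines the best
iterate: L-BFGS on the Huber-smoothed objective (per-row
√(‖ρ‖² + μ²) − μ, μ = 1e-9), whose minimiser coincides with the nonsmooth
optimum to well below test tolerances. The polish makes parameter recovery
on realizable data exact to ~1e-14 and matches an independent
iteratively-reweighted-least-squares (Weiszfeld) minimiser — used purely as
a cross-check oracle in tests — to ~1e-8 in objective value. Determinism:
the solver is deterministic given its configuration; the seed field exists
for optional randomised components only.

ε is selected by grid search maximising validation NDCG@5 with NDCG@10 as
tie-break; the default grid is logarithmic over [1e-4, 1]. No intercept is
fitted (the scoring map is purely linear); optional per-feature z-scoring
with training-set statistics is available but off by default, and no
normalisation is applied when reading data files.

### Scoring procedure

Predicted targets Θ̂ = XB have one column per importance level. Ranking is
cyclic: rank 1 takes the remaining row maximising column 1, rank 2 the
remaining row maximising column 2, …, resetting to column 1 after every K
assignments. Ties take the lowest row index, making the output
deterministic. With K = 1 this is a descending sort on the single score.

## Evaluation metrics

DCG@k = Σ_{r≤k} y_{π_r}/log(1+r); NDCG@k divides by the ideal DCG@k and is
undefined (excluded, counted) when IDCG@k = 0. P@k is the fraction of
relevant documents in the top k after binarising at the AP threshold;
AP@k = (1/m) Σ_{j≤k} P@j·1(relevant at j) with m the number of relevant
documents *within the top k* (not query-wide), undefined when m = 0. The
binarisation threshold for 3-grade data defaults to 1, treating "partially
relevant" and "definitely relevant" alike, and is configurable.

## Robustness protocols

- **Gaussian noise**: i.i.d. noise with user-chosen mean and fixed small
  standard deviation (default 0.001) added to every feature entry of a
  uniformly random ⌈0.75·T⌉ query subset (selection without replacement,
  seeded). Suggested mean levels: {0.05, 0.1, 0.2, 0.4}. Note that for
  purely linear rankers a common additive shift leaves within-query
  orderings nearly unchanged; this attack mainly stresses nonlinear models
  and interacts with generalisation quality.
- **Universal FGSM**: a pointwise OLS regression of grade on features
  (fit on clean training data) supplies the cost J = (w′x + b − y)²;
  selected test documents move by σ·sign(∇_x J) = σ·sign(2(w′x + b − y)w),
  so every coordinate changes by exactly −σ, 0 or +σ.
- **Black-box FGSM**: a substitute model is fit to the victim's observed
  per-document outputs (for this model, the first predicted GTD column),
  then FGSM runs with the substitute's gradient. The substitute interface
  is pluggable — any trainer mapping (features, outputs) to an object with
  a `gradient(x, y)` method — with linear least squares as the default.
- **Label poisoning**: training labels in {0, 1, 2} are independently
  resampled from a row-stochastic table with retention probability e on
  the diagonal; the extreme grades put 2/3 of their error mass on the
  middle grade and the middle grade splits its error mass evenly. The
  protocol retrains on the poisoned training set and evaluates on clean
  test data (e = 0.85 low noise, e = 0.7 high noise).

## Synthetic data

The generator emulates graded-relevance benchmark structure at the scale of
a small document-retrieval query set: T = 100 queries, 10–30 documents
each, p = 45 features, grades 0..2. Each document carries a nonnegative,
right-skewed latent relevance s ~ Exponential(1) — mimicking retrieval
features such as BM25, where irrelevant documents cluster near the origin —
with features x = s·w + feature_noise·η (unit direction w, Gaussian η,
feature_noise default 0.3) and grades assigned by per-query quantile
binning of u = s + noise_sd·ε. Quantile binning guarantees per-query label
diversity; all-zero-label queries appear only via an explicit flag for
edge-case tests.

A centered symmetric feature design (e.g., standard Gaussian x with grades
thresholded on w′x) was rejected: under the mean residual-norm loss, the
exact-zero target rows of irrelevant documents penalise any nonzero
prediction by ‖B′x‖, and with a symmetric latent score the achievable gain
on relevant documents never exceeds that penalty, making B = 0 the global
optimum. The skewed nonnegative construction reflects how real relevance
features behave and removes the degeneracy.

What passing tests on this generator do **not** show: behaviour under real
feature semantics (correlated, heavy-tailed, heterogeneous scales),
query-dependent feature distributions, or the nonlinear relevance
mechanisms of real corpora.

The realizable generator plants B\* and emits targets θ = B\*′x directly
(bypassing the GTD formulas) so the training objective has a known optimum;
by default B\* = w·c′ with positive decreasing level weights c, making
every target column monotone in w′x so that the cyclic scoring procedure
can achieve the ideal ordering on labels binned from the same score.

## Robustness-ordering experiment

The qualitative claim that the robust model degrades less than empirical
risk minimisation is checked on 20 seeded replicates of a deliberately
limited-data regime (train 10 queries, validation 8, test 12; p = 45;
latent label noise sd 1.0), where regularisation has room to matter — the
regime the method targets. Per replicate, ε is tuned on validation over
{0.01, 0.05, 0.2}; the Gaussian attack uses mean 0.2 on 75 % of test
queries; the label attack poisons training labels at e = 0.7, after which
both models are refit (and ε re-tuned, mirroring how hyperparameters are
chosen on validation whenever a model is retrained). The assertion is on
means over replicates: tuned-ε NDCG@5 ≥ ε=0 NDCG@5 under each attack. At
ample sample sizes both models coincide and the comparison is vacuous;
this experiment intentionally avoids that regime.

## Numerical choices and edge cases

- Positions are 1-based in all formulas; document indices 0-based in
  memory. File feature indices are 1-based (SVMlight convention).
- Ties in the ideal order use a stable sort, making targets deterministic.
- Zero-residual rows contribute a zero subgradient; the s=∞ regulariser's
  subgradient is zero while the max row sum is below the identity block's 1.
- Labels are parsed as floats, validated nonnegative; non-integer labels
  are accepted with a warning and used as-is by the metrics.
- Empty datasets, all-degenerate training sets, dimension mismatches, and
  out-of-range AP/label inputs raise errors rather than guessing.
- Model files are JSON; coefficient matrices round-trip bit-exactly via
  shortest-repr floats.

## Known limitations

- Only r ∈ {1, 2, ∞} is implemented; the quasi-Newton polish covers r = 2.
- The K levels interact with query length: queries shorter than K rely on
  the padding rule, and the cyclic scorer revisits column 1 every K ranks
  regardless of n_q.
- The label-poisoning table is defined for 3-grade data only.
- Training cost is dominated by target construction (O(n_q²) swap scores
  per query) and the per-iteration SVD of B; both are negligible at the
  scales exercised here but not tuned for web-scale corpora.
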