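# Methods

## Problem and model

Given a two-class dataset with `n` cases and `d` numeric features, wrapper
feature selection seeks the bit vector `x ∈ {0,1}^d \ {0}` maximizing

    f(x) = β (d − s)/d + (1 − β) · acc(x),

with `s = Σ x_j`, `acc(x)` the stratified k-fold cross-validated accuracy of
a classifier restricted to the selected columns, and `β ∈ [0,1]` the weight
of the feature-reduction term (default 0.2). Because `acc ∈ [0,1]` and
`s ≥ 1`, the fitness is strictly positive, which the roulette-selection
operator relies on. Setting `β = 0` recovers plain accuracy as the
objective ("acc mode").

Fold counts follow the small-study convention: k = 5 when n < 100, k = 10
otherwise. Folds are always stratified — with n as small as 34–72 cases and
unbalanced classes, unstratified folds can lose a class entirely and leave
sensitivity/specificity undefined. Within one search (and across algorithms
in a benchmark) the fold plan is frozen, so all subset comparisons are
paired; the reported accuracy of a final subset is computed on that same
plan.

## Relief weighting

Weights start at zero and, for each visited case, grow by the feature-wise
distance to the nearest miss and shrink by the distance to the nearest hit,
each divided by the visit count T. Choices made where the classic recipe
leaves room:

- **T and sampling.** Deterministic every-case-once sweep (T = n) by
  default; uniform random sampling with replacement is available with a
  seed.
- **Distance.** Euclidean over all features for both the hit and miss
  search; the visited case is excluded from its own hit search; ties break
  to the lowest case index.
- **k-NN variant.** The update sums over the k nearest misses minus the k
  nearest hits and divides by `T·k`; the 1/k averaging is a normalization
  choice made so the k = 1 variant coincides exactly with the
  nearest-neighbour variant. Default k = 3.
- **Scaling.** Features should be min-max normalized to [0,1] first (the
  selector does this internally by default); Relief's absolute differences
  are otherwise dominated by whichever feature has the widest range. The
  implementation warns when it sees un-normalized input. We do not use the
  classic per-feature range division inside the update, since global
  min-max normalization makes it a no-op.

Weights feed the transfer function as coefficients `γ_j`. The default
mapping is the identity; `minmax` (rescale the weight range onto [−1,1])
and `clip` are available for datasets whose weight magnitudes saturate or
starve the sigmoid.

## Lévy flight and binarization

Steps are sampled per dimension with the Mantegna algorithm at stability
index β_levy = 1.5 and scale α = 1: `s = u/|v|^(1/β_levy)` with
`u ~ N(0, σ_μ²)`, `v ~ N(0,1)` and σ_μ given by the closed form (≈ 0.6966
at β_levy = 1.5, exactly 1 at β_levy = 1). The step alone drives the bit
probability through the weighted sigmoid; no continuous position is
accumulated across iterations. The two sigmoid branches (step ≥ 0 and
step < 0) are mirror images, both equal ½ at step = 0, so γ = 0 features
are unbiased coins — the natural limit, with no special-casing. The
`rand ≤ sig` tie is inclusive. Exponent arguments are clamped at ±700;
beyond that the probability is exactly 0 or 1.

A proposed all-zero subset has undefined fitness and is repaired before
evaluation: the weighted search sets the highest-γ bit, the unweighted
baselines one uniformly random bit.

Acceptance is greedy (a nest keeps proposed bits only on improvement),
mirroring the compare-and-replace step of classical cuckoo search;
unconditional replacement is available via `acceptance="always"`.

## Elite regeneration

Each iteration, after the Lévy proposals, `floor(p_r · (n_pop − 1))` worst
non-elite nests are replaced by offspring: parent pairs are drawn by
roulette over the whole population (selected × selected), crossed at a
uniform cut point in {1, …, d−1} with probability p_c, cloned otherwise.
The single elite nest is copied through untouched, and elite ties break
toward fewer selected features, then lower index. `p_r` plays the
structural role of the classical abandonment probability; no additional
abandonment step exists in the hybrid search. Defaults p_c = 0.5,
p_r = 0.3.

## Baselines

- **BCS**: identical loop with γ ≡ 1 and, in place of regeneration, the
  worst `floor(p_a·(n_pop−1))` non-elite nests re-randomized each iteration
  (p_a = 0.25, the customary cuckoo-search value; the comparison protocol
  that fixes the other algorithms' parameters does not list BCS).
- **BGA**: generational; roulette selection, single-point crossover at
  p_c = 0.8, independent per-bit mutation at p_m = 0.1, elitism of one.
- **BPSO**: velocity `v ← ωv + c1 r1 (pbest − x) + c2 r2 (gbest − x)`
  clamped to ±6, bits resampled as 1 with probability `1/(1+e^{−v})`;
  c1 = 1, c2 = 2, ω = 0.9.

All four initialize nests as Bernoulli(0.5) bits (repaired if empty), run a
fixed iteration budget (default 100; no convergence rule is imposed), and
report a best-so-far trajectory that is non-decreasing by construction.
Fitness values are memoized by bit string; `n_evaluations` counts distinct
classifier evaluations and cache hits are reported separately, which both
speeds up low-d searches enormously (subsets recur constantly) and makes
evaluation budgets comparable across algorithms.

## Randomness and reproducibility

One root seed is split into named, independent streams (initialization,
per-nest Lévy flights, genetic operators, velocities, abandonment) via
`SeedSequence.spawn`. Per-nest Lévy streams mean a population-size change
does not perturb the draws of unrelated nests. Identical configuration and
seed give bit-identical results, including trajectories; serialized run
results omit wall time for byte-level reproducibility.

## Synthetic data

The generator emulates the two-class tabular benchmarks this method targets:
informative features are N(0,1) in class 0 and N(effect, 1) in class 1
(`effect` is the standardized mean shift, default 2.0), redundant features
are noisy copies of informative ones, everything else is N(0,1) noise in
both classes, labels are Bernoulli(class balance), and column order is
shuffled. It does **not** emulate heavy-tailed expression distributions,
feature-block correlation structure, batch effects or label noise — so
passing tests demonstrate correct mechanics and signal recovery under clean
Gaussian separation, not performance on real microarray data. Default sizes
(n = 200, d = 50, 5 informative) keep a planted-recovery run under ten
seconds with the surrogate classifier while leaving 45 decoy features.

## Classifiers

SVMs follow the dimensionality convention: RBF kernel below 2000 features,
linear kernel above, C = 1 and the variance-scaled RBF bandwidth
(`gamma="scale"`), since the benchmark protocol fixes kernels but not
hyperparameters. The surrogate is a plain nearest-centroid rule in numpy;
it exists because oracle tests enumerate all 255 subsets of a d = 8
instance (and searches evaluate ~10³–10⁴ subsets), where per-call SVM
overhead would dominate. The surrogate is the default for the selectors'
internal fitness; user-facing CLI selection defaults to the SVM.

Zero-denominator metrics (no positive predictions, or a fold without
positives) are reported as 0 with an `undefined` flag rather than dropped,
so averages always exist. The benchmark's Std is the population
(divide-by-R) standard deviation over run accuracies — material at R = 5
and flagged here because either convention is defensible.

## Problem sizes in tests and the acceptance script

Oracle-equivalence tests run Relief on 50 random instances with n ≤ 30,
d ≤ 6 against an independent double-loop implementation; search-level
properties run at n = 60, d = 12 (where exhaustive enumeration is cheap and
the fitness cache collapses repeats) and the planted-recovery check at
n = 200, d = 50. The acceptance script benchmarks three algorithms for five
runs of 50 iterations each at n = 200, d = 50 — chosen as the smallest
configuration that exercises the full protocol with a clear planted signal.

## Known limitations

- Two-class problems only; multi-class Relief and metrics are out of scope.
- No SVM hyperparameter tuning or nested CV; reported accuracies are
  optimistically biased as model-selection criteria always are.
- The positive class for sensitivity/specificity defaults to label 1 (the
  lexicographically larger original label) and is configurable, not
  inferred.
- Whether Lévy steps should accumulate as a continuous latent position is
  ambiguous in the binary-search literature; this implementation binarizes
  each fresh step directly.
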