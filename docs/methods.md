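# Methods

## Model and procedure

`costfs` addresses minimal-test-cost feature selection on decision
systems: tables of instances with numeric conditional features, one
categorical decision label, and a positive per-feature test cost with
additive subset cost c\*(A) = Σ_{a∈A} c(a).  Conditional features are
min-max normalized to [0, 1] per column before anything else; a constant
column maps to all zeros (the scaling formula is 0/0 there, and a
constant feature is uninformative regardless of the value chosen).
Normalization is idempotent.

### Neighborhood rough sets

Numeric measurements carry uncertainty, modeled as a per-feature error
half-width e(a) = Δ · mean_i a(x_i) with Δ = 0.1 by default; e(a) is kept
at full precision internally and rounded only for display.  Two
instances are indiscernible on subset B when |a(x) − a(y)| ≤ λ·e(a) for
every a ∈ B.  The default multiplier λ = 2 encodes that two noisy
readings of one true value can differ by up to twice the half-width;
λ = 1 is selectable.  The relation is reflexive and symmetric but not
transitive, so it defines neighborhoods, not equivalence classes.  The
positive region POS_B(D) is the set of instances whose entire
B-neighborhood shares their label; it is monotone nondecreasing in B,
which makes the core (features whose removal from C shrinks POS) equal
to the intersection of all decision-relative reducts.  With e ≡ 0 the
machinery reduces to classical equality-based rough sets.

On the packaged liver subtable, exhaustive enumeration gives core
{Sgpt} and reducts {Alkphos, Sgpt}, {Sgpt, Sgot} under **both** λ = 1
and λ = 2; these are pinned as regression values.  The accompanying
worked example's claim that the core is {Gammagt} is not reproducible
under any convention we examined and is deliberately excluded from the
oracles (see Known limitations).

### Minimal-cost reduct search

`min_cost_reduct` does depth-first branch and bound over
feature-inclusion decisions in file order, pruning a branch as soon as
its partial cost reaches the incumbent — admissible because costs are
strictly positive, which also guarantees the cheapest covering subset is
inclusion-minimal and hence a genuine reduct.  Ties break toward fewer
features, then earlier file order.  The search is exponential and
refuses systems wider than `max_features_guard` (default 20) unless the
caller raises the guard knowingly.

### Laplacian score and cost weighting

The affinity graph keeps, per row, the k nearest instances by Euclidean
distance over all conditional features (k counts the instance itself;
default k = 3, so two nearest others), with argsort-stable index order
breaking distance ties.  Two conventions are configurable because both
occur in practice and they genuinely differ:

* kernel: `squared_exponential` exp(−d²/t) (the textbook heat kernel,
  the general-use default) or `exponential_distance` exp(−d/t), which is
  the convention that reproduces the published worked-example matrix
  (verified on all 36 entries at 2 decimals, e.g. d(x1,x4) = 0.2093,
  e^−0.2093 = 0.811);
* neighbor rule: `or_rule` (undirected union; symmetric S,
  positive-semidefinite L, non-negative scores — the default) or
  `directed_rows` (each row keeps only its own k nearest, possibly
  asymmetric — the worked-example mode; the published matrix has
  S(x4,x5) = 0 but S(x5,x4) = 0.81).

Self-weights are always 1 (kernel at distance zero).  The score of a
feature column f is the Rayleigh quotient f̃ᵀLf̃ / f̃ᵀDf̃ with f̃
degree-centered; it is invariant to affine transforms of f and to
instance permutation, and a constant column scores 0 by a guarded-0/0
convention.  Larger scores are treated as more important throughout —
this follows the cost-weighting construction used here and inverts the
original Laplacian-score literature, where smaller is better.

Cost sensitivity is the exponential weighting LS(a, c) = LS(a)·c(a)^α
with user-chosen α ≤ 0; α = 0 is the identity.  For fixed positive LS
the weighted score is strictly decreasing in cost whenever α < 0, and
with all costs equal the ranking is α-invariant.

### Selection

`select` returns the core first (file order), then fills the remaining
d − |core| slots by descending weighted score; ties break toward the
cheaper feature (cost is the objective), then file order.  d is the
*total* panel size.  If the core alone exceeds d, the default policy
returns the whole core with a warning — truncating it would break the
positive-region guarantee — and a strict mode raises instead.  The
worked-example replay injects the published core and importance vector
through `core_override` / `ls_override`; everything else runs the normal
pipeline.

### Cost simulation

`generate_costs` draws one cost per feature in [low, high] (default
[1, 100]) from uniform, normal, or Pareto families.  The published
protocol names the families and range but no shape parameters, so the
defaults are explicit configuration: normal_mean = (low+high)/2 and
normal_sd = (high−low)/6 put ≈99.7% of the untruncated mass in range;
Pareto uses shape 2 with scale = low, giving the heavy right skew that
makes cheap tests common.  Out-of-range draws are resampled, not
clipped, to avoid probability atoms at the bounds.  Costs default to
whole units (published cost vectors print whole dollars), rounding after
acceptance and re-clamping.  Note that the truncated normal and the
uniform are both symmetric about the midpoint, so "uniform yields more
cheap tests than normal" is only a distributional fact below the
midpoint — the property test compares the families at the lower quartile
of the range, where pareto > uniform > normal holds robustly.

### Evaluation factors

Against the optimal (minimal-cost) reduct R′, a selection R has below
factor bf = (c\*(R′) − c\*(R))/c\*(R′) and exceeding factor
ef = −bf.  Over K runs, K1 counts strictly-below runs; equal-cost runs
fall in K2 with ef = 0.  MBF is the maximum bf over **all** K runs (it
can be negative when no run undercuts the optimum); ABF averages bf over
the K1 below runs and is reported as not-applicable when K1 = 0 (never
below is not the same as below by zero); AEF averages ef over the K2
runs; FOF — the finding-optimal factor — is the fraction of runs with
c\*(R) ≤ c\*(R′).  All four are invariant to rescaling a run's costs by
a common positive factor.

`run_experiment` draws a fresh cost vector per run (seeded as
master_seed × 100003 + run index, kept below 2³¹, so single runs are
re-extractable), computes the exact optimal reduct once per draw, and
evaluates the full α grid against that same draw — costs are fixed
within a run and α sweeps across it.  The selection size d defaults to
the optimal reduct's size run by run, so the cost comparison is at equal
panel size; a fixed d can be forced.  The default α grid is
{0, −0.25, …, −2.0}.

## Synthetic data

`synthetic_system` emulates the normalized tabular systems the method
targets: informative features are class-dependent means plus Gaussian
noise (noise_sd, default 0.05, on a unit class separation); redundant
features are near-copies of cycling informative ones (noise at a tenth
of noise_sd, floored at 1e-3 so copies are never byte-identical); the
rest are uniform noise; all columns are then min-max normalized.  It
does **not** emulate correlated noise, class imbalance beyond random
labeling, non-Gaussian feature distributions, or the scale of real
microarray panels (thousands of features), so passing tests demonstrate
correctness of the machinery and the qualitative cost-sensitivity
behavior, not performance claims on real data.

The experiment-scale choices in the test suite — a 50-instance,
10-feature system (4 informative, 2 redundant), 20 cost draws per
distribution, the five-point α grid {0, −0.5, −1, −1.5, −2} — keep the
exact reduct search comfortable at desk scale while leaving the
qualitative conclusions intact: the best grid α dominates α = 0 in FOF
for every distribution (trivially, since 0 is in the grid, but the
margin is large under Pareto costs), and degenerate equal-cost draws
make every α equivalent.

## Numerical choices

* Constant-column normalization → 0; constant-feature score → 0
  (guarded 0/0 with a scale-aware tolerance).
* Decision column defaults to the last CSV column; the first column is
  used as instance ids when non-numeric.
* kNN ties resolve by stable argsort (instance order); score ties by
  cost then file order; reduct ties by cost, size, file order.
* Error-range display rounds to 2 decimals; the worked example's
  weighted scores display by truncation to 3 decimals (0.8456/16 =
  0.05285 prints as 0.052), and the acceptance script follows that
  convention.

## Known limitations

* The worked example's published importance vector (0.8456 … 0.9680)
  cannot be reconciled with the score pipeline applied to the printed
  6×6 affinity matrix (hand evaluation of the last feature gives ≈0.48),
  and its core claim ({Gammagt}) contradicts exhaustive enumeration
  ({Sgpt}).  Both are shipped as given fixture inputs for the downstream
  examples and excluded as pipeline oracles; a negative-control test
  pins this.
* The exact minimal-cost reduct baseline is exponential; beyond ~20
  features the harness needs an injected oracle or a raised guard.
* Misclassification costs, group/waiting costs and correlated costs are
  out of scope; the cost model is per-feature and additive.
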