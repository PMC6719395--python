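# Methods

## The model

Bulk DNA sequencing of a tumor yields, for each of `n` somatic mutations and
each of `m` samples, a frequency `f[p][c]` — the fraction of cells in sample
`p` carrying mutation `c`.  Under the two-state perfect phylogeny (infinite
sites) model the evolutionary history is a rooted tree `T` on the `n`
mutations: each vertex introduces exactly one mutation, none is ever lost,
and the clone at vertex `c` carries precisely the mutations on the
root-to-`c` path.  Writing `B` for the `n x n` binary genotype matrix whose
row `c` is that path set, and `U` for the `m x n` matrix of clone
proportions per sample (rows summing to at most 1, the remainder being
normal cells), the observed frequencies are `F = U B`.  The inverse
problem — given `F`, find `(U, B)` — is the perfect phylogeny mixture
problem, and it is typically non-unique: this package's purpose is to
characterize, count, enumerate, sample and shrink the full set of solutions
rather than return one of them.

Two structures drive everything:

- **Ancestry graph.**  `G_F` has an edge `(c, d)` iff `f[p][c] >= f[p][d]`
  in every sample.  Any solution tree must be a spanning arborescence of
  `G_F`, because in a perfect phylogeny an ancestor's frequency dominates
  each descendant's in every sample.
- **Sum condition.**  A spanning arborescence `T` of `G_F` is a solution iff
  in every sample each mutation's frequency is at least the sum of its
  children's frequencies.  The mixture then is
  `u[p][c] = f[p][c] - sum_{d child of c} f[p][d]`, which is the unique `U`
  with `F = U B(T)`; the sum condition is exactly nonnegativity of `U`.

Both facts are standard in the tumor-deconvolution literature; the package
implements them as checkable contracts (`verify_solution` re-derives
`F = U B` entrywise in rational arithmetic).

## Exact arithmetic

Frequencies are held as `fractions.Fraction` throughout.  The ancestry
relation and the sum condition are order relations with meaningful ties
(equal columns, a parent exactly equal to the sum of its children), and
floating point is precisely wrong at ties.  Decimal strings parse exactly;
floats are interpreted through their shortest round-trip decimal.  The TSV
writer emits a terminating decimal when one exists and `p/q` otherwise, so a
write/read cycle is lossless.  A comparison tolerance `tol` (default 0) is
threaded through graph construction and sum-condition checks for users with
noisy inputs; the default assumes error-free frequencies, which is the
regime all of the package's guarantees are stated in.

On the sampling hot path the sum condition is evaluated in floating point
with an exact rational re-check whenever the minimum slack falls within
1e-9 of zero.  Since the two evaluations can only disagree inside that band,
the fast path never misclassifies a tree.

## Counting

The number of spanning arborescences of `G_F` rooted at `i` is
`det(L_i)` where `L_i` deletes row and column `i` from the in-degree
Laplacian (directed matrix-tree theorem); the total over all roots is an
efficiently computable upper bound on the number of solutions.  When `F` has
no repeated columns `G_F` is a DAG with a unique source and the count
collapses to the product of non-source in-degrees (a topological ordering
triangularizes the reduced Laplacian).  Determinants use fraction-free
Bareiss elimination over Python integers: counts are combinatorial
quantities and are reported exactly at any size, where a floating
determinant of even a 13-vertex Laplacian would already be suspect.
Repeated columns produce 2-cycles in `G_F`; the general counter then reports
the per-root breakdown as well, since arborescences with different roots are
genuinely different solutions there.

## Enumeration

Arborescences are enumerated by growing a partial tree from each candidate
root and branching on a single admissible frontier edge: first every tree
containing it, then every tree avoiding it (a reachability check prunes
branches that can no longer span).  The two branches partition the tree set,
so each arborescence appears exactly once, and a fixed vertex ordering makes
the stream deterministic.  Solution enumeration maintains the per-vertex,
per-sample slack as the tree grows; slack only decreases when children are
attached, so a partial tree with negative slack anywhere can be discarded
without losing solutions.  Tests verify both soundness and completeness of
the pruning against the unpruned filter, and verify stream cardinalities
against the matrix-tree counts.

Enumeration is exponential in the worst case and solution counting is
#P-complete, so `count_solutions` is guarded by `max_n` (default 13, the
largest size in the simulation protocol); exceeding it is an explicit user
decision, not a silent stall.  Canonical tree identity — used for
deduplication, dictionary keys and uniformity tests — is the sorted
(child, parent) label vector, which determines the rooted tree uniquely.

## Uniform sampling

For the generic single-source DAG case, assigning every non-root vertex a
uniform random in-neighbor as parent yields a uniform spanning arborescence
in linear time.  For cyclic ancestry graphs a root is first drawn with
probability proportional to its exact arborescence count (the counting
module makes these exact integers cheap at these sizes), then Wilson's
cycle-popping / loop-erased-walk algorithm on the reversed graph produces a
uniform arborescence with that root; marginally the draw is uniform over all
arborescences over all roots.  Rejection against the sum condition then
gives exactly uniform samples from the solution set, with expected
acceptance rate `#solutions / #arborescences`.  That ratio decays rapidly
with `n` (empirically around 1e-2 at n = 11 and as low as 1e-10 by n = 21),
which is why the sampler carries a trial budget (default 1e7) and fails
loudly with the estimated fraction rather than hanging; rejection sampling
is a small-`n` instrument, and no efficient almost-uniform sampler can exist
for this problem unless RP = NP.

The chi-square audit (`uniformity_chi_square`) tests observed tree counts
against the uniform distribution over a given support (degrees of freedom
`|support| - 1`, unobserved support trees contributing their expected
count).  Observations outside the support are excluded from the statistic
and reported separately as incorrect solutions — the shape in which samples
imported from external MCMC tools can be audited too.  The test warns below
the standard expected-count-of-5 rule.  The `SamplingReport` produced by
`rejection_sample` records its chi-square against the *observed* support;
the sharper audit against an enumerated solution set is a separate call.
All stochastic entry points take a single seeded NumPy generator, and seeds
are recorded in reports and manifests; seeded runs are bit-reproducible.

## Constraints

A long-read pair must be ancestrally comparable in an admissible tree; an
error-free single cell exposes one clone's full mutation set.  For cells two
readings ship: `root_path` (default; the set must equal a root-to-vertex
path, which is what an error-free clone genotype is under the model) and the
weaker `chain` (pairwise comparability only), because published narratives
are consistent with either.  `root_path` implies `chain`, and the simulator's
cells satisfy both.  Constraints are applied as post-hoc filters over
enumerated or sampled solution sets — correctness first; pushing pair
comparability into enumeration pruning is possible (it is monotone under
tree growth) but not needed at enumerable sizes.  Error models for noisy
single-cell/long-read data are out of scope; semantics are error-free.

## Simulator

The generator reproduces the study conditions the package's experiments
use: for each `n` in {3, 5, 7, 9, 11, 13}, 10 replicate trees; for each
tree, bulk sample counts `m` in {1, 2, 5, 10}; 240 instances in total.
Within a replicate the same tree and clone proportions are reused across all
`m`, isolating the effect of sampling density.

Choices the protocol leaves open, fixed here and documented:

- **Topology law**: uniform over the `n^(n-1)` labeled rooted trees (uniform
  Pruefer sequence + uniform root).  Least-informative and reproducible; it
  is a swappable component, and quantitative curve *levels* from other
  generators are not expected to match — the package's tests assert the
  monotone trends, not levels.
- **Clone proportions**: symmetric Dirichlet with concentration 1 (flat on
  the simplex), rationalized onto denominator 1e6 with every clone kept at
  least 1/1e6 and the total exactly 1, so all downstream identities hold in
  exact arithmetic.
- **Bulk samples**: clones are assigned to `m` parts uniformly at random,
  rejecting assignments with an empty part; proportions are renormalized
  within each part, so each mixture row sums to exactly 1 (no normal-cell
  fraction — the protocol normalizes fully; a contamination parameter could
  scale rows down but is not part of the protocol).  When a caller requests
  `m > n` through the batch driver, the effective sample count is capped at
  `n` (the finest partition, each sample a single clone); `mix_bulk_samples`
  itself rejects `m > n`.
- **Constraint draws**: cells sample a clone proportional to its overall
  proportion and report its root path; long-read pairs are drawn uniformly
  without replacement from the truth tree's comparable pairs.  Both are
  consistent with the truth by construction, so filtering can never
  eliminate the generating tree — a property the tests rely on.
- **Read counts**: error-free export at fixed depth `d = 1,000,000` per
  entry with `a = round(f * d)` (round-half-even: deterministic and
  unbiased).  No binomial resampling — the export targets the error-free
  regime where a likelihood method's optimum is the true `F`.

What the simulator deliberately does not emulate: sequencing noise and
coverage variation, mutation clustering errors, copy-number aberrations,
violations of infinite sites, interval-valued frequencies.  Green tests
therefore certify the combinatorics and the samplers under the model's
assumptions, not robustness to real-data error; on real data one would
cluster mutations and propagate frequency uncertainty before using these
tools.

## Problem sizes in the test suite

Exhaustive enumeration in pure Python is comfortable through `n = 9` at any
`m` (an `n = 9`, `m = 1` instance has 8! = 40,320 arborescences), while
`m = 1` instances at `n` in {11, 13} have 10!–12! arborescences; the suite
therefore runs its trend experiments on the grid `n` in {3, 5, 7, 9} and
`m` in {1, 2, 5} with the protocol's 10 replicates per cell, and at
`n` in {11, 13} verifies truth-tree membership directly from the defining
conditions (arborescence of `G_F` plus sum condition) instead of by
enumeration — an equivalent, exact check.  Uniformity audits use 1e4
accepted samples per instance, the protocol's figure.

## Numerical and degenerate-input notes

- Ties are exact: equal columns yield 2-cycles and are routed to the
  general (cyclic) counting/sampling paths rather than collapsed; an
  instance whose ancestry graph has no spanning arborescence is simply
  infeasible (empty solution list, not an error).
- `branching_coefficient` is undefined for `n < 2` and raises.
- The root-draw in the general sampler uses a 62-bit uniform ticket against
  exact integer counts; the distortion is at most 2^-62 per draw.
- Internally vertices are 0-based indices aligned with the mutation-label
  order of the instance; all I/O and error messages use the labels.

## Known limitations

- Enumeration is not output-sensitive; the `max_n` guard is the interface
  to that reality.
- Rejection sampling does not scale past roughly a dozen mutations (by
  design — see the acceptance-rate decay above).
- The interval/confidence-interval variant of the problem used for real
  cohorts with uncertain frequencies is not implemented; `tol` is a blunt
  instrument by comparison.
- The chi-square audit is asymptotic; at small expected counts it warns
  rather than switching to an exact multinomial test.
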