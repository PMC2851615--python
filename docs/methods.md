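# Methods

This note records the model, the algorithmic choices, and the numerical
conventions behind `degsample`, in enough detail that results can be
re-derived and limitations judged.

## Graphicality testing

A non-increasing positive integer sequence `d_1 >= ... >= d_n` is
graphical if and only if its sum is even and `L_k <= R_k` for the relevant
prefix lengths `k`, where `L_k = sum_{i<=k} d_i` and
`R_k = k(k-1) + sum_{i>k} min(k, d_i)` (Erdős–Gallai). The implementation
never recomputes these sums from scratch. `L` uses
`L_k = L_{k-1} + d_k`; `R` uses

```
R_k = R_{k-1} + 2(k-1) - min(k-1, d_k) + #{i > k : d_i >= k},
```

where the final indicator count is read off a *crossing-index* table:
`x_k` is the position of the first entry with degree below `k` (sentinel
`n+1` when absent), built in a single histogram pass, giving
`#{i > k : d_i >= k} = max(0, x_k - k - 1)`. Because `x_k` is
non-increasing in `k`, there is an index `k*` beyond which the indicator
vanishes and the recurrence becomes crossing-free. This recurrence form is
*defined* by its contract — exact equality with the direct sums for every
`k` — and that contract is enforced by tests on random sequences up to
`n = 500` and exhaustively on all small sequences.

Checked range: the inequalities are evaluated for `k` up to the Durfee
number (the largest `k` with `d_k >= k`). For non-increasing sequences the
inequalities at larger `k` follow from the ones below the Durfee number;
the full-range variant is retained as an oracle and the equivalence of the
two verdicts is itself a test. The empty sequence is graphical (all
conditions vacuous); zero degrees are stripped at normalization and
reported as isolated nodes, mirroring the construction's removal of
exhausted nodes.

## The sampler

State: residual degrees kept sorted (ascending internally), updated by
O(1) block swaps per unit decrement; the current hub; the forbidden set
`X` (the hub plus nodes already linked to it in this phase); the records
`m_i` (allowed-set sizes) and `k̂_j` (hub residual degrees at selection).

Hub policy: always an active node of maximum residual degree, ties broken
by smallest original label. A random hub choice would also produce valid
samples, but the deterministic policy is what makes the number of
construction paths leading to a given graph exactly `prod_j k̂_j!`, hence
the weight formula exact; it is therefore fixed, not configurable.

Allowed sets. For a fresh hub (no links placed this phase, guaranteed
maximum degree by the policy) every other active node is allowed — the
Havel–Hakimi property. Otherwise the maximum fail-degree `d*` is found by
scanning a test sequence `D''`: the hub is temporarily linked to all but
the last (lowest-degree; ties resolved to the latest position) member of
its leftmost adjacency set, leaving it one stub; entries are ordered
non-increasing with forbidden-before-free among equal degrees and the hub
last. For each prefix length `k` the scan compares `L_k` and `R_k` of
`D''`:

* `L_k = R_k` (case 1): the degree of the first non-forbidden entry past
  position `k` is a fail-degree candidate;
* `L_k = R_k - 1` (case 2): the first non-forbidden entry past `k` with
  degree at most `k` is a candidate (located via the crossing index of
  threshold `k+1`);
* `L_k <= R_k - 2` (case 3): no candidate at this `k`.

`d*` is the maximum candidate, and `A` is every non-forbidden active node
with residual degree above `d*` (all of them when no candidate exists).
The scan runs over `k` up to the Durfee number of `D''` and stops at the
first case (1). Both truncations are treated as conjectures to be
enforced, not assumed: the suite checks, at every construction step over
randomized runs, that the bounded scan, the exhaustive scan over all `k`,
and a naive oracle that explicitly tests every candidate (link it, then
apply the star-constrained graphicality test: connect the hub's remaining
stubs to its full leftmost adjacency set and Erdős–Gallai-test the rest)
all agree.

Internally the production scan works on a degree histogram (no physical
re-sort of `D''`); marked entries occupy block-prefix runs, and candidate
lookups hop over those runs. `build_test_sequence` materializes the
explicit ordered sequence for inspection and testing.

Weights. `ln w = sum_i ln m_i - sum_j ln k̂_j!` is accumulated in the log
domain with `lgamma`; the integer records are kept on each sample so the
weight can be re-evaluated in exact rational arithmetic, and the two are
required to agree within 1e-9. `w = 1` exactly for unique-realization
(threshold) sequences; the all-ones sequence of length `2m` has
`w = (2m-1)!!` on every path.

Randomness: one seeded `numpy` generator per sample; uniform choice over
`A` by index. Batch sampling derives per-sample sub-seeds from
`SeedSequence(master, spawn_key=(i,))`, so runs are reproducible and
parallel-safe, and the sub-seed is recorded on the sample.

## Exactness argument, as tested

For every graphical sequence with `n <= 6` and `d_1 <= 5` the full
decision tree of the sampler is expanded with exact rational arithmetic
(an independent re-implementation using the naive allowed-set oracle):
path probabilities sum to 1; the reachable graphs equal the brute-force
realization set (ergodicity); the path count per graph equals
`prod_j k̂_j!`; and consequently `E[w · 1_G] = 1` exactly for every
realization `G`, which is the statement that weighted sampling is uniform
over the ensemble. The brute-force enumerator completes nodes one at a
time in label order (each neighborhood choice yields a distinct graph) and
its existence variant is memoized on the residual multiset; neither uses
the Erdős–Gallai criterion, keeping the oracle independent.

## Estimation

`weighted_average` is the self-normalized (ratio) importance-sampling
estimator. Log-weights are shifted by their maximum before
exponentiation, so inputs up to ~1e6 in `ln w` cause no overflow and the
estimate is invariant under rescaling all weights. The standard error is
the linearized ratio-estimator formula
`sqrt(sum omega_i^2 (x_i - mean)^2)` with normalized weights `omega`, and
the effective sample size is `(sum w)^2 / sum w^2` — both standard
importance-sampling diagnostics, supplied because the estimator itself
carries no error bars. The log-normality diagnostic is the
Kolmogorov–Smirnov distance of the standardized `ln w` sample from the
standard normal: a distribution-free score in [0, 1] chosen over
histogram-Gaussian fitting so that it can be asserted in tests (a
degenerate zero-variance sample scores 0.5, the KS distance of a point
mass). Scaling of `mean(ln w)` and `sd(ln w)` with `N` is fitted by least
squares on log-log values.

## Ensembles

Degree distributions: power law `p(k) ∝ k^-gamma` (with `gamma = 0` the
uniform distribution as a special case), binomial `Binomial(N-1, p)`
truncated below `k_min` and renormalized (the degree distribution of
Erdős–Rényi graphs), and uniform. `k_min` defaults to 1 — zero degrees
are never drawn, matching the convention that sequences are positive. The
structural cutoff policy caps the support at `floor(sqrt(<k> N))` with
`<k>` the mean of the pmf truncated at `N-1`, applied once (not iterated
to a fixed point); this one-step approximation is deliberate and
documented, as the cutoff only needs to be an O(sqrt(<k> N)) cap to
suppress degree correlations in heavy-tailed ensembles.

Sequences are `N` i.i.d. draws. A draw with odd sum or failing the
graphicality test is redrawn *wholesale* (counted separately as parity
fixes and graphicality rejections); whole-sequence redraw preserves the
i.i.d. structure conditional on acceptance, whereas repairing single
entries would bias the ensemble. A cap of 1e6 redraws guards degenerate
specifications.

## Complexity accounting

Worst case per sequence: each stub of the `j`-th hub costs `O(N_j)` with
`N_j = N - j + 1` a bound on the residual-sequence length, giving
`C(D) <= sum_j k̂_j N_j`. Since each link belongs to exactly one hub,
`sum_j k̂_j = M`, and the `j`-th hub's residual degree is bounded by the
`j`-th largest input degree; the reported bound loads the link budget `M`
greedily onto the earliest ranks (which maximizes the dot product with the
shrinking windows), and the `N·M` form is reported alongside. An
"elementary step" in the instrumentation is one residual-sequence entry
visited while building the test sequence or scanning, counted once per
link placement as the active-sequence length; measured steps are asserted
to stay below the bound.

Distribution level: the expected degree profile
`dbar_i = max{d : N P(K >= d) >= i}` (the largest degree whose expected
count of nodes at or above it is at least `i`) replaces `k̂_j`, giving the
estimate `E[C] = sum_i dbar_i (N - i + 1)`. This per-rank form is a
reconstruction built on the per-stub accounting above; it is flagged as
such in reports. Two closed-form checks pin it down: a point mass at `c`
gives `c · N(N+1)/2`, and the uniform distribution without cutoff gives
`E[C]/N^3 -> 1/3` (the Riemann sum of `(1-x)^2`), so the fitted leading
exponent over `N = 1e3..1e6` is 3 — the package's headline reproduced
value. Fits are unweighted least squares on log-log values with the
regression standard error.

## Synthetic data and what the tests show

All inputs are synthetic: ensemble draws from the three families above and
printed toy sequences. The generators emulate the degree heterogeneity of
the study conditions (heavy tails with structural cutoff, Erdős–Rényi-like
binomial degrees, dense uniform degrees) but not features of real
networks beyond the degree sequence — no degree correlations, communities,
or connectedness constraints. Passing tests therefore certify the
*sampling machinery* (exactness, weights, complexity scaling), not any
claim about real-world network structure; on real data the user supplies
the observed degree sequence and the same guarantees apply to its
ensemble.

Problem sizes used by the suite: exhaustive checks at `n <= 7` (all 1,715
bounded-degree sequences) and `n <= 6, d_1 <= 5` for decision-tree
exactness; 1,000 random sequences at `n <= 500` for table exactness; 200
sequences at `N <= 300` for rejection-free validity; 100 sequences ×
100 samples at `N = 1000` (power law, `gamma = 3`, structural cutoff) for
the log-normality diagnostic, whose KS score is required to be below
0.05.

## Numerical conventions and degenerate inputs

* Exact integer arithmetic wherever the quantity is integral (EG tables,
  weights in test mode); float tolerances only at the log-weight interface
  (1e-9) and statistical fits.
* Empty sequence: graphical; sampling returns the empty graph.
* Ties: equal degrees sort by ascending original label at normalization;
  the "last" leftmost-set member under degree ties is the latest position
  in the test-sequence convention (forbidden-before-free, then position).
  Tie conventions only affect which of several exchangeable nodes is
  temporarily linked, never the resulting allowed set.
* Edge lists are emitted 0-based with `u < v`, rows sorted
  lexicographically — a bit-exact output contract used by the CLI
  determinism tests.

## Known limitations

* Undirected simple graphs only: no bipartite/directed (Gale–Ryser)
  variants, no multigraphs, no connectedness or adjacency-functional
  constraints (the construction could accommodate them in principle; not
  implemented).
* The sampler is biased by design; observables must be computed through
  the weighted estimator. For sequences with very broad weight
  distributions the effective sample size can be much smaller than the
  sample count — inspect `ess` and the log-weight diagnostics.
* The configuration-model baseline is the restart-from-scratch variant
  only, used as a contrast case, not as a recommended generator.
* The structural-cutoff mean degree is the one-step truncated-pmf
  approximation described above.
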