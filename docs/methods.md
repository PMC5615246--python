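# Methods

## Estimator

apMI estimates I(x; y) for a pair of genes from their sample ranks. Both
profiles are first converted to strict permutations of {0, …, M−1}
(ties broken uniformly at random, reproducibly per gene from the run
seed), which makes both marginals exactly uniform and the whole pipeline
invariant to any per-gene strictly increasing transform — the reason no
normalisation or log-scaling convention is imposed on the input matrix.

The rank square [0, M)² is partitioned adaptively. A rectangle of widths
(w_x, w_y) holding n points is quartered at the integer midpoints of its
rank intervals; the quadrant counts n₁…n₄ are tested against local
uniformity with T = Σ (n_q − n/4)² / (n/4), and the quadrants are
refined further only when T exceeds `chi2_crit`. A rectangle is a leaf
when it is not split; a leaf contributes (n/M)·ln(n·M/(w_x·w_y)) nats —
the plug-in term with joint density n/(w_x·w_y) and marginal densities
w_x/M, w_y/M, both exact under uniform marginals. The total is clamped
at zero, since finite-sample leaf terms can sum slightly negative.

Two structural choices matter:

- **The root is always quartered** (when it holds at least `min_points`
  points). With strict rank marginals the root's quadrant counts are
  determined by a single hypergeometric draw (the two halves of each
  axis contain exactly ⌈M/2⌉/⌊M/2⌋ points), so the four-cell statistic
  there has one effective degree of freedom, and gating the root at the
  df-3 critical value would pass only ~0.5% of independent pairs —
  collapsing the independence null onto an atom at zero MI and making
  p-value thresholding meaningless. Unconditional first partitioning is
  also what reference adaptive-partitioning estimators do. From depth 1
  on, marginal counts inside a rectangle are genuinely random and the
  chi-square gate applies as stated.
- **Splits are at interval midpoints**, not point medians, so the
  partition geometry depends only on rank coordinates and the estimator
  is exactly symmetric under swapping x and y.

The partition frontier lives in a FIFO queue processed breadth-first.
Empty quadrants are dropped immediately (they contribute nothing), which
keeps the queue within M − 3 entries in all randomized and adversarial
trials exercised by the tests; the traversal order is immaterial — a
depth-first recursion gives the identical value, which the test suite
asserts against an independent recursive implementation to 1e-10.

Defaults: `chi2_crit = 7.815` (χ², df 3, α = 0.05) and `min_points = 8`,
the canonical adaptive-partitioning constants; both are exposed
parameters. MI is reported in nats (natural log); a bits mode would be a
constant rescale and is deliberately omitted.

## Null model and threshold

Each gene row is shuffled independently across samples, destroying all
gene–gene dependence while preserving marginals; n₀ (TF, gene) pairs
(TF ≠ gene, drawn uniformly with replacement from the hypothesis space
actually tested) give the null MI sample. The threshold at p ≥ 1/n₀ is
the smallest observed null value whose empirical survival is ≤ p. For
p < 1/n₀ (the pipeline default p = 10⁻⁸ with n₀ = 10⁵ needs this) a line
is fitted by least squares to ln S(mi) over the largest ⌈n₀/1000⌉
(minimum 50) distinct upper-tail values and solved for the cutoff,
floored just above the observed maximum. The tail-width rule is fixed so
runs are reproducible. When the null is degenerate (tiny M can clamp
every null MI to zero) no tail model exists and sub-resolution p-values
fall back to the empirical maximum.

The threshold is computed once on the original matrix and reused across
bootstraps; a flag (`null_per_bootstrap`) enables per-resample
recomputation for sensitivity checks.

## Pruning

Thresholding sets the Boolean mask to `mi >= threshold`, leaving MI
values untouched. DPI then examines every unordered TF pair plus gene
whose three edges all survive in the *input* mask and marks edge e for
removal iff mi(e) < min(other two) · (1 − tolerance), strictly. All
removals are decided against the input snapshot and applied at the end,
so the result is independent of triangle evaluation order (verified
against a shuffled triple-loop oracle) — equal-MI ties are retained,
keeping the outcome free of floating-point order effects. The default
tolerance is 0 (strict DPI); tolerance 1 disables pruning. Only
TF–TF–target triangles exist in the model: gene–gene edges are never
hypothesised.

## Bootstrap consolidation

Each bootstrap resamples the M sample columns with replacement (seed + b
for bootstrap b, so any single resample is independently reproducible;
the rank stage re-breaks the ties that duplicated columns introduce).
Surviving edges accumulate into MI-sum and occurrence-count matrices.
Consolidation enumerates the canonical edge universe — directed TF→gene
slots without self edges and with each TF–TF pair counted once (smaller
row index as regulator) — of size E = N_tf·N_genes − N_tf − C(N_tf, 2),
sets λ to (total occurrences)/E (the null that occurrences scatter
uniformly over slots), computes p(e) = P(Poisson(λ) ≥ k) for each edge
seen k ≥ 1 times, Bonferroni-corrects over the observed candidate edges
(the set actually tested — the more conservative universe), and claims
edges with corrected p < α. Claimed edges report MI as the mean of their
per-run values. The Poisson model is informative only when the edge
universe is much larger than the claimed set; at toy scale (a handful of
genes) λ saturates and nothing is claimed, so tests and examples pad the
universe with unregulated genes.

## Synthetic data

`generate_grn` draws each TF→target edge independently with probability
`density`, assigns link weights uniform in [0.6, 1.0] (strong enough to
be detectable at a few hundred samples without saturating), and wires a
`cascade_fraction` of TFs as middle nodes fed by a root TF, recording
the (t1, t2, g) triples whose shortcut is absent. `simulate_expression`
draws root TFs i.i.d. standard normal per sample and each regulated node
as link(Σ w·regulator) + N(0, noise_sd²); the wiring is acyclic by
construction and cyclic hand-built networks are rejected. The `sigmoid`
link is tanh — a zero-centred sigmoid, so regulated nodes stay centred
and the nonlinearity is symmetric; `linear` is the identity. Cascade
targets depend on the upstream TF only through the middle TF, so the DPI
premise holds exactly in the generating law.

What the generator does *not* emulate: count noise (negative binomial,
library size), feedback loops, combinatorial logic beyond weighted sums,
and hidden confounders. Passing tests on this data therefore demonstrate
correctness of the estimator, thresholding, pruning and consolidation
under the model's own assumptions — not recovery performance on real
RNA-seq, where unmodelled structure (shared technical factors, feedback)
can create dependences the pipeline will faithfully report as edges.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to make every
property measurable with tight Monte-Carlo error: M = 200–1000 samples,
10–20 TFs, 60–200 targets, n₀ = 10³–10⁴ null draws, 20 seeded replicates
for rate estimates. Gaussian closed-form recovery is asserted within 0.1
nats of −½ ln(1 − ρ²) (the estimator's small negative bias at high ρ and
M = 1000 is ~0.05 nats); type-I calibration within 3 Monte-Carlo
standard errors of nominal p; BFS-vs-DFS agreement to 1e-10 (pure
summation-order tolerance). Negative MI totals clamp to 0; thresholds
compare with ≥ so a threshold of 0 keeps all non-self edges; network
files are written sorted by (regulator, target) with 6-significant-digit
MI so identical runs are byte-identical.

## Known limitations

- Edge direction is conventional (TF → target), not inferred; TF–TF
  edges are undirected in substance and reported once in canonical
  order.
- The M − 3 queue bound is an observed property checked by tests, not a
  theorem of this implementation; the diagnostic `max_queue_length` is
  returned so violations would surface.
- The Poisson rate λ treats edge occurrences as exchangeable across
  slots; with very dense true networks this null is misspecified and
  consolidation turns conservative.
- Conditional MI (three-way partitioning) and closed-form null models
  are out of scope.
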