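# Methods

## Model and scope

`bnboot` works with discrete Bayesian networks: a DAG over categorical
variables, one conditional probability table (CPT) per node, joint
distribution the product of the per-family conditionals. Data are complete
categorical observations (missing values are rejected, not imputed — every
learner implemented here assumes complete data). Continuous (Gaussian)
networks, latent variables and interventional data are out of scope, as is
Markov-network (undirected-model) learning; the threshold estimator itself
is agnostic to all of this and only ever sees a confidence vector.

## Edge confidences

`bootstrap_confidences` draws m nonparametric bootstrap replicates (rows
resampled with replacement; the parametric bootstrap is not implemented),
learns one structure per replicate, and records for every unordered node
pair the fraction of replicate graphs containing it in either orientation.
Directed occurrences are counted separately per orientation but are used
only to orient the final averaged network: significance is assessed on
presence alone, because score-equivalent structures make individual edge
directions unidentifiable for score-based learners. m defaults to 500;
200 gives very similar confidences and is a reasonable economy.

Replicate b's randomness comes from `SeedSequence(master).spawn(m)[b]`, so
the full confidence set is reproducible bit for bit from the master seed and
is independent of the order (or concurrency) in which replicates run. Every
stochastic operation in the package takes one seed and derives nested
streams the same way.

## The threshold estimator

Write p̂(1) ≤ … ≤ p̂(k) for the sorted confidences of the k = N(N−1)/2
pairs, F for their empirical CDF. The ideal limiting configuration — a
consistent learner, sample size large — is a 0/1 vector whose CDF is the
one-step function F·ideal(x; t) = t on [0, 1), jumping to 1 at 1; t is the
fraction of non-significant edges. The estimate t̂ minimises the L1 distance

    L1(t) = Σ·i |F(x·i) − t| · (x·{i+1} − x·i)

with segment endpoints {0} ∪ {jump points} ∪ {1}; this sum equals the
defining integral exactly because both CDFs are step functions. L1(t) is
convex piecewise-linear, so the minimiser is the weighted median of the
segment CDF values weighted by segment widths — an exact closed form
evaluated in one pass; tests certify it against a 1e-5 grid search and the
sum against 1e6-point numerical integration of the integral form.

Numerical conventions, each of which matters at the boundaries:

- **Right-continuity.** F(x) is the fraction of confidences ≤ x. The
  quantile is the generalised inverse inf{x : F(x) ≥ t}; at t = 0 the
  infimum is unbounded below and 0.0 is returned by convention.
- **Flat optima.** When the cumulative weight hits exactly half the total at
  a segment value, every t in an interval minimises L1; the interval
  midpoint is returned (tie rule chosen here, tolerance 1e-12 on the
  half-weight comparison).
- **Strict selection.** An edge is significant iff p̂ > F⁻¹(t̂), strictly;
  the equivalent "minimum significant confidence" (the smallest p̂ above the
  cut-off) is reported for interpretability.
- **Degenerate vectors.** All-ones confidences give t̂ = 0 and select
  everything; all-zeros give t̂ = 1 and select nothing; a single distinct
  value is legal and yields all-or-nothing selection.

L2 (minimiser: width-weighted mean) and L∞ (midpoint of extreme segment
values) are provided for comparison only; L1 is the default because it does
not weight large CDF deviations more than small ones and is therefore robust
across confidence-vector shapes.

## Structure learning

The bundled learner is greedy hill climbing over single-edge additions,
deletions and reversals, scored by BDeu with equivalent sample size (ess)
10 by default — the Dirichlet hyperparameters are ess/(q·r) for a family
with q parent configurations and r child levels, giving equal scores to
Markov-equivalent DAGs (verified exhaustively over all 543 DAGs on 4
nodes). Search starts from the empty graph, applies the best strictly
improving acyclicity-preserving move, and stops at a local optimum; a score
gain below 1e-9 counts as non-improving so that score-equivalent reversals
(whose gain is gammaln round-off, ~1e-13) cannot cycle. Ties are broken
canonically (addition < deletion < reversal, then lexicographic edge) for
determinism. Random restarts exist (`restarts=`) but default to 0. Family
scores are cached per (child, parent set) without eviction; at desk scale
hill climbing revisits few thousand families per run.

Greedy search carries no global guarantee: the test suite documents a
3-node dataset where plain hill climbing stops in a verified single-move
local optimum that restarts escape. Constraint-based and hybrid learners are
intentionally not implemented — any algorithm can be plugged in as a
`learner(df, seed) -> DiGraph` callable.

## Noise floor

`noise_floor` implements the permutation baseline: each replicate
independently permutes every column (destroying all dependence, preserving
marginals) and learns a single network — one network per permutation, not a
nested bootstrap. An edge is significant when its bootstrap confidence
strictly exceeds the maximum floor over all pairs. Permutation count
defaults to 100 (no canonical value exists; 100 puts the floor's resolution
at 0.01). Note a finite-sample asymmetry the tests document: on genuinely
independent data the bootstrap confidences sit slightly above the floor,
because all bootstrap replicates share whatever chance associations the one
realised sample contains, while the floor re-randomises every replicate.

## Synthetic fixtures and what they show

`random_network` stands in for the classical sparse benchmark networks:
nodes are ordered uniformly, each forward pair becomes an edge with
probability `avg_neighbours/(N−1)` (default average degree 2.5, matching
benchmark densities of 1.2–1.9 edges per node), and CPT rows are symmetric
Dirichlet draws (concentration 0.5, favouring peaked, learnable rows).
Fixtures emulate the *shape* of real benchmark networks — size, density,
discrete levels — but not their hand-crafted, logic-like CPTs, their
determinism patterns, or real biological data's measurement noise; passing
recovery tests therefore demonstrates correctness of the pipeline under
known ground truth, not field performance on expression data.

## Recovery study design

`run_simulation` runs, per (sample size, repetition) cell: forward-sample,
bootstrap-average with hill climbing + BDeu, estimate t̂, select, and score
sensitivity / specificity / accuracy against the true skeleton (directions
ignored). Ad hoc policies select p̂ > t directly — the literature convention
the estimated threshold is compared against — on the same confidence sets.
Cell means carry normal-approximation 95% intervals. The shipped study uses
a 10-node, 12-edge binary fixture, m = 100, 10 repetitions and sizes
{100, 500, 2000, 5000}: sizes chosen so a full grid runs in about a minute
on one core while spanning n/p from ~3 to ~160.

A caveat the numbers make visible: with 12 true edges among 45 possible
pairs this fixture is far denser (27%) than the classical benchmarks (7%
for a 37-node/46-edge network), and near-1 specificity is known to be a
consequence of that sparsity. On the dense desk fixture the estimated
threshold buys its large sensitivity advantage at small n (0.85 vs 0.32 for
an ad hoc 0.95 cut-off at n = 100) with visibly lower specificity, and mean
specificity/accuracy dip well below 0.9 at n = 100 under any policy. The
acceptance tests assert the sparse-regime expectations unmodified, so three
of them fail on this fixture by design rather than be weakened.

## Network file format

The BIF-subset dialect (see `bnboot.bif`) covers `network`, `variable` /
`type discrete [k] {levels}` and `probability` blocks with parenthesised
parent configurations, free-form whitespace and `//` comments. Writing uses
12 significant digits, so a write/read round trip reproduces edges exactly
and CPT entries to well under 1e-9. Parse errors carry line numbers and are
typed: syntax, undeclared variable, and arity/shape mismatches are distinct
exception classes.

## Known limitations

- Hill climbing is the only bundled learner; dense or high-arity networks
  need `max_parents` to bound runtime.
- The threshold assumes the confidence vector mixes a noise block and a
  signal block; for k very small (a handful of pairs) the weighted median
  is coarse, quantised to the observed CDF plateaus.
- No confidence interval on t̂ is provided; the estimate is known to track
  the particular sample rather than converge as n grows.
- Significance is for edge presence only, never for direction.
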