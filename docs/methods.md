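# Methods

## Model and assumptions

Expression values are modeled as jointly Gaussian, so conditional
independence is equivalent to vanishing conditional mutual information and
both MI and CMI reduce to log-determinant ratios of the sample covariance
matrix. Everything downstream inherits this assumption: the tests measure
*partial linear* dependence exactly, and capture nonlinear monotone
dependence only insofar as it shows up in covariances. The sample
covariance uses the unbiased n−1 denominator; since MI and CMI are ratios
of determinants, any common normalization cancels and the choice is purely
a documentation matter. All information quantities are in nats.

Determinants below 1e−300 are treated as degenerate covariance and raise
an error rather than producing ±inf; during skeleton pruning such errors
are caught, the edge is kept, and a warning is emitted — an untestable
edge is never silently deleted.

## Independence decision

The primary decision rule is a direct threshold θ on the MI/CMI statistic
(defaults in the benchmarks: 0.05 for 10 genes, 0.1 for 50–100 genes, 0.01
for the 9-gene SOS-scale data). A secondary mode converts the statistic to
a partial correlation ρ = sqrt(1 − exp(−2·CMI)), applies the Fisher
z-transform with n − |Z| − 3 effective degrees of freedom and tests the
two-sided p-value against a significance level; it requires n > |Z| + 3
and refuses otherwise. The threshold mode is the default because it is the
rule under which the published benchmark numbers were produced; the
p-value mode adapts to sample size but is not used by any default
pipeline.

## Discretization

The MIT score needs discrete data, so the continuous matrix is binned per
gene, equal-width (default, λ = 10, matching the [0,1]-scaled benchmark
data) or equal-frequency (λ = 9 for the 9-sample SOS shape, one value per
bin). Bins are half-open [low, high) with the final bin closed; a value on
a cut point belongs to the upper bin. Equal-frequency group sizes differ
by at most one (larger groups first) and ties are assigned by a stable
sort on (value, sample position). Constant genes collapse to a single
level with a warning. Discretization feeds *only* the scoring step; all
independence tests run on the continuous covariance model, so binning
noise never affects edge deletion.

## MIT score

Local score: 2N·MI_D(X_i; Pa_i) minus the sum of chi-square quantiles
χ²_{α,l_j}, one per parent, with degrees of freedom
l_j = (r_i−1)(r_σ(j)−1)·Π_{k<j} r_σ(k) accumulated in decreasing order of
parent cardinality (ties broken by gene order in the data) — the canonical
permutation that makes the penalty well defined. Cardinalities r count
*observed* distinct levels rather than the nominal λ, so empty bins do not
inflate penalties; unobserved configurations contribute nothing to the
empirical MI either. α defaults to 0.999: the penalty is meant to be a
stiff significance bar per added parent, and the default is exposed as a
regular parameter. A parentless node scores exactly 0, making the empty
graph the score origin. Local scores are memoized per (node, parent-set);
move deltas touch one local score for add/delete and two for reverse.

## Search

Hill climbing accepts only strictly improving moves, taking the largest
score delta and breaking ties lexicographically by (move-type, x, y), so
every trajectory is deterministic given its start. Reversals that would
close a directed cycle are excluded from the candidate set, as are
cycle-closing additions. A safety cap of 10·n² iterations exists but
greedy strict improvement terminates well before it. Restarted search runs
50 independent climbs by default (seeds seed+i) and keeps the best final
score, first-found winning ties. In orientation mode the move set is
restricted to reversals, which provably preserves the skeleton; initial
points are random acyclic orientations along a random vertex permutation.

## Hybrid pipeline

Order 0 prunes the complete graph by marginal MI and orients with
restarted reversal-only search. At order i ≥ 1, separator candidates for
an edge X–Y are all genes adjacent to X or Y in the previous order's DAG —
deliberately a superset of the common-neighbour candidates the baseline
uses. Each candidate Z is weighted by the number of undirected simple
paths starting at X or at Y on which Z sits as a chain or fork node; a
collider occurrence is not credited, because conditioning on a collider
opens rather than blocks a path. Paths are enumerated up to 4 edges by
default (configurable; exact enumeration is practical up to ~15 genes) —
short paths carry almost all the correlation a separator needs to block,
and the cap bounds the enumeration on dense graphs. The median of the
candidate weights (mean of the two central values for even counts) is the
selection bar; candidates at or above it form the selected set K. Edges
are deleted immediately within a sweep, in gene-pair order; the weights
are computed against the previous order's DAG throughout the sweep. After
each sweep the pruned skeleton is re-oriented (restart seeds offset per
order), and the loop stops at the first order where no edge has at least i
selected candidates. Because repeated orientation makes the pipeline
stochastic, headline numbers are averages over repeated runs (100 by
default in `repeated_runs`, seeded seed+1…seed+n).

Design points that were genuinely open and the choices made:

* *Path semantics of the weight.* Only chain/fork occurrences of Z credit
  its weight; blocking via an unconditioned collider is a property of the
  path, not of Z, and crediting it would reward irrelevant candidates.
* *Median with even counts* is the mean of the middle pair.
* *Orientation never deletes edges*: the constraint stage owns the edge
  set, the score stage owns directions only.
* *Immediate (not batched) deletion* within an order, for both algorithms,
  matching sequential-loop semantics of the baseline.

## Evaluation

Skeleton confusion counts partition all n(n−1)/2 unordered pairs; the
derived measures are ACC, FPR, FDR, PPV, F, MCC, TPR with zero
denominators mapped to 0 plus a warning. The subgraph-selection
probability is the hypergeometric point probability of drawing TP true and
FP false edges when picking TP+FP of all possible edges uniformly,
evaluated in log space (gammaln) so it stays finite for hundreds of genes.
Fractional averaged counts are rounded half-up to integers before this
probability, matching how the published averaged counts are reported
(8.8 → 9, 1.8 → 2).

## Synthetic data

The generator emulates the benchmark inputs: a uniform random DAG with a
fixed edge count (10 genes/10 edges, 50/77, 100/166, or the 9-gene/24-edge
SOS shape) and a linear-Gaussian structural equation model sampled in
topological order, edge coefficients with magnitude in (0.5, 1.5) and
random sign, unit noise, each gene affinely rescaled to [0,1] like the
in-silico benchmark matrices (affine per-gene maps leave MI/CMI
untouched). Coefficient range and noise level are chosen so that direct
effects are clearly detectable at a few hundred samples while indirect
correlations remain strong enough to make pruning nontrivial. What the
generator does *not* emulate: kinetic ODE dynamics, time-series
autocorrelation, measurement-noise heteroscedasticity, and nonlinear
regulation — so passing tests demonstrate correctness of the algorithms
under their own (Gaussian, linear) assumptions, not performance on real
microarray data.

## Problem sizes used in the test suite

Unit and property tests run at 2–8 genes with 10–200 samples. The
statistical checks use a 3-gene chain at n = 500 over 50 seeds; the
search-optimality check compares 50 restarts against exhaustive
enumeration of all acyclic orientations of 4-node skeletons; the
pipeline comparison runs both algorithms on twenty 10-gene/10-edge
fixtures at n = 500. These sizes keep every check exact or statistically
stable while remaining desk-scale; the original 50- and 100-gene benchmark
matrices are no longer distributed, so the corresponding published tables
are covered by the scaled property checks rather than replication.

## Known limitations

* Gaussian CMI misses purely non-monotone dependence.
* The skeleton stage is order-dependent (immediate deletion in gene-pair
  order), as in the baseline algorithm; permuting gene order can change
  results near the threshold.
* With very few samples (e.g. the 9×9 SOS shape) high-order CMI tests are
  noisy; the threshold mode does not correct for conditioning-set size.
* The hybrid's weight heuristic is evaluated on the previous order's DAG,
  which is itself a stochastic orientation; averaging over repeated runs
  is part of the method, not an optional extra.
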