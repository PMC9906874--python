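# Methods

## The distance family

All distances are transforms of a correlation `rho in [-1, 1]` between two
expression profiles:

| name | formula | metric? | absolute? |
|------|---------|---------|-----------|
| `d_a` | `1 - |rho|` | no | yes |
| `d_r` | `sqrt(1 - |rho|)` | yes (Pearson, Spearman, uncentered) | yes |
| `d_s` | `sqrt(1 - rho^2)` | yes | yes |
| `d_o` | `sqrt((1 - rho) / 2)` | yes | no — `d_o(rho=-1) = 1` |
| `d_alpha` | `sqrt(1 - |rho|^alpha)` | unverified for `alpha != 1` | yes |

"Absolute" means perfect anticorrelation maps to distance 0, the behavior
wanted when negatively co-regulated genes should cluster together.

The metric property of `d_r` rests on the normalization identity: shift
each profile to zero mean and scale to unit Euclidean norm; then Pearson
correlation is the plain dot product of the normalized vectors, and

```
sqrt(2 - 2|X.Y|) = min(||X - Y||_2, ||X + Y||_2)
```

so `sqrt(2) * d_r` is a Euclidean point-to-nearer-of-{Y, -Y} distance and
satisfies the triangle inequality by the four expansions of
`||X ± Z||` through `Y`.  Spearman is Pearson on average ranks and the
uncentered case is the same dot-product argument without centering, so both
inherit the property.  `min_norm_distance` implements the right-hand side
directly and serves as an independent oracle for the transform chain in the
tests (1,000 seeded pairs, agreement within 1e-9).

Useful exact relations, asserted as tests rather than stated as lore:
`d_r = sqrt(d_a)` elementwise; `d_s = sqrt(d_a * (2 - d_a)) >= d_r` with
equality only at `|rho| in {0, 1}`; and `d_a`, `d_r` induce identical rank
orderings of pairwise distances (the square root is monotone), which is why
min/max-based linkages cannot tell them apart (below).

Correlations are clamped into `[-1, 1]` after computation (tolerance 1e-12
for declaring a value out of range) so `sqrt(1 - |rho|)` never sees a
negative argument.  Constant profiles (zero variance, or zero norm for the
uncentered case) have no defined correlation and raise an error carrying
the item identifier; matrix-level operations report the first offender.
Spearman ties get average ranks, the standard convention.

## Triangle auditing

`audit_triangle` checks `d(i,k) <= d(i,j) + d(j,k) + tol` for every ordered
triple with `j` as the middle point, default tolerance 1e-9 — roughly eight
orders of magnitude below the slack of a genuine `d_a` violation (the
canonical three-profile example violates by 0.263), so floating-point noise
cannot masquerade as a violation.  Exhaustive mode is the default up to 200
items (~1.3M ordered triples, vectorized per middle point); larger matrices
are sampled with a recorded seed.  Violations are deduplicated to unordered
triples, keeping the maximizing arrangement.  Audits of `d_alpha` with
`alpha != 1` carry a "metric status unverified" note in the report.

## Clustering

Hierarchical clustering delegates to `scipy.cluster.hierarchy.linkage` on
the condensed distance matrix; `cut` uses `cut_tree` to obtain exactly k
clusters.  Single and complete linkage only ever select existing distances,
so any strictly increasing transform of the matrix (in particular
`d_a -> d_r`) yields topologically identical dendrograms with transformed
heights; average linkage (UPGMA) averages distances and can reorder merges.
The suite asserts both: clade-set equality for min/max linkages on 50
random datasets, and the existence of an average-linkage topology
difference at n = 25.  Tie-breaking among exactly equal merge candidates is
scipy's; ties have probability zero for the continuous inputs used here.

PAM is the classical BUILD + SWAP k-medoids on a precomputed distance
matrix: BUILD seeds with the item minimizing total distance and greedily
adds the medoid with the largest cost reduction; SWAP repeatedly applies
the single medoid/non-medoid exchange with the steepest cost decrease.
Ties break toward the lowest item index, making the default run fully
deterministic.  Single-exchange descent can stop in a local optimum even on
tiny instances (observed on ~7% of random instances with n <= 8): the
optional `n_restarts` parameter adds seeded random initializations, each
refined by SWAP, keeping the best result; with 10 restarts PAM matched
exhaustive enumeration on 200/200 small instances.  The oracle-equivalence
tests use restarts; the default remains pure BUILD + SWAP.

The number of clusters is chosen by the Calinski–Harabasz index
`CH = (SS_B / SS_W) * ((N - k) / (k - 1))`, computed on the original
profile vectors in Euclidean space (the index is defined through variances;
no distance-space variant is used).  `select_k` clusters at every candidate
k, returns the full curve, and picks the argmax; a user who prefers an
elbow reads the curve.  Degenerate candidates (zero within-cluster
variance) are skipped with a warning.  Note the Euclidean geometry makes CH
blind to sign structure: a cluster containing both a profile and its
negation has huge within-cluster variance, so on data with anti-correlated
members CH-based selection is only meaningful after orienting or on
flip-free data.

## Evaluation

ARI uses scikit-learn's `adjusted_rand_score` behind an item-set-checked
interface, and is verified against a brute-force pair-counting oracle in
the tests.  The enrichment comparison consumes two generic term -> p-value
tables, restricts to shared terms (exclusion counts are reported), counts
strict inequalities in each direction, and returns the natural log of the
count ratio: natural log because only sign and zero-crossing carry meaning
for the statistic's use; equal p-values count for neither side; a single
zero count gives signed infinity and two zero counts are an error rather
than a fake 0.  `paired_differences` reports win/loss/tie counts of `a - b`
and delegates the signed-rank test on nonzero differences to
`scipy.stats.wilcoxon` (p-value `None` when every pair ties).

## Bootstrap robustness

One experiment: resample the n items with replacement (size n), re-cluster
the resample with the same recipe, repeat `n_bootstraps = 100` times.
Duplicated draws are kept as distinct rows during clustering (their
pairwise distance is 0, which PAM and linkage handle naturally) and
collapsed to original identities for scoring.  Two scoring rules require a
convention the resampling leaves open:

* **Jaccard / dissolution** uses *sets* of original identifiers (an item
  drawn three times counts once), matching the Jaccard definition.  Each
  original class is first restricted to the items actually present in the
  bootstrap (`restrict_to_sampled`, default on) — unsampled items cannot be
  recovered and would deflate J artificially; a bootstrap where the class
  has no sampled member is skipped for that class and recorded.  Both
  thresholds are strict exactly as specified: a dissolve event is
  `J < 0.5`, and a class is dissolved when the event count is `> 40` of
  100.
* **Pair consistency** assigns each sampled item the cluster of its
  first-drawn copy, a deterministic rule under which `n2 + n3 = n1` exactly
  (co-clustered plus separated equals co-sampled).  A consequence worth
  knowing: a "together"-oriented pair (`n2 > n3`) always has ratio
  `n2/n1 > 0.5`.  `upsilon` is the product of the median together-ratio and
  the median apart-ratio over nonzero ratios; it is undefined (an error,
  not a sentinel) when either orientation has no pairs, e.g. at k = 1.

`compare_distances` runs `n_iterations = 20` independent experiments per
recipe.  Per-iteration seeds are spawned from the master seed via
`numpy.random.SeedSequence`, and both recipes receive the same per-iteration
seed, hence identical resamples — the upsilon values are paired, wins are
counted per iteration, and the paired list feeds the signed-rank test.  The
whole pipeline is a pure function of (data, recipes, seed); the test suite
asserts bit-reproducibility of the full 20 × 100 comparison.

## Synthetic data

`generate` plants k archetypes (standard-normal draws scaled to unit norm)
and emits each item as `sign * gain * archetype + noise`: gains uniform on
a strictly positive interval (default 0.5–2.0, so sign information lives
only in the flip), flips Bernoulli(`flip_prob`), noise i.i.d.
`N(0, noise_sd^2)` per entry.  Items are dealt to archetypes round-robin;
archetypes are not forced orthogonal — for moderate `n_dims` their pairwise
`|rho|` concentrates near 0, which is all the separation the tests need.
Ground truth ignores the sign, encoding the premise that anti-correlation
is co-membership.  Defaults (60 items, 20 dims, 3 clusters, noiseless,
flip-free) describe a clean recovery regime; tests and examples state their
own sizes, chosen small enough that whole suites of seeded replicates run
in seconds.  The generator emulates correlation structure only — no counts,
dropout, library-size or temporal autocorrelation effects — so green tests
certify the machinery, not performance on real sequencing data.

Problem sizes used by the shipped studies: the metric fuzz suite audits
10^4 random triples (10 dims) plus 200 random matrices (5–15 items, 3–40
dims) per correlation kind; the robustness study uses 24 items × 12 dims
with k = 3 at the full 20 × 100 bootstrap protocol.

## Known limitations

* `d_alpha` is provided for exploration; nothing here proves or disproves
  its triangle inequality for `alpha != 1`, and audits of it say so.
* Kendall correlation, missing-value handling, and enrichment computation
  itself (the evaluation module consumes ready-made p-value tables) are out
  of scope.
* PAM's default run is a local search; use `n_restarts` when the global
  optimum matters and the instance is small.
* CH-based k selection assumes Euclidean cluster compactness and conflicts
  with sign-flipped structure (see above).
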