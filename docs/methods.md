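# Methods

## The problem

Plant–frugivore networks are usually sampled by watching birds visit
fruiting plants. A visit, however, is not a dispersal event. Frugivorous
birds handle fleshy fruits in three qualitatively different ways:

* **seed dispersal** — the bird swallows the fruit whole and later
  defecates or regurgitates viable seeds (a mutualism);
* **pulp pecking** — the bird pecks pieces of pulp and drops the seed
  below the parent plant (an exploitation: no dispersal, no destruction);
* **seed predation** — the bird cracks and digests the seed
  (an antagonism).

`seednet` attaches one of these outcome labels to every link of a
quantitative visitation network, removes the non-mutualistic links
(either all of them, or only the predatory ones), and quantifies how the
network's structure changes, at the whole-network level and per species.

## Data model

A network is a plants × birds matrix of non-negative integer visit
counts `a_ij` (plants are rows everywhere). Every nonzero cell carries
exactly one outcome label and a provenance flag (`direct` observation or
`inferred`). Networks recorded as visitation *rates* are converted to
counts by multiplying the rate by the sampling time and rounding to the
nearest whole number; halves round up (`0.25 × 10 → 3`), a deterministic
convention that is pinned by tests.

Pruning zeroes the targeted cells but keeps all species rows/columns, so
a species that lost every link still exists with a zero marginal total.
Degree and interaction frequency are reported as 0 for such species
(dropping them would bias mean changes toward zero); d′, species strength
and resilience are undefined without links and are reported as missing.
Lists of fully disconnected species are recorded separately by
`PruneResult`.

### Outcome inference

When a (bird, plant) pair has no direct natural-history record, its
outcome can be inferred from the same bird's interactions with (1) a
congeneric plant, or failing that (2) a plant with the same fruit type
and seed-size class. Conflicting records are resolved by majority vote;
a tie under rule 1 is broken by the rule-2 vote, and any remaining tie
deterministically by lexicographic label order. Giving the congeneric
rule precedence over trait similarity is a convention of this package
(field practice uses expert judgment without a stated precedence), and
every inferred label is flagged in the provenance column so downstream
users can audit or re-do the inference.

## Network-level metrics

All metrics use natural logarithms; effective numbers are base-invariant.
Species with zero totals are excluded from every metric computation.

* **Size** — number of species with at least one link.
* **Weighted connectance** — quantitative linkage density
  `LD = (1/2m) [Σ_j A_j n_j + Σ_i A_i n_i]` divided by size, where
  `n_k = exp(H_k)` is the effective partner number of species `k`
  (Shannon entropy of its interaction vector) and `A` are marginal
  totals. A uniform complete matrix attains 0.5 for any shape.
* **Weighted NODF** — rows and columns are ordered by decreasing
  marginal totals; an ordered pair (richer `u`, strictly poorer `v`)
  scores `100 · #{0 < w_v < w_u} / #{w_v > 0}`, pairs with equal
  marginal totals score 0, and the index is the mean over all row and
  column pairs. Note that this is the strict-marginal convention pinned
  by this package's tests; implementations that additionally require
  decreasing *fill* (e.g. `vegan::nestednodf`) return different values
  on matrices where marginal totals decrease but fill does not.
* **H2′** — the two-dimensional Shannon entropy `H2` of `p_ij = a_ij/m`,
  standardized as `(H2max − H2)/(H2max − H2min)` and clamped to [0, 1].
  `H2max` is the entropy of the continuous marginal product
  distribution (`H_rows + H_cols`). `H2min` is found by greedy integer
  packing — repeatedly pairing the largest remaining row and column
  totals, with a second start that first consumes exactly matching
  row/column totals — refined by full-depth 2×2 moves that preserve
  marginals. Entropy is concave, so its minimum lies at a vertex of the
  transportation polytope and full-depth moves walk between vertices;
  the refined heuristic reproduces the exhaustively enumerated minimum
  on every integer matrix up to 3×3 with total ≤ 8 (exact integer
  optimization is intractable in general, hence the clamp).
* **Modularity (Barber Q)** —
  `Q = (1/m) Σ_ij [a_ij − A_i A_j/m] · 1{module(i) = module(j)}` over a
  partition of both guilds, maximized by a two-phase label-propagation
  search: each species repeatedly adopts the adjacent module label with
  the largest modularity contribution; at convergence every pairwise
  module merge is tried, each followed by re-propagation, keeping the
  best strict improvement. Restarts beyond the first randomize the
  initial column labels. The search is deterministic given a seed, the
  seed is recorded in every report, and the default is a single run with
  a `repeats` flag for multi-start robustness checks. On all integer
  matrices up to 3×3 with total ≤ 8 (six species), two restarts already
  recover the exhaustive maximum over all 203 species partitions.
  Convergence uses a modularity-gain tolerance of 1e−10 and a cap of
  10⁴ propagation sweeps, both configurable.

## Species-level metrics

* **Degree** and **interaction frequency** — row (or column) nonzero
  count and marginal total.
* **d′** — the Kullback–Leibler deviation
  `d = Σ_j p′_j ln(p′_j/q_j)` of a species' partner use `p′` from
  partner availability `q` (marginal totals of the *current* network
  state: pruned availabilities for pruned states, because every metric
  is recomputed on the post-removal network), standardized between
  integer-constrained extremes and clamped to [0, 1]. The maximum places
  the species' whole total on the rarest partner (`d_max = −ln min q`,
  the vertex maximum of a convex function over the allocation simplex).
  The minimum starts from a largest-remainder proportional allocation
  and applies steepest-descent unit exchanges; because the objective is
  separable and convex, this local search provably reaches the global
  integer minimum, and it matches exhaustive enumeration on all small
  cases. When the extremes coincide (a single available partner), d′ is
  reported as 0: the species has no room to be selective.
* **Species strength** (frugivores) — `Σ_i a_ij / A_i`, the summed
  dependencies of plants on bird `j`. Strengths sum to the number of
  linked plant species, a conservation law used as a test invariant.

## Null models and Δ-transformation

Because most metrics respond mechanically to size and marginal
structure, observed values are Δ-transformed: the mean of the metric
over an ensemble of null matrices (default 1,000) is subtracted from the
observed value.

* **patefield** — uniform tables conditional on both marginal totals,
  drawn by pairing the `m` row-labeled interaction tokens with a random
  permutation of the `m` column-labeled tokens (the multivariate
  hypergeometric distribution; cell means converge to `r_i c_j / m`).
* **quasiswap_count** — additionally preserves the number of nonzero
  cells. A Patefield draw is pushed toward the observed fill with
  2×2 submatrix updates that keep marginals fixed (full-depth moves to
  lower fill, unit moves to raise it, fill-neutral moves accepted to
  keep the chain mobile), then mixed with `10 × n_cells` fill-preserving
  unit-swap attempts. The procedure guarantees the conservation
  contract — exact marginals and exact fill — and well-mixed samples,
  not bit-equality with any other implementation; the mixing length and
  the iteration cap are configurable.

Metrics undefined on a null sample are skipped and counted; a skip rate
above 10% triggers a warning. Modularity is Δ-transformed by re-running
the search on every sample with a per-sample seed derived from the
recorded seed stream. Only Δ values (no z-scores) are reported.

## Coextinction model

Birds are removed one at a time, least-frequent first (frequency as a
proxy for abundance; ties broken by species id). A plant undergoes
dispersal failure once it has lost **at least** 75% of its original
interaction frequency — the inclusive reading matters for integer edge
cases and is pinned by a worked 2×2 example in the tests. Failure is
absorbing. The survival curve starts at (0, 1) and is recorded after
every removal; **robustness** is its trapezoidal area (in [0, 1]) and a
plant's **Resilience₇₅** is the fraction of birds removed before it
failed. For pruned states the removal order is recomputed on the pruned
network by default (an explicit order can be supplied to reuse the
original sequence). Plants with no links in a state are excluded from
the curve denominator, consistent with the missing-value policy.

## Paired comparisons

Every question is directional (e.g. nestedness is hypothesized to
*increase* when antagonistic links are removed), so all tests are
one-tailed in the hypothesized direction:

* **Wilcoxon signed-rank** on paired before/after values: zero
  differences dropped (classic convention, not Pratt), ties midranked,
  exact enumeration of the 2ⁿ sign distribution up to n = 25 (via a
  polynomial convolution over doubled ranks), normal approximation with
  tie and continuity corrections above.
* **Spearman rank correlation** between before and after values, exact
  by permutation up to n = 8, t-approximation above. The test is run
  against the positive alternative: a *non-significant* positive
  correlation flags a change in the ranking of networks or species.
* **Bernoulli-process probability** for multiple testing: the exact
  binomial point probability of observing `K` significant results among
  `N` tests at level α (α = 0.05 in the summaries).

Change tables report, per metric, the mean absolute change, the mean
percentage change, the range of changes, and a coefficient of variation
(100 · sample SD / |mean|). Species-level means are computed per network
first and then averaged across networks; species-level tests are run
both pooled across networks and separately per network.

## Synthetic study conditions

The generator emulates the statistical shape of European bird–fruit
visitation data so that the full pipeline is testable without field
data. Defaults (one "study" = 7 networks):

| parameter | default | rationale |
|---|---|---|
| networks | 7 | matches the empirical study design the pipeline mirrors |
| plants × birds | 20 × 25 | a few dozen species per assemblage |
| abundance distribution | lognormal, σ = 1.5 | strongly right-skewed abundances, skewed visit counts |
| expected total visits | 800 | several hundred visits per assemblage |
| non-mutualistic link share | uniform in [0.21, 0.48] | the qualitative prevalence envelope observed in the field |
| damping | 0.25 | non-mutualists visit fruit far less often, keeping their *frequency* share (≈ 6–24%) well below their link share |
| role flavors (pulp : predator : mixed) | 0.12 : 0.13 : 0.20 | pulp peckers and seed predators in similar numbers, plus birds whose outcome depends on the plant |
| mixed-role rule | seed size < bill gape ⇒ predation | bill morphology limits which seeds a predator can crack; the same bird disperses large-seeded plants and destroys small-seeded ones |

Counts are Poisson around an abundance-product mean (a negative-binomial
overdispersion parameter is available but off by default). Birds are
flipped to non-mutualistic roles lowest-degree first (antagonists have
narrower niches than mutualists), until a per-network target link share
drawn from the envelope is reached; at least one exclusively
non-mutualistic frugivore is guaranteed whenever pure non-mutualist
roles are configured. Labels carry synthetic provenance flags (≈27%
marked inferred).

What the generator does **not** emulate: taxonomic structure (the
concentration of dispersal in thrushes and warblers and of predation in
finches and tits), fruit-level mixed outcomes within a single link,
sampling effort variation between assemblages, and spatial structure.
Passing directional tests on this ensemble therefore shows that the
pipeline recovers the expected direction-of-change pattern under the
stated statistical structure, not that any particular field system will
show it.

## Problem sizes used in the test suite

The oracle-equivalence suites enumerate all integer matrices up to 3×3
with total ≤ 8 (≈14,600 matrices after dropping zero rows/columns, which
carry no weight). Null-model conservation is checked on 1,000 samples of
a random 10×10 matrix per model; the strength conservation law on 10⁴
random matrices; Wilcoxon type-I calibration on 1,000 null replicates of
20 pairs; and directional recovery on 50 independent 7-network
ensembles. The pipeline's default null-ensemble size is 1,000 per the
Δ-transformation definition; tests and examples use smaller ensembles.

## Known limitations

* One categorical label per link: real interactions fall on a
  mutualism–antagonism continuum, and a bird can have mixed outcomes on
  a single plant species; the package models the predominant outcome.
* Fruit removal is only the departure stage of dispersal; post-removal
  fates (deposition site, germination) are out of scope.
* H2′'s integer minimum is a refined heuristic; on large matrices it is
  a (very tight) upper bound on the true minimum, so H2′ can be
  marginally underestimated before clamping.
* The modularity search is stochastic; reported values depend on the
  recorded seed, and single-run values can sit below the attainable
  maximum on large networks (use `repeats` to check).
* The coextinction model is purely topological: no rewiring, no
  abundance dynamics, and removal of birds only.
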