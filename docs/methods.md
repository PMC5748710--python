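# Methods

## Model and procedure

`misrank` measures the association between a query gene set *Q* and each
class of a disease-gene catalog on a weighted, undirected PPI network with
integer edge confidences `S(p1, p2)` (STRING combined-score convention;
higher = the interaction is more likely).  The pipeline, per run:

1. **Load and filter.**  The network is read from the `protein.links`
   dialect; both orientations of each pair are collapsed into one undirected
   edge, and a score conflict between orientations is an error.  The query
   set and every class are passed through the same map-and-filter step: raw
   IDs are optionally translated through a user-supplied two-column table and
   genes that are not network nodes are dropped (and counted per set in the
   run metadata).  No live ID-resolution service is consulted: the mapping is
   a static input, for reproducibility and offline operation.
2. **Per-gene score.**  `MIS(g) = max{S(g, g′) : g′ ∈ Q, g′ ≠ g}`, with 0 as
   the no-edge sentinel (below the minimum real score, so an unconnected gene
   is well-defined rather than missing).  *g* is excluded from the target
   set: a gene present in both a class and the query set must not match
   itself (the network has no self-loops, so this only matters for set
   membership bookkeeping).
3. **Permutation calibration.**  `n` random node sets (default 1000) of size
   `|Q|` are drawn uniformly without replacement from the full node universe
   — query members included, since nothing in the statistic's logic excludes
   them and the widest universe is the least assumptive choice.  One
   collection is drawn per run and reused for every gene of every class, so
   p-values are comparable across classes; per-gene resampling would only add
   Monte-Carlo variance.  `p(g) = Λ/n` with
   `Λ = #{i : MIS_i(g) > MIS(g)}` — *strictly* greater, so p-values live on
   the grid `{0, 1/n, …, 1}` and `p = 0` is attainable.
4. **Class summary.**  The PT curve of a class evaluates the strict empirical
   CDF of its p-values on the threshold grid `{0, 1/n, …, 1}` (p-values only
   exist at that resolution).  The reported AUC is the exact integral of the
   step curve, `mean(1 − p)`; a trapezoid-on-grid variant is kept for
   plotting and agrees with the exact value to half the grid step.  Classes
   are ranked by AUC descending, ties broken lexicographically by name for
   determinism.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_permutations` | 1000 | random sets per run; p-value resolution is 1/n |
| `min_score`, `max_score` | 150, 999 | accepted edge-score range (validation only, configurable for non-STRING networks) |
| `report_cutoff` | 0.05 | presentation filter for the "significant genes" table; never used inside scoring |
| `seed` | — | drives the one random-set draw; identical (inputs, seed) gives byte-identical outputs |

## Known biases of the strict-greater rule

`Λ` counts only random sets that strictly beat the query MIS, so ties count
in the gene's favor.  Two tie sources exist and both deflate p-values
(inflate AUC) relative to an exchangeable-uniform null:

* **Both-zero ties.**  If the gene has no edge into *Q* and none into `D_i`,
  both MIS values are 0.  Probability ≈ `z²` with `z = (1 − π)^d`, where
  `π = |Q|/N` is the inclusion probability and `d` the gene's degree.
* **Shared-top-neighbor ties.**  If the gene's best-scoring neighbor lies in
  both *Q* and `D_i`, the two maxima coincide exactly.  Summing over the
  neighbor rank gives mass ≈ `π/(2 − π)`.

Under an exchangeable null, `E[p] = (1 − P(tie))/2`, so the expected null
AUC is `0.5 + P(tie)/2`.  At full scale (N ≈ 19 000, |Q| ≈ 342, mean degree
≈ 440: π ≈ 0.018, z ≈ 4·10⁻⁴) the bias is below 0.01 and harmless.  In a
scaled-down study it is **not** automatically small: the tie mass is set by
π and d, not by the raw edge density, so synthetic calibration studies here
use π = 0.1 and mean degree ≈ 20 (e.g. a 200-node network with a query of 20
and edge probability 0.1), where the predicted null AUC is ≈ 0.536 — matching
what the null-calibration suite measures (grand mean ≈ 0.54).  Configurations
with larger π or sparser connectivity push the null AUC well above 0.55 and
should not be used for calibration claims.  The `(Λ+1)/(n+1)` convention
would remove the `p = 0` atom and soften this, but the strict form is the
method's definition and is kept.

A corner case of the same rule: a degree-0 gene has MIS = 0 *and* every
`MIS_i = 0`, hence `Λ = 0` and `p = 0` — maximally significant despite
carrying no signal.  Degree-0 genes are vanishingly rare at the densities
used here (probability `(1−p_edge)^(N−1)`), but real sparse networks should
be pre-filtered to their connected part if this matters.

## Synthetic studies

The generator emulates the statistical skeleton the method assumes: an
Erdős–Rényi `G(N, p_edge)` background whose edges draw i.i.d. integer scores
(uniform on [150, 999] by default, minimizing score ties for clean
calibration; a low-score-heavy `skewed` sampler — Beta(1, 4)-shaped — is
available to stress tie handling), a query block, and classes whose genes
receive, independently with probability `planting_strength`, one edge to a
uniformly chosen query member with a uniform score in a configurable planted
range (default [980, 999]).  Planted edges overwrite any existing score for
the pair — a simpler invariant than max-merging.  Class/query node blocks are
disjoint by default; the non-disjoint mode draws class genes uniformly from
the non-query nodes, which is what the null-calibration study uses (20
classes × 30 genes cannot be disjoint on 200 nodes).

What the generator does *not* emulate: scale-free/hub-dominated degree
structure, correlated evidence channels, or STRING's empirical score
distribution.  Passing calibration and recovery benchmarks on these fixtures
therefore demonstrates the statistic's correctness and its behavior in a
controlled tie regime, not robustness to real-network degree heterogeneity —
on a real network, hub genes are exactly the ones the permutation test is
there to discount.

Benchmark sizes were chosen to keep the full suite in seconds while leaving
binomial noise well inside the asserted bands: null calibration uses 10
replicate studies of 20 classes × 30 genes (6 000 gene-level p-values, 200
permutations each); planted recovery uses 50 replicates of 5 classes × 20
genes at strengths 0–1 on 300 nodes (query 30, edge probability 0.1 — the
same π = 0.1 tie regime).  With 1 000 gene measurements per strength, the
~0.11 AUC separation between adjacent strengths is ≈ 10 standard errors.

## Numerical and design choices

* AUC is computed in closed form (`mean(1 − p)` over sorted values, making
  the result bit-identical under input reordering); the grid-trapezoid
  variant exists only for plotting and back-compatibility.
* The published headline AUC this method reproduces at full scale (0.9621
  for the nutritional class) is checked to ±0.005, absorbing the unknown
  discretization of the original curve-area computation.
* Random sets are materialized both as ID tuples (the API contract) and as a
  boolean membership matrix; per-gene MIS over all sets is one masked
  row-max, which keeps 1000-permutation runs on the full STRING network
  tractable in pure numpy.
* The node universe is sorted before sampling, so results are independent of
  iteration order of the underlying graph container.
* Header detection in the links dialect: a first line whose last field is
  non-numeric is a header.  Bounds [150, 999] are defaults, not laws — the
  loader takes explicit bounds, and validation can be relaxed entirely.
* Empty-after-filtering classes yield a warning and an empty record list and
  are ranked last (NaN AUC); an empty-after-filtering query set is fatal.

## Limitations

* The p-value is anti-conservative under ties (above); between-class AUC
  differences carry no confidence statement, and no multiple-testing
  correction is applied across classes — the AUC ranking is descriptive.
* MIS uses a single best edge: a class gene with many medium-score links to
  the query set scores lower than one with a single high-score link, by
  design of the statistic.
* Random sets ignore degree structure; a degree-preserving null would answer
  a different (also interesting) question and is out of scope.
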