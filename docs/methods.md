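# Methods

This note documents the models implemented in `xtrait`, the choices made
where conventions differ, and what the synthetic-data tests do and do not
demonstrate.

## Interactome representation

Networks are undirected graphs of opaque, case-sensitive node identifiers
read from edge lists or SIF. Self-loops are dropped (with a count),
duplicate undirected edges merged, and weights must be positive (default
1.0). No gene-symbol normalisation is attempted: mapping variants or probes
to genes is assumed to have happened upstream, and all set operations are
exact string matches. Edge weights are carried but only consulted by
operations documented as weighted (node strength, PageRank); distances are
always unweighted hop counts, because interaction-confidence scores are not
metric lengths and no principled conversion exists.

## Module detection

Three detectors produce candidate decompositions; all are deterministic
(lexicographic node order everywhere, no hidden RNG).

**MCODE.** Each node is weighted by its core-clustering coefficient: the
density of the highest k-core of its closed neighbourhood times that core's
k. Complexes grow outward from the highest-weight unvisited seed, admitting
neighbours whose weight exceeds `(1 − vwp)` times the seed weight
(`vwp = 0.2`). Complexes without a 2-core are discarded; `haircut` (default
on) strips singly-connected members, `fluff` (default off) re-adds dense
neighbourhoods and may create overlaps. Complexes are scored by
density × size. Defaults follow the algorithm's published plugin
conventions since the analyses this package supports rarely report them.

**Markov clustering.** Flow simulation on the column-stochastic adjacency
matrix with unit self-loops: expansion (matrix power 2), inflation
(entrywise power 2.0 with column renormalisation), pruning below 1e−5,
until the largest entry change is below 1e−8 or 100 iterations (the result
then carries `converged=False`). Clusters are read off attractor rows; a
node attracted by several rows joins the one with most flow.

**Greedy modularity.** Newman's fast-greedy agglomeration maximising
`Q = Σ_c (e_c/m − (d_c/2m)²)`, unweighted. This is the community-detection
core of the GLay workflow; implementing the objective directly avoids any
GUI dependency while optimising the identical quantity.

For the two disjoint-cover methods, modules smaller than
`min_module_size = 3` go to `unassigned` (multi-gene modules are the object
of interest; pairs and singletons carry no within-module structure).

## Entropy-based method selection

Network structure entropy is `E = −Σ I_i ln I_i`, `I_i = k_i/Σ_j k_j`, over
nodes of positive degree, natural log. `E` is permutation-invariant,
invariant to uniform weight scaling, maximal (`ln N`) exactly for regular
graphs, and undefined on edgeless graphs (an error, not 0).

Applying `E` to a *decomposition* requires choosing the graph it is
evaluated on, and published descriptions are usually silent here. Three
variants are implemented and reported:

* `module_union` (default): `E` of the graph formed by all within-module
  edges over all assigned nodes. Methods that keep fewer, denser nodes score
  lower, which reproduces the characteristic ordering in published
  comparisons (complex-detection < flow/modularity partitions);
* `per_module_mean`: mean of `E` over each module's induced subgraph;
* `global`: `E` of the whole network — method-independent, reference only.

`select_method` takes the argmin; ties break in the fixed order
mcode → mcl → greedy with a warning.

The **main module** of a decomposition aggregates three per-node metrics
over each module — weighted degree (node strength), normalised betweenness
and PageRank (damping 0.85, tolerance 1e−10) — all computed on the full
disease network so modules are compared in context. Aggregation is a sum by
default (mean available): a module's influence grows with both member
importance and size. If one module is rank-1 under all three metrics it
wins; otherwise each candidate is scored by its characteristic path-length
disturbance — |Δ| of the mean shortest-path length over reachable pairs of
the union-of-modules subgraph when the candidate's nodes are removed — and
the maximum disturbance wins. A candidate whose removal leaves fewer than
two reachable pairs scores +inf and is flagged as disconnecting.

## Network proximity

The asymmetric closest distance `d(X,Y)` averages, over y ∈ Y, the hop
distance to the nearest member of X; the symmetric `d_AB` averages the
nearest-cross-set distance over both directions, and
`s_AB = d_AB − (d_AA + d_BB)/2` with `d_AA` the mean nearest-other-member
distance (singletons give 0). Unreachable pairs are excluded and counted
rather than imputed with diameter+1: imputation moves `s_AB` discontinuously
near 0, exactly where the overlap/separation call is made.

The z-score standardises the observed `d(X,Y)` against a null of randomly
redrawn sets of the same sizes. By default the draw is degree-preserving:
nodes are binned by `floor(log2(degree+1))`, sparse bins merged upward until
each holds ≥ 10 nodes, and each replacement set matches the original's
per-bin counts. 1000 draws by default. Uniform sampling is available by
flag for sensitivity; both the degree-matched and uniform nulls are standard
in the disease-module literature and neither is canonical. The empirical p
uses add-one smoothing, `p = (1 + #{null ≤ obs})/(1 + n_perm)`. Because hop
distances are heavily tied, this convention is *conservative* (p-values are
stochastically larger than uniform under the null) — a validity property the
tests assert explicitly; exact uniformity is unattainable for a discrete
statistic without randomised tie-breaking.

## Cross-trait statistics

Per-SNP z-scores across K traits combine into the sample-size-weighted
`S_Hom = (Σ √n_k z_k)²/Σ n_k` (χ²₁ under the null). The heterogeneity-robust
`S_Het` maximises `S_Hom` over the nested subsets `{k: |z_k| ≥ τ}` for τ in
the observed |z| values (the full set is always a candidate, so
`S_Het ≥ S_Hom` holds by construction). Its null is calibrated by direct
Monte-Carlo simulation of independent standard normals under the same
maximisation (100,000 draws by default, shared across SNPs). Because an
empirical p cannot fall below `1/(n_sims+1)`, statistics exceeding every
null draw fall back to the Bonferroni bound `K · χ²₁-tail(S_Het)` — an upper
bound on the true p, so the far tail remains conservative while genuinely
extreme SNPs can still clear genome-wide thresholds. Trait independence
(no sample overlap) is assumed; with overlapping cohorts the z-scores would
need decorrelation first.

Clumping is greedy PLINK-style: index SNPs visited by ascending p below
`p1 = 5e−8`, each absorbing SNPs with p < `p2 = 1e−5` within 500 kb and
r² > 0.2 (r² consumed as a precomputed lookup; missing pairs count as 0 —
computing LD from genotypes is out of scope). The shared-SNP rule keeps
SNPs whose single-trait p beats 1e−5 in *every* trait (the stricter reading
of "shared"; an `any` rule is available) and whose meta p beats 5e−8, all
strict inequalities.

## Colocalisation

Per SNP and trait, Wakefield's approximate Bayes factor with `z = β/se`,
`V = se²`, `W = sd_prior²`:

    log ABF = ½[ln(V/(V+W)) + z²·W/(V+W)] .

`sd_prior = 0.15` (quantitative-trait convention; 0.2 is typical for
case-control traits and available via argument). Under the single-causal-
variant assumption the five hypothesis sums are enumerated with priors
`p1 = p2 = 1e−4`, `p12 = 1e−5` and accumulated in log space (|z| up to ~40
occurs in real summary data; naive sums overflow). Posteriors are
renormalised to sum to one exactly; `PPH4 > 0.95` sets the `colocalised`
flag. Regions/windows are caller-defined; no LD-aware or multi-causal
extension is attempted.

## Mendelian randomisation

Instruments: SNPs with exposure p < 5e−8 (strict), clumped at r² ≤ 0.001
within 10,000 kb when an r² lookup is supplied (p-filter only, with a
warning, otherwise). Harmonisation aligns the outcome to the exposure's
effect allele: direct match kept, allele swap flips `β_y`, strand
(complement) flips resolved the same way; palindromic A/T and G/C SNPs are
dropped unless both allele frequencies lie outside 0.5 ± 0.08, in which case
orientation is inferred by frequency matching; irreconcilable allele pairs
are dropped. Every decision is recorded per SNP.

* **IVW**: `θ̂ = Σw β_x β_y / Σw β_x²`, `w = se_y⁻²`; fixed-effect
  `SE = (Σw β_x²)^−½`, inflated multiplicatively by `max(1, √(Q/(J−1)))`
  when Cochran's Q has p < 0.05 (overridable). One instrument degrades to
  the Wald ratio with a warning.
* **MR-Egger**: weighted regression of `β_y` on `β_x` with intercept,
  exposure effects oriented positive. SEs use the estimated residual scale
  `RSS/(J−2)` and t(J−2) p-values — this matches a generic WLS fit exactly
  and gives exactly calibrated intercept p-values under normal errors; a
  `max(1,·)` truncation of the scale would make them conservative.
* **Weighted median**: ratio estimates ordered ascending, inverse-variance
  weights normalised, estimate interpolated at cumulative weight 0.5 using
  the `S_j − w_j/2` midpoints; SE by parametric bootstrap (1000 draws).
* **Weighted mode**: argmax of the weighted normal-kernel density of the
  ratios; bandwidth `0.9 · min(weighted 1.4826·MAD, weighted SD) · J^{−1/5}`
  scaled by a user factor; bootstrap SE.
* **Cochran's Q** on the IVW fit, df = J−1.
* **MR-PRESSO**: observed RSS takes each SNP's weighted residual against
  the IVW fit of the other J−1 SNPs; the null is 1000 parametric simulations
  (β_x and β_y redrawn at their standard errors around the no-pleiotropy
  fitted values) with leave-one-out slopes re-fitted per simulation. The
  per-SNP empirical p is Bonferroni-adjusted across J (note the floor
  `J/(n_sim+1)`: detecting outliers at α = 0.05 with J = 50 requires
  n_sim ≥ 1000, hence the default). The distortion test compares the
  estimate shift after outlier removal against removals of random subsets of
  the same size (1000 draws).
* **Multivariable IVW**: weighted multiple regression of `β_y` on the
  exposure-beta matrix, no intercept, over the union of instruments
  harmonised by allele-swap sign flips; rank-deficiency raises an error
  naming the collinear exposures. The same Q-triggered inflation rule as
  univariable IVW on J−K df makes the single-exposure case an exact
  reduction.
* **F statistics**: `F_j = (β_x/se_x)²`, with a warning when the mean is
  below the conventional threshold of 10.

Outcome betas are treated as log-odds for binary outcomes; every fit exposes
`OR = exp(β)` with the exponentiated CI.

## Synthetic data

The generators are pure functions of (parameters, seed) and serialise their
ground truth alongside the data.

* **Interactomes**: stochastic block models, default 4 blocks × 25 nodes
  with `p_in = 0.3`, `p_out = 0.02` — dense enough for communities to be
  identifiable, sparse enough that detection is non-trivial, and sized so
  that permutation nulls and repeated detection runs stay fast.
* **Target pairs**: drawn from one block with an exact planted member
  overlap, or from two distinct blocks for separated pairs.
* **MR instruments**: default J = 50 and true effect θ = 0.3; exposure
  effects `~N(0, 0.05²)` truncated away from 0 (keeps Wald ratios finite)
  and boosted so observed exposure associations are genome-wide significant
  (per-instrument F around 40–100, comparable to well-powered published
  analyses); `se_y = 0.05`, `se_x = se_y/5` (two-sample designs typically
  have better-powered exposure GWAS). Directional pleiotropy and outlier
  shifts are planted *per exposure-increasing allele* (i.e. with the sign of
  β_x): pleiotropy defined relative to an arbitrary allele labelling would
  cancel under the orientation every estimator applies and be unrecoverable
  by construction. A configurable fraction of SNPs receives palindromic
  alleles with ambiguous (0.45–0.55) frequencies so harmonisation drops
  them.
* **Colocalisation regions**: 100 independent SNPs, causal |z| = 10, equal
  standard errors; scenarios null / shared / distinct.

What passing these tests shows — and does not. The generators reproduce the
statistical structure the methods operate on (community structure with
degree heterogeneity, effect/SE pairs with consistent p-values, shared or
distinct causal configurations) under the methods' own assumptions. They do
not simulate linkage disequilibrium, allele-frequency spectra, sample
overlap between traits, winner's-curse selection of instruments, or
interactome ascertainment bias. Recovery on synthetic data therefore
validates correctness of the implementations, not robustness of the methods
to those real-data violations.

## Numerical and degenerate-input conventions

* Entropy of an edgeless graph, proximity of fully disconnected sets,
  MR with zero instruments, colocalisation with < 2 shared SNPs: errors,
  never silent sentinel values.
* p = 0 in GWAS input is clamped to the smallest positive float (public
  summary files contain underflow); se ≤ 0 or p outside (0,1] drops the row
  with a count.
* All hypothesis/configuration sums in colocalisation use log-sum-exp.
* Empirical p-values use add-one smoothing throughout and are never 0.
* Ties: method selection by fixed method order; weighted-median exactly at
  a midpoint returns the boundary ratio; module metric ties resolve to the
  lower module index; all iteration orders are sorted.

## Problem sizes

The shipped tests and the acceptance script use 100-node interactomes with
1000-draw permutation nulls, 50-instrument MR panels with up to 500
replicate datasets, 100-SNP colocalisation regions and 100,000-draw
Monte-Carlo calibrations — sizes at which every stochastic check is stable
across seeds while the full suite completes in well under a minute of
compute per stage.

## Known limitations

* LD is consumed, never computed: clumping degrades to p-filtering without
  a user-supplied r² lookup, and colocalisation assumes independent SNPs.
* CPASSOC-style correlation handling for overlapping GWAS samples is not
  implemented; traits are assumed independent.
* Single-causal-variant colocalisation only (no SuSiE-style extension).
* The entropy-on-decomposition variant is a documented choice, not a
  community standard; all three variants are reported for transparency.
* MCODE's `fluff` step can produce overlapping complexes, which downstream
  per-module statistics handle by first-containing-module assignment.
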