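# xtrait

Tools for asking whether two complex traits are linked — on the interactome
and in the genome. `xtrait` implements, in one tested Python package, the
analysis pipeline commonly used to relate a metabolic phenotype to a family
of diseases: partition each disease's protein–protein interaction (PPI)
network into functional modules and pick the best partition by minimum
network structure entropy; quantify how close two sets of disease targets
sit in the interactome (separation score and permutation z); filter GWAS
summary statistics for cross-trait shared loci; test whether a shared locus
reflects one causal variant (Bayesian colocalisation); and estimate causal
effects by two-sample Mendelian randomisation with a full sensitivity
battery. A synthetic-data module generates every input with known ground
truth, so the whole pipeline is exercisable and testable without any
external database.

It is written for computational biologists and genetic epidemiologists who
have an edge-list network, gene sets and per-trait GWAS summary tables and
want a scriptable, reproducible alternative to chaining web tools.

## The quantities it computes

**Network structure entropy.** For a network with node degrees `k_i`, node
importance is `I_i = k_i / Σ_j k_j` and the entropy is

    E = − Σ_i I_i ln I_i .

A regular graph attains the maximum `E = ln N`; hub-dominated decompositions
score lower. Among candidate module partitions (MCODE, Markov clustering,
greedy modularity), the method with minimum entropy is selected, and the
main module is the one ranked first by aggregate node strength, betweenness
and PageRank (path-length disturbance breaks disagreements).

**Network proximity.** For target sets X and Y on the interactome,

    d(X,Y) = (1/|Y|) Σ_{y∈Y} min_{x∈X} d(x,y)
    s_AB   = d_AB − (d_AA + d_BB)/2
    z      = (d − μ)/σ

where μ, σ come from a degree-preserving permutation null. `s_AB < 0` and
`z < 0` mean the two target neighbourhoods overlap topologically.

**Cross-trait filtering.** Per-SNP z-scores are combined across traits into
`S_Hom = (Σ_k √n_k z_k)² / Σ_k n_k` and the heterogeneity-robust `S_Het`
(maximum of `S_Hom` over |z|-thresholded trait subsets, Monte-Carlo
calibrated). A SNP is shared when its single-trait p < 1e−5 in every trait
and its meta p < 5e−8, after PLINK-style clumping.

**Colocalisation.** Wakefield approximate Bayes factors per SNP, enumerated
into posterior probabilities of hypotheses H0–H4; `PPH4 > 0.95` declares a
shared causal variant.

**Mendelian randomisation.** IVW (fixed/random effects via Cochran's Q),
MR-Egger, weighted median, weighted mode, MR-PRESSO outlier/distortion
tests, leave-one-out, multivariable IVW and per-instrument F statistics,
after allele harmonisation with palindromic-SNP handling.

## Worked example

```python
import xtrait as x

# a planted-partition interactome and two target sets sharing one block
net, truth = x.gen_sbm(n_blocks=4, block_size=25, p_in=0.3, p_out=0.02, seed=7)
mets, ra = x.gen_target_pair(net, truth, overlap=0.5, size_a=10, size_b=10, seed=7)
res = x.proximity_z(net, mets, ra, n_perm=1000, seed=7)
print(f"s_AB = {res.s_AB:.3f}   z = {res.z:.2f}   p = {res.p_empirical:.4f}")

# two-sample MR with a true causal effect of 0.3 on the log-odds scale
exposure, outcome, _ = x.gen_mr_dataset(j=50, theta=0.3, seed=7)
inst = x.harmonise(exposure, outcome)
fit = x.ivw(inst)
lo, hi = fit.or_ci
print(f"IVW: beta = {fit.estimate:.3f} (SE {fit.se:.3f}), "
      f"OR = {fit.or_estimate:.3f} [{lo:.3f}, {hi:.3f}], p = {fit.p:.2e}")
eg = x.egger(inst)
print(f"Egger intercept = {eg.egger_intercept:.4f} (p = {eg.egger_intercept_p:.2f}); "
      f"Q = {fit.q:.1f} on {fit.q_df} df (p = {fit.q_p:.2f})")
```

prints

```
s_AB = -0.500   z = -3.95   p = 0.0010
IVW: beta = 0.285 (SE 0.067), OR = 1.329 [1.166, 1.515], p = 1.97e-05
Egger intercept = 0.0001 (p = 1.00); Q = 41.9 on 49 df (p = 0.75)
```

The two target sets planted in the same network block are topologically
overlapping (`s_AB < 0`) and significantly closer than degree-matched random
sets (`z = −3.95`). The IVW estimate recovers the simulated causal effect
(0.3) within one standard error; the Egger intercept near zero and the
non-significant Q indicate no directional pleiotropy and no heterogeneity —
as constructed.

The same stages are available from the shell:

```bash
xtrait simulate targets --seed 7 --out demo/
xtrait run --network demo/network.tsv --targets demo/targets.gmt --seed 7 --out demo/run
xtrait mr uni --exposure exp.tsv --outcome out.tsv --presso --loo --seed 7
```

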