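"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed, and returns a
:class:`SyntheticTruth` describing what was planted so tests can score
recovery:

* stochastic-block-model interactomes with planted communities;
* pairs of target sets with a controlled membership overlap, drawn from one
  block (overlapping) or from two distinct blocks (separated);
* instrument-level two-sample MR summary statistics with a true causal
  effect, optional directional pleiotropy, planted outliers and a
  configurable fraction of palindromic variants;
* single-region association statistics under a shared, distinct or absent
  causal variant for colocalisation.

The generators emulate the statistical structure these methods consume —
degree-heterogeneous community graphs, effect/SE pairs with p-values
consistent with beta/se — not the biology of any particular interactome or
cohort (no linkage disequilibrium, realistic allele-frequency spectra or
genome coordinates beyond monotone positions).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GWAS_COLUMNS, InteractionNetwork, TargetSet

__all__ = [
    "SyntheticTruth",
    "gen_sbm",
    "gen_target_pair",
    "gen_mr_dataset",
    "gen_coloc_region",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside every generated dataset."""

    seed: int
    planted_modules: list[list[str]] = field(default_factory=list)
    target_overlap: float = 0.0
    theta: float = 0.0
    pleiotropy_intercept: float = 0.0
    outlier_ids: list[str] = field(default_factory=list)
    palindromic_ids: list[str] = field(default_factory=list)
    coloc_scenario: str = ""
    causal_snps: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def gen_sbm(
    n_blocks: int = 4,
    block_size: int = 25,
    p_in: float = 0.3,
    p_out: float = 0.02,
    seed: int = 0,
) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Planted-partition (stochastic block model) interaction network.

    Nodes are named ``g<block>_<i>``. Warns when the expected mean degree is
    below 1 (graph likely fragments into dust).
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    n = n_blocks * block_size
    mean_deg = (block_size - 1) * p_in + (n - block_size) * p_out
    if mean_deg < 1:
        import warnings

        warnings.warn("expected mean degree < 1: graph likely fragmented")
    rng = np.random.default_rng(seed)
    names = [f"g{b}_{i}" for b in range(n_blocks) for i in range(block_size)]
    block = np.repeat(np.arange(n_blocks), block_size)
    g = nx.Graph()
    g.add_nodes_from(names)
    upper = np.triu_indices(n, k=1)
    same = block[upper[0]] == block[upper[1]]
    probs = np.where(same, p_in, p_out)
    draws = rng.random(len(probs)) < probs
    for a, b in zip(upper[0][draws], upper[1][draws]):
        g.add_edge(names[a], names[b], weight=1.0)
    truth = SyntheticTruth(
        seed=seed,
        planted_modules=[
            names[b * block_size : (b + 1) * block_size] for b in range(n_blocks)
        ],
    )
    return InteractionNetwork(g, name=f"sbm{n_blocks}x{block_size}"), truth


def gen_target_pair(
    net: InteractionNetwork,
    truth: SyntheticTruth,
    overlap: float = 0.5,
    size_a: int = 10,
    size_b: int = 10,
    seed: int = 0,
) -> tuple[TargetSet, TargetSet]:
    """Two target sets with controlled overlap on a planted-partition graph.

    ``overlap > 0``: both sets are drawn from the first planted block and
    share exactly ``floor(overlap * min(size_a, size_b))`` nodes.
    ``overlap == 0``: set A comes from the first block, set B from the
    second (disjoint blocks, topologically separated when p_out is small).
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    blocks = [sorted(b) for b in truth.planted_modules]
    if overlap > 0:
        pool = blocks[0]
        n_shared = int(overlap * min(size_a, size_b))
        need = size_a + size_b - n_shared
        if need > len(pool):
            raise ValueError("block too small for requested sizes")
        chosen = list(rng.choice(pool, size=need, replace=False))
        shared = chosen[:n_shared]
        a = shared + chosen[n_shared : n_shared + (size_a - n_shared)]
        b = shared + chosen[n_shared + (size_a - n_shared) :]
    else:
        if size_a > len(blocks[0]) or size_b > len(blocks[1]):
            raise ValueError("block too small for requested sizes")
        a = list(rng.choice(blocks[0], size=size_a, replace=False))
        b = list(rng.choice(blocks[1], size=size_b, replace=False))
    truth.target_overlap = overlap
    return TargetSet("set_A", tuple(a)), TargetSet("set_B", tuple(b))


def _gwas_frame(snp, chrom, bp, a1, a2, beta, se, eaf, n) -> pd.DataFrame:
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se)))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "snp": snp,
            "chr": chrom,
            "bp": bp,
            "a1": a1,
            "a2": a2,
            "beta": beta,
            "se": se,
            "p": p,
            "eaf": eaf,
            "n": n,
        }
    )[GWAS_COLUMNS]


def gen_mr_dataset(
    j: int = 50,
    theta: float = 0.3,
    intercept: float = 0.0,
    outlier_frac: float = 0.0,
    outlier_shift: float = 0.0,
    se_scale: float = 0.05,
    palindromic_frac: float = 0.0,
    n_exposure: int = 200_000,
    n_outcome: int = 150_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Instrument-level exposure/outcome summary statistics.

    beta_x ~ N(0, 0.05^2) truncated at |beta_x| > 0.005 (keeps Wald ratios
    finite), observed with noise se_x; beta_y = theta*beta_x + intercept +
    outlier_shift for planted outliers + N(0, se_y^2). ``se_scale`` sets the
    outcome (and exposure/5) standard errors. A ``palindromic_frac`` of SNPs
    gets A/T or G/C alleles; the rest are unambiguous. Exposure p-values are
    computed from the *observed* beta_x/se_x, so strong true effects pass the
    genome-wide threshold.
    """
    rng = np.random.default_rng(seed)
    snps = [f"rs{1000 + i}" for i in range(j)]
    bx_true = rng.normal(0.0, 0.05, size=j)
    small = np.abs(bx_true) <= 0.005
    while small.any():
        bx_true[small] = rng.normal(0.0, 0.05, size=int(small.sum()))
        small = np.abs(bx_true) <= 0.005
    # make instruments genome-wide significant for the exposure
    bx_true = np.sign(bx_true) * (np.abs(bx_true) + 6.0 * se_scale / 5.0)
    se_x = np.full(j, se_scale / 5.0)
    se_y = np.full(j, se_scale)
    bx_obs = rng.normal(bx_true, se_x)
    n_out = int(round(outlier_frac * j))
    outlier_idx = rng.choice(j, size=n_out, replace=False) if n_out else np.array([], int)
    shift = np.zeros(j)
    shift[outlier_idx] = outlier_shift
    # directional pleiotropy is defined per exposure-increasing allele, so the
    # planted intercept follows the sign of beta_x (Egger orients beta_x > 0)
    by_obs = rng.normal(theta * bx_true + (intercept + shift) * np.sign(bx_true), se_y)

    n_pal = int(round(palindromic_frac * j))
    pal_idx = set(rng.choice(j, size=n_pal, replace=False).tolist()) if n_pal else set()
    a1, a2 = [], []
    for i in range(j):
        if i in pal_idx:
            pair = _PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))]
        else:
            pair = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        a1.append(pair[0])
        a2.append(pair[1])
    eaf = rng.uniform(0.45, 0.55, size=j)  # ambiguous frequencies: palindromes drop
    bp = 1_000_000 + 500_000 * np.arange(j)
    exposure = _gwas_frame(snps, "1", bp, a1, a2, bx_obs, se_x, eaf, n_exposure)
    outcome = _gwas_frame(snps, "1", bp, a1, a2, by_obs, se_y, eaf, n_outcome)
    truth = SyntheticTruth(
        seed=seed,
        theta=theta,
        pleiotropy_intercept=intercept,
        outlier_ids=[snps[i] for i in sorted(outlier_idx.tolist())],
        palindromic_ids=[snps[i] for i in sorted(pal_idx)],
    )
    return exposure, outcome, truth


def gen_coloc_region(
    n_snps: int = 100,
    scenario: str = "shared",
    z_causal: float = 10.0,
    se: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """One genomic region for two traits under a planted causal structure.

    ``null``: all z ~ N(0,1) in both traits. ``shared``: one common SNP gets
    an additional signal of |z| = z_causal in both traits. ``distinct``: two
    different SNPs get the signal, one per trait. SNPs are independent (no
    LD), consistent with the single-causal-variant ABF model.
    """
    if scenario not in ("null", "shared", "distinct"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    snps = [f"rs{5000 + i}" for i in range(n_snps)]
    z1 = rng.standard_normal(n_snps)
    z2 = rng.standard_normal(n_snps)
    causal: dict[str, str] = {}
    if scenario == "shared":
        i = int(rng.integers(n_snps))
        z1[i] += z_causal
        z2[i] += z_causal
        causal = {"trait1": snps[i], "trait2": snps[i]}
    elif scenario == "distinct":
        i, k = rng.choice(n_snps, size=2, replace=False)
        z1[int(i)] += z_causal
        z2[int(k)] += z_causal
        causal = {"trait1": snps[int(i)], "trait2": snps[int(k)]}
    bp = 2_000_000 + 1_000 * np.arange(n_snps)
    alleles = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))] for _ in range(n_snps)]
    a1 = [a for a, _ in alleles]
    a2 = [b for _, b in alleles]
    eaf = rng.uniform(0.05, 0.95, size=n_snps)
    se_arr = np.full(n_snps, se)
    t1 = _gwas_frame(snps, "2", bp, a1, a2, z1 * se_arr, se_arr, eaf, 100_000)
    t2 = _gwas_frame(snps, "2", bp, a1, a2, z2 * se_arr, se_arr, eaf, 100_000)
    truth = SyntheticTruth(seed=seed, coloc_scenario=scenario, causal_snps=causal)
    return t1, t2, truth
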