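"""Candidate functional-module detection on an interaction network.

Three detectors are provided, each fully deterministic (node iteration order
is lexicographic, no hidden RNG):

* :func:`mcode` — molecular complex detection: vertex weighting by the
  core-clustering coefficient (density of the highest k-core of a node's
  closed neighbourhood times its core number), seeded complex growth with a
  vertex-weight-percentage cutoff, then 2-core filtering with optional
  haircut/fluff post-processing. Complexes may overlap after fluff.
* :func:`mcl` — Markov clustering: flow simulation on the column-stochastic
  adjacency matrix with self-loops, alternating expansion (matrix power) and
  inflation (entrywise power + column renormalisation) until the matrix is
  stable, clusters read off the attractor rows.
* :func:`greedy_modularity` — Newman fast-greedy agglomerative maximisation
  of modularity Q = sum_c (e_c/m - (d_c/2m)^2); this is the community stage
  of the GLay clustering workflow.

Modules smaller than ``min_size`` (default 3) are moved to ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import InteractionNetwork

__all__ = ["ModuleSet", "mcode", "mcl", "greedy_modularity", "detect_all"]

DEFAULT_MIN_SIZE = 3


@dataclass
class ModuleSet:
    """A family of node subsets produced by one partition method.

    For ``mcl`` and ``greedy`` the modules are pairwise disjoint and together
    with ``unassigned`` cover all nodes; ``mcode`` complexes may overlap and
    ``unassigned`` holds nodes in no complex.
    """

    method: str
    modules: list[frozenset[str]]
    unassigned: frozenset[str]
    params: dict = field(default_factory=dict)
    scores: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def assigned_nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m
        return frozenset(out)

    def labels(self) -> dict[str, int]:
        """node -> module index (first containing module wins for overlaps)."""
        lab: dict[str, int] = {}
        for i, m in enumerate(self.modules):
            for n in sorted(m):
                lab.setdefault(n, i)
        return lab


# ---------------------------------------------------------------------------
# MCODE


def _core_clustering_weight(g: nx.Graph, node: str) -> float:
    """MCODE vertex weight: k * density of the highest k-core of N[node]."""
    nbhd = list(g.neighbors(node)) + [node]
    sub = g.subgraph(nbhd)
    core_nums = nx.core_number(sub)
    k = max(core_nums.values())
    if k == 0:
        return 0.0
    core_nodes = [n for n, c in core_nums.items() if c >= k]
    core = sub.subgraph(core_nodes)
    n = core.number_of_nodes()
    if n < 2:
        return 0.0
    density = 2.0 * core.number_of_edges() / (n * (n - 1))
    return k * density


def mcode(
    net: InteractionNetwork,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.2,
    min_size: int = DEFAULT_MIN_SIZE,
) -> ModuleSet:
    """Molecular complex detection.

    Parameters follow the plugin's conventions: ``vwp`` is the vertex weight
    percentage (a neighbour joins a growing complex when its weight exceeds
    ``(1 - vwp)`` times the seed weight), ``haircut`` removes singly-connected
    nodes from each complex, ``fluff`` adds dense neighbourhoods back after
    haircut. Complexes lacking a 2-core are discarded; results are sorted by
    descending score = density x size of the complex subgraph.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    weights = {n: _core_clustering_weight(g, n) for n in g.nodes}
    seen: set[str] = set()
    complexes: list[set[str]] = []
    # seeds in descending weight, lexicographic tie-break
    for seed in sorted(g.nodes, key=lambda n: (-weights[n], n)):
        if seed in seen or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        complex_nodes = {seed}
        frontier = [seed]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for v in sorted(g.neighbors(u)):
                    if v in seen or v in complex_nodes:
                        continue
                    if weights[v] > threshold:
                        complex_nodes.add(v)
                        nxt.append(v)
            frontier = nxt
        seen |= complex_nodes
        complexes.append(complex_nodes)

    processed: list[frozenset[str]] = []
    for comp in complexes:
        sub = g.subgraph(comp)
        core_nums = nx.core_number(sub)
        if not core_nums or max(core_nums.values()) < 2:
            continue  # no 2-core: discard
        nodes = set(comp)
        if haircut:
            # iteratively strip degree-1 nodes within the complex
            changed = True
            while changed and len(nodes) > 1:
                sub = g.subgraph(nodes)
                drop = {n for n in nodes if sub.degree(n) < 2}
                changed = bool(drop)
                nodes -= drop
        if fluff:
            extra: set[str] = set()
            for n in sorted(nodes):
                for v in g.neighbors(n):
                    if v in nodes or v in extra:
                        continue
                    nb = list(g.neighbors(v)) + [v]
                    nsub = g.subgraph(nb)
                    nn = nsub.number_of_nodes()
                    dens = 2.0 * nsub.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
                    if dens > fluff_density:
                        extra.add(v)
            nodes |= extra
        if len(nodes) >= min_size:
            processed.append(frozenset(nodes))

    def score(c: frozenset[str]) -> float:
        sub = g.subgraph(c)
        n = sub.number_of_nodes()
        dens = 2.0 * sub.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        return dens * n

    processed.sort(key=lambda c: (-score(c), sorted(c)))
    assigned = set().union(*processed) if processed else set()
    return ModuleSet(
        method="mcode",
        modules=processed,
        unassigned=frozenset(set(g.nodes) - assigned),
        params={
            "vwp": vwp,
            "haircut": haircut,
            "fluff": fluff,
            "min_size": min_size,
        },
        scores=[score(c) for c in processed],
    )


# ---------------------------------------------------------------------------
# MCL


def mcl(
    net: InteractionNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    min_size: int = DEFAULT_MIN_SIZE,
    tol: float = 1e-8,
) -> ModuleSet:
    """Markov clustering by alternating expansion and inflation.

    Self-loops of weight 1 are added before column normalisation. Iteration
    stops when the largest entry change falls below ``tol``; if ``max_iter``
    is reached first the result carries ``converged=False``. Clusters are the
    supports of attractor rows; a node attracted by several rows joins the
    one with the largest flow (lexicographic tie-break via sorted node order).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    g = net.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, w in net.edges():
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    m[np.diag_indices(n)] = 1.0
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, expansion)
        new = np.power(new, inflation)
        new[new < prune_threshold] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.max(np.abs(new - m)) < tol:
            m = new
            converged = True
            break
        m = new

    # attractors: rows with a non-negligible diagonal entry
    attractors = [i for i in range(n) if m[i, i] > prune_threshold]
    owner = np.full(n, -1)
    for j in range(n):
        flows = m[attractors, j] if attractors else np.array([])
        if flows.size and flows.max() > 0:
            owner[j] = attractors[int(np.argmax(flows))]
    # merge attractors that share members (overlapping attractor systems)
    clusters: dict[int, set[str]] = {}
    for j in range(n):
        key = int(owner[j]) if owner[j] >= 0 else j
        clusters.setdefault(key, set()).add(nodes[j])
    raw = sorted(clusters.values(), key=lambda c: (-len(c), sorted(c)))
    modules = [frozenset(c) for c in raw if len(c) >= min_size]
    assigned = set().union(*modules) if modules else set()
    return ModuleSet(
        method="mcl",
        modules=modules,
        unassigned=frozenset(set(nodes) - assigned),
        params={
            "inflation": inflation,
            "expansion": expansion,
            "prune_threshold": prune_threshold,
            "max_iter": max_iter,
            "min_size": min_size,
        },
        scores=[float(len(c)) for c in modules],
        converged=converged,
    )


# ---------------------------------------------------------------------------
# greedy modularity (GLay community stage)


def greedy_modularity(
    net: InteractionNetwork, min_size: int = DEFAULT_MIN_SIZE
) -> ModuleSet:
    """Fast-greedy agglomerative modularity maximisation (unweighted).

    Returns the partition at maximum achieved modularity. Communities smaller
    than ``min_size`` go to ``unassigned``.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    comms = nx.community.greedy_modularity_communities(g, weight=None)
    comms = sorted((frozenset(c) for c in comms), key=lambda c: (-len(c), sorted(c)))
    modules = [c for c in comms if len(c) >= min_size]
    assigned = set().union(*modules) if modules else set()
    q = nx.community.modularity(g, comms, weight=None)
    return ModuleSet(
        method="greedy",
        modules=modules,
        unassigned=frozenset(set(g.nodes) - assigned),
        params={"min_size": min_size},
        scores=[float(len(c)) for c in modules],
    )


def detect_all(net: InteractionNetwork, min_size: int = DEFAULT_MIN_SIZE) -> dict[str, ModuleSet]:
    """Run all three detectors with defaults; keyed by method name."""
    return {
        "mcode": mcode(net, min_size=min_size),
        "mcl": mcl(net, min_size=min_size),
        "greedy": greedy_modularity(net, min_size=min_size),
    }
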