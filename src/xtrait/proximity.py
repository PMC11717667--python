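"""Network proximity between two disease target sets.

Implements the closest-distance family of measures on an unweighted
interactome:

* d(X,Y) — mean over targets y in Y of the shortest-path distance to the
  nearest member of X (asymmetric closest distance);
* d_AB, d_AA, d_BB and the separation score s_AB = d_AB - (d_AA + d_BB)/2,
  where d_AB is the symmetric closest distance and d_AA the mean within-set
  nearest-neighbour distance (self excluded). s_AB < 0 means the two target
  neighbourhoods overlap topologically; s_AB >= 0 means they are separated.
* z = (d - mu)/sigma — the observed d(X,Y) standardised against a null of
  random target sets of matching sizes, by default matched to the degree
  distribution of X and Y through log2-degree bins (merged until each bin
  holds at least ``bin_min`` network nodes).

Distances are hop counts; unreachable target pairs are excluded from the
means (and counted) rather than imputed, because imputation distorts the
sign of s_AB near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .io import InteractionNetwork, TargetSet

__all__ = [
    "ProximityResult",
    "closest_distance",
    "separation",
    "proximity_z",
    "distance_matrix",
]


@dataclass
class ProximityResult:
    d_AB: float
    d_AA: float
    d_BB: float
    s_AB: float
    d_XY_asym: float
    z: float
    mu_null: float
    sd_null: float
    p_empirical: float
    n_perm: int
    n_mapped_A: int
    n_mapped_B: int
    n_unreachable: int
    degree_binned: bool = True


def distance_matrix(net: InteractionNetwork) -> tuple[list[str], np.ndarray]:
    """All-pairs unweighted shortest-path (hop) matrix; inf = unreachable."""
    nodes = sorted(net.graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for a, b, _ in net.edges():
        rows += [idx[a], idx[b]]
        cols += [idx[b], idx[a]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    return nodes, dist


def _map_indices(net: InteractionNetwork, ts: TargetSet, idx: dict[str, int]) -> np.ndarray:
    mapped = [idx[g] for g in ts.genes if g in idx]
    if not mapped:
        raise ValueError(f"no gene of {ts.name!r} maps onto the network")
    return np.asarray(sorted(set(mapped)), dtype=int)


def _closest_from_matrix(dist: np.ndarray, xi: np.ndarray, yi: np.ndarray) -> tuple[float, int]:
    """(mean over y of min_x d(x,y), number of unreachable y-nodes)."""
    mins = dist[np.ix_(xi, yi)].min(axis=0)
    finite = np.isfinite(mins)
    n_unreachable = int((~finite).sum())
    if not finite.any():
        raise ValueError("disconnected target sets: no y reachable from X")
    return float(mins[finite].mean()), n_unreachable


def _within_distance(dist: np.ndarray, ai: np.ndarray) -> tuple[float, int]:
    """Mean nearest-other-member distance within a set (singleton -> 0)."""
    if len(ai) < 2:
        return 0.0, 0
    sub = dist[np.ix_(ai, ai)].copy()
    np.fill_diagonal(sub, np.inf)
    mins = sub.min(axis=0)
    finite = np.isfinite(mins)
    if not finite.any():
        raise ValueError("disconnected target set: no within-set paths")
    return float(mins[finite].mean()), int((~finite).sum())


def closest_distance(net: InteractionNetwork, X: TargetSet, Y: TargetSet) -> float:
    """Asymmetric closest distance d(X,Y) = mean_y min_x d(x,y)."""
    nodes, dist = distance_matrix(net)
    idx = {v: i for i, v in enumerate(nodes)}
    xi, yi = _map_indices(net, X, idx), _map_indices(net, Y, idx)
    d, _ = _closest_from_matrix(dist, xi, yi)
    return d


def separation(
    net: InteractionNetwork, A: TargetSet, B: TargetSet
) -> tuple[float, float, float, float]:
    """Return (d_AB, d_AA, d_BB, s_AB) with the symmetric closest d_AB."""
    nodes, dist = distance_matrix(net)
    idx = {v: i for i, v in enumerate(nodes)}
    ai, bi = _map_indices(net, A, idx), _map_indices(net, B, idx)
    d_AB = _symmetric_closest(dist, ai, bi)
    d_AA, _ = _within_distance(dist, ai)
    d_BB, _ = _within_distance(dist, bi)
    s_AB = d_AB - (d_AA + d_BB) / 2.0
    return d_AB, d_AA, d_BB, s_AB


def _symmetric_closest(dist: np.ndarray, ai: np.ndarray, bi: np.ndarray) -> float:
    block = dist[np.ix_(ai, bi)]
    a_min = block.min(axis=1)
    b_min = block.min(axis=0)
    vals = np.concatenate([a_min, b_min])
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("disconnected target sets")
    return float(vals[finite].mean())


def _degree_bins(net: InteractionNetwork, nodes: list[str], bin_min: int = 10) -> dict[str, int]:
    """Assign each node a log2-degree bin; sparse bins merged upward to >= bin_min."""
    degs = dict(net.graph.degree)
    raw = {v: int(np.log2(degs[v] + 1)) for v in nodes}
    # merge ascending until every occupied bin has >= bin_min members
    levels = sorted(set(raw.values()))
    counts = {lv: sum(1 for v in raw.values() if v == lv) for lv in levels}
    remap: dict[int, int] = {}
    acc, members = 0, []
    for lv in levels:
        members.append(lv)
        acc += counts[lv]
        if acc >= bin_min:
            for m in members:
                remap[m] = members[0]
            acc, members = 0, []
    if members:  # leftover small top bins merge into the previous group
        prev = max(remap.values(), default=members[0])
        for m in members:
            remap[m] = prev
    return {v: remap[b] for v, b in raw.items()}


def proximity_z(
    net: InteractionNetwork,
    X: TargetSet,
    Y: TargetSet,
    n_perm: int = 1000,
    seed: int = 0,
    degree_binned: bool = True,
    bin_min: int = 10,
) -> ProximityResult:
    """Permutation z-score of the closest distance d(X,Y).

    The null redraws both sets ``n_perm`` times as random node sets of the
    same sizes (matched per log2-degree bin when ``degree_binned``), recomputes
    the asymmetric d(X_r, Y_r) each time and reports z = (d - mu)/sigma plus
    the add-one-smoothed empirical p of observing a distance as small as the
    observed one. z < 0 means X and Y are closer than random expectation.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    nodes, dist = distance_matrix(net)
    idx = {v: i for i, v in enumerate(nodes)}
    xi, yi = _map_indices(net, X, idx), _map_indices(net, Y, idx)
    if len(nodes) < 2 * (len(xi) + len(yi)):
        raise ValueError("network too small for null resampling")

    d_obs, n_unreach = _closest_from_matrix(dist, xi, yi)
    d_AB = _symmetric_closest(dist, xi, yi)
    d_AA, _ = _within_distance(dist, xi)
    d_BB, _ = _within_distance(dist, yi)
    s_AB = d_AB - (d_AA + d_BB) / 2.0

    rng = np.random.default_rng(seed)
    if degree_binned:
        bins = _degree_bins(net, nodes, bin_min=bin_min)
        pools = {}
        for v, b in bins.items():
            pools.setdefault(b, []).append(idx[v])
        pools = {b: np.asarray(sorted(p)) for b, p in pools.items()}

        def draw(members: np.ndarray) -> np.ndarray:
            need: dict[int, int] = {}
            for i in members:
                b = bins[nodes[i]]
                need[b] = need.get(b, 0) + 1
            out = [rng.choice(pools[b], size=k, replace=False) for b, k in sorted(need.items())]
            return np.concatenate(out)

    else:
        all_idx = np.arange(len(nodes))

        def draw(members: np.ndarray) -> np.ndarray:
            return rng.choice(all_idx, size=len(members), replace=False)

    null = np.empty(n_perm)
    for k in range(n_perm):
        xr, yr = draw(xi), draw(yi)
        mins = dist[np.ix_(xr, yr)].min(axis=0)
        finite = np.isfinite(mins)
        null[k] = mins[finite].mean() if finite.any() else np.nan
    null = null[np.isfinite(null)]
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (d_obs - mu) / sd if sd > 0 else float("nan")
    p_emp = (1.0 + float((null <= d_obs).sum())) / (1.0 + len(null))
    return ProximityResult(
        d_AB=d_AB,
        d_AA=d_AA,
        d_BB=d_BB,
        s_AB=s_AB,
        d_XY_asym=d_obs,
        z=z,
        mu_null=mu,
        sd_null=sd,
        p_empirical=p_emp,
        n_perm=int(len(null)),
        n_mapped_A=len(xi),
        n_mapped_B=len(yi),
        n_unreachable=n_unreach,
        degree_binned=degree_binned,
    )
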