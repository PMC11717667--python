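"""Readers and writers for networks, gene sets and GWAS summary statistics.

All format invariants are enforced at this boundary: networks are undirected,
deduplicated and self-loop free; target sets are non-empty ordered sets;
summary-statistic rows must satisfy ``se > 0`` and ``p in (0, 1]`` (underflowed
``p = 0`` is clamped to the smallest positive float rather than rejected,
because public summary files routinely contain it).

Node and gene identifiers are case-sensitive opaque strings; no symbol
normalisation is attempted here.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "TargetSet",
    "RunConfig",
    "GWAS_COLUMNS",
    "read_network",
    "write_network",
    "read_target_sets",
    "read_gwas",
    "write_gwas",
    "write_run_metadata",
]

#: canonical lower-case column names of a GwasTable, in output order
GWAS_COLUMNS = ["snp", "chr", "bp", "a1", "a2", "beta", "se", "p", "eaf", "n"]

_REQUIRED_GWAS = ["SNP", "A1", "A2", "BETA", "SE", "P"]
_OPTIONAL_GWAS = ["CHR", "BP", "EAF", "N"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class InteractionNetwork:
    """An undirected protein/gene interaction network.

    Thin wrapper around :class:`networkx.Graph` guaranteeing no self-loops,
    deduplicated undirected edges and strictly positive weights (default 1.0).
    """

    graph: nx.Graph
    name: str = "network"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for a, b, d in self.graph.edges(data=True):
            yield a, b, float(d.get("weight", 1.0))

    def subgraph(self, nodes: Iterable[str]) -> "InteractionNetwork":
        sub = self.graph.subgraph([n for n in nodes if n in self.graph]).copy()
        return InteractionNetwork(sub, name=self.name)

    def validate(self) -> None:
        if any(a == b for a, b in self.graph.edges):
            raise FormatError("network contains self-loops")
        for _, _, w in self.edges():
            if not w > 0:
                raise FormatError("edge weights must be positive")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        name: str = "network",
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            a, b = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            if a == b:
                continue
            g.add_edge(str(a), str(b), weight=w)
        net = cls(g, name=name)
        net.validate()
        return net


@dataclass
class TargetSet:
    """A named, order-preserving set of gene/protein identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g))
        self.genes = tuple(seen)
        if not self.genes:
            raise FormatError(f"target set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def mapped(self, net: InteractionNetwork) -> "TargetSet":
        """Restrict to genes present in *net* (dropped genes are counted by caller)."""
        kept = tuple(g for g in self.genes if g in net.graph)
        if not kept:
            raise FormatError(
                f"no gene of target set {self.name!r} maps onto the network"
            )
        return TargetSet(self.name, kept)


@dataclass
class RunConfig:
    """Flat run configuration: seed, permutation counts, thresholds, output dir."""

    seed: int = 0
    n_permutations: int = 1000
    params: dict = field(default_factory=dict)
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.pop("seed", 0)),
            n_permutations=int(raw.pop("n_permutations", 1000)),
            out_dir=str(raw.pop("out_dir", ".")),
            params=dict(raw),
        )


# ---------------------------------------------------------------------------
# networks


def read_network(
    path: str | Path, format: str = "edgelist", name: str | None = None
) -> InteractionNetwork:
    """Read an undirected network from an edge list or SIF file.

    Edge list: 2 or 3 whitespace/tab-separated columns (node_a node_b [weight]);
    lines starting with ``#`` are ignored except for a header comment of the
    form ``# nodes: a b c`` which declares isolated nodes to retain.
    SIF: ``nodeA relation nodeB`` triples, relation ignored, weight 1.0.

    Self-loops are dropped with a warning; duplicate undirected edges are
    merged (first weight wins).
    """
    path = Path(path)
    g = nx.Graph()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("nodes:"):
                    g.add_nodes_from(body[6:].split())
                continue
            fields = line.split()
            if format == "sif":
                if len(fields) != 3:
                    raise FormatError(
                        f"{path.name}:{lineno}: SIF line needs 3 columns, got {len(fields)}"
                    )
                a, _, b = fields
                w = 1.0
            else:
                if len(fields) not in (2, 3):
                    raise FormatError(
                        f"{path.name}:{lineno}: edge line needs 2 or 3 columns, got {len(fields)}"
                    )
                a, b = fields[0], fields[1]
                try:
                    w = float(fields[2]) if len(fields) == 3 else 1.0
                except ValueError as exc:
                    raise FormatError(
                        f"{path.name}:{lineno}: bad weight {fields[2]!r}"
                    ) from exc
                if not w > 0:
                    raise FormatError(f"{path.name}:{lineno}: weight must be > 0")
            if a == b:
                n_self_loops += 1
                continue
            if not g.has_edge(a, b):
                g.add_edge(a, b, weight=w)
    if n_self_loops:
        warnings.warn(f"dropped {n_self_loops} self-loop(s) while reading {path.name}")
    return InteractionNetwork(g, name=name or path.stem)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write a network as a 3-column TSV edge list (isolated nodes in a header)."""
    path = Path(path)
    isolated = sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0)
    with open(path, "w") as fh:
        if isolated:
            fh.write("# nodes: " + " ".join(isolated) + "\n")
        fh.write("# node_a\tnode_b\tweight\n")
        for a, b, w in sorted(
            (tuple(sorted((a, b))) + (w,) for a, b, w in net.edges())
        ):
            fh.write(f"{a}\t{b}\t{w:g}\n")


# ---------------------------------------------------------------------------
# gene sets


def read_target_sets(path: str | Path, format: str = "gmt") -> list[TargetSet]:
    """Read target sets from a GMT file or a one-gene-per-line list.

    GMT: ``name<TAB>description<TAB>member...`` per line. List format yields a
    single set named after the file stem. Duplicate members are collapsed with
    a warning; an empty set is an error naming the set.
    """
    path = Path(path)
    sets: list[TargetSet] = []
    if format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path.name}:{lineno}: GMT line needs name, description, members"
                    )
                name, members = fields[0], [f for f in fields[2:] if f]
                if not members:
                    raise FormatError(f"target set {name!r} is empty")
                if len(set(members)) < len(members):
                    warnings.warn(f"duplicate genes collapsed in set {name!r}")
                sets.append(TargetSet(name, tuple(members)))
    elif format == "list":
        genes = [
            ln.strip()
            for ln in open(path)
            if ln.strip() and not ln.startswith("#")
        ]
        if not genes:
            raise FormatError(f"target set {path.stem!r} is empty")
        if len(set(genes)) < len(genes):
            warnings.warn(f"duplicate genes collapsed in set {path.stem!r}")
        sets.append(TargetSet(path.stem, tuple(genes)))
    else:
        raise ValueError(f"unknown target-set format {format!r}")
    return sets


def write_target_sets(sets: Iterable[TargetSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ts in sets:
            fh.write("\t".join([ts.name, "na", *ts.genes]) + "\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics


def read_gwas(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read tab-delimited GWAS summary statistics into a validated GwasTable.

    Required columns: SNP, A1, A2, BETA, SE, P (case-insensitive; *aliases*
    maps non-standard header names onto these). Optional: CHR, BP, EAF, N.
    Invalid rows (se <= 0, p outside (0,1], a1 == a2) are dropped and counted;
    p == 0 is clamped to the smallest positive float with a warning. The
    returned frame uses lower-case canonical column names and preserves row
    order; ``df.attrs['n_dropped']`` records the drop count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    rename = {c: c.upper() for c in df.columns}
    if aliases:
        rename.update({k: v.upper() for k, v in aliases.items()})
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_GWAS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    for col in _OPTIONAL_GWAS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[_REQUIRED_GWAS[:1] + ["CHR", "BP"] + _REQUIRED_GWAS[1:] + ["EAF", "N"]]
    df.columns = ["snp", "chr", "bp", "a1", "a2", "beta", "se", "p", "eaf", "n"]
    return validate_gwas(df)


def validate_gwas(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a GwasTable in place: clamp p=0, drop invalid rows (counted)."""
    df = df.copy()
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    for col in ("beta", "se", "p", "eaf"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    n_clamped = int((df["p"] == 0).sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} p-value(s) of 0 clamped to {sys.float_info.min:g}")
        df.loc[df["p"] == 0, "p"] = sys.float_info.min
    ok = (
        (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & df["beta"].notna()
        & (df["a1"] != df["a2"])
    )
    dropped = int((~ok).sum())
    out = df[ok].reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    out.attrs["n_clamped"] = n_clamped
    return out


def write_gwas(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.columns = [c.upper() for c in out.columns]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_run_metadata(
    path: str | Path,
    config: Mapping | RunConfig,
    warnings_list: Iterable[str] = (),
) -> None:
    """Write the per-run JSON metadata file (config echo, seed, versions)."""
    if isinstance(config, RunConfig):
        payload = {
            "seed": config.seed,
            "n_permutations": config.n_permutations,
            "out_dir": config.out_dir,
            **config.params,
        }
    else:
        payload = dict(config)
    meta = {
        "config": payload,
        "warnings": list(warnings_list),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
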