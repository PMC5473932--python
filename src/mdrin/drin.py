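"""Dynamic residue interaction networks and their red/ox differential.

A binary interaction time series A_ij(t) (one per residue pair and
interaction type) is condensed into the maximum interaction lifetime

    Gamma_ij = the largest tau such that some window [tau0, tau0 + tau - 1]
               of A_ij is all ones,

i.e. the length of the longest run of consecutive frames in which the
interaction persists (0 when the pair never interacts).  One DRIN graph
per state and interaction type carries these lifetimes as edge weights.
The differential network between oxidized and reduced ensembles weighs
each pair by the shrunken log fold change

    Delta_ij = log2((Gamma_ij^ox + eps) / (Gamma_ij^red + eps)),

with a pseudocount eps > 0 (default 1 frame) preventing division by zero;
Delta is antisymmetric under a state swap.  Thresholding |Delta| and
merging the per-type graphs (keeping parallel typed edges) gives the
exported network, with node size = max |Delta| over incident edges and a
sigmoid display weight 2 / (1 + exp(-|Delta|)) - 1 per edge.

Lifetimes are stored in frames; the frame-to-time conversion is carried as
metadata because a "run" only has meaning within one contiguous
trajectory.  When several trajectories exist per state, compute Gamma per
trajectory and combine with :func:`combine_drins` (runs cannot span
trajectory boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .rin import AdjacencySeries

__all__ = [
    "max_lifetime",
    "DRINGraph",
    "DifferentialGraph",
    "compile_drin",
    "combine_drins",
    "differential_drin",
    "threshold_merge",
    "export_graph",
    "load_graphml",
    "write_drin_tsv",
    "read_drin_tsv",
]


def max_lifetime(series) -> int:
    """Maximum interaction lifetime: the longest run of consecutive 1s.

    Accepts any 0/1 sequence; returns 0 for all-zero input.  Non-binary
    values are rejected.
    """
    a = np.asarray(series)
    if a.size == 0:
        return 0
    if not np.isin(a, (0, 1)).all():
        raise ValueError("series must be binary (0/1)")
    a = a.astype(np.int8)
    padded = np.concatenate([[0], a, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    if len(starts) == 0:
        return 0
    return int((ends - starts).max())


@dataclass
class DRINGraph:
    """One state's DRIN for one interaction type: pair -> Gamma (frames)."""

    state: str
    kind: str
    n_frames: int
    edges: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, gamma in self.edges.items():
            if not 0 < gamma <= self.n_frames:
                raise ValueError(
                    f"Gamma for {pair} must be in 1..{self.n_frames}, got {gamma}"
                )

    def gamma(self, i: int, j: int) -> int:
        return self.edges.get((min(i, j), max(i, j)), 0)


def compile_drin(
    series: list[AdjacencySeries], state: str
) -> dict[str, DRINGraph]:
    """Compile adjacency time series into one DRIN graph per type.

    Every series must have the same length; pairs with zero lifetime are
    dropped.
    """
    if not series:
        return {}
    lengths = {len(s.values) for s in series}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    n_frames = lengths.pop()
    graphs = {
        kind: DRINGraph(state=state, kind=kind, n_frames=n_frames)
        for kind in sorted({s.kind for s in series})
    }
    for s in series:
        gamma = max_lifetime(s.values)
        if gamma > 0:
            pair = (min(s.pair), max(s.pair))
            prev = graphs[s.kind].edges.get(pair, 0)
            graphs[s.kind].edges[pair] = max(prev, gamma)
    for g in graphs.values():
        DRINGraph.__post_init__(g)
    return graphs


def combine_drins(graphs: list[DRINGraph]) -> DRINGraph:
    """Combine per-trajectory DRINs of one state: max Gamma per pair.

    Runs cannot span trajectory boundaries, so the state-level lifetime of
    a pair is the largest lifetime observed in any single trajectory.
    """
    if not graphs:
        raise ValueError("no graphs to combine")
    states = {g.state for g in graphs}
    kinds = {g.kind for g in graphs}
    if len(states) != 1 or len(kinds) != 1:
        raise ValueError("can only combine graphs of one state and one type")
    out = DRINGraph(
        state=graphs[0].state,
        kind=graphs[0].kind,
        n_frames=max(g.n_frames for g in graphs),
    )
    for g in graphs:
        for pair, gamma in g.edges.items():
            out.edges[pair] = max(out.edges.get(pair, 0), gamma)
    return out


@dataclass
class DiffEdge:
    delta: float
    gamma_ox: int
    gamma_red: int


@dataclass
class DifferentialGraph:
    """Red/ox differential network for one interaction type."""

    kind: str
    eps: float
    edges: dict[tuple[int, int], DiffEdge] = field(default_factory=dict)
    cutoff: float | None = None  # |Delta| threshold already applied, if any


def differential_drin(
    ox: DRINGraph, red: DRINGraph, eps: float = 1.0
) -> DifferentialGraph:
    """Delta_ij = log2((Gamma_ox + eps) / (Gamma_red + eps)) per pair.

    Computed over the union of the two edge sets (a missing edge has
    Gamma = 0); eps must be positive.  Swapping the states negates every
    Delta exactly.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if ox.kind != red.kind:
        raise ValueError(f"interaction types differ: '{ox.kind}' vs '{red.kind}'")
    pairs = set(ox.edges) | set(red.edges)
    out = DifferentialGraph(kind=ox.kind, eps=eps)
    for pair in pairs:
        g_ox = ox.gamma(*pair)
        g_red = red.gamma(*pair)
        # difference of logs (not log of ratio) keeps the antisymmetry
        # Delta(ox,red) == -Delta(red,ox) exact in floating point
        out.edges[pair] = DiffEdge(
            delta=math.log2(g_ox + eps) - math.log2(g_red + eps),
            gamma_ox=g_ox,
            gamma_red=g_red,
        )
    return out


def threshold_merge(
    diffs: list[DifferentialGraph], cutoff: float = 1.0
) -> nx.MultiGraph:
    """Merge per-type differential graphs, keeping edges with |Delta| >= cutoff.

    Parallel edges of different types between the same pair survive as
    separate typed edges; the node set is exactly the endpoints of the
    surviving edges.  The default cutoff of 1 keeps pairs whose lifetime
    changed at least two-fold.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    g = nx.MultiGraph()
    for diff in diffs:
        for (i, j), e in sorted(diff.edges.items()):
            if abs(e.delta) >= cutoff:
                g.add_edge(
                    int(i),
                    int(j),
                    key=diff.kind,
                    kind=diff.kind,
                    delta=float(e.delta),
                    gamma_ox=int(e.gamma_ox),
                    gamma_red=int(e.gamma_red),
                    display_weight=_display_weight(e.delta),
                )
    # node attributes: size = max |Delta| over incident edges
    for node in g.nodes:
        g.nodes[node]["size"] = max(
            abs(d["delta"]) for _, _, d in g.edges(node, data=True)
        )
        g.nodes[node]["residue"] = int(node)
    return g


def _display_weight(delta: float) -> float:
    """Sigmoid-like map of |Delta| to edge thickness in [0, 1)."""
    return 2.0 / (1.0 + math.exp(-abs(delta))) - 1.0


def annotate_domains(graph: nx.MultiGraph, partition) -> None:
    """Attach each node's domain tag from a DomainPartition (in place)."""
    for node in graph.nodes:
        graph.nodes[node]["domain"] = partition.tag_of(int(node))


def export_graph(graph: nx.MultiGraph, path: str | Path, fmt: str | None = None):
    """Write the merged differential network as GraphML or SIF + tables.

    GraphML keeps all node/edge attributes in one file.  SIF writes the
    typed edge list plus two TSV attribute tables (``<stem>.edges.tsv``,
    ``<stem>.nodes.tsv``) for network viewers that want separate files.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty graph")
    path = Path(path)
    fmt = fmt or ("sif" if path.suffix.lower() == ".sif" else "graphml")
    if fmt == "graphml":
        nx.write_graphml(graph, str(path))
        return path
    if fmt == "sif":
        edge_rows = []
        with open(path, "w") as fh:
            for i, j, key, d in sorted(graph.edges(keys=True, data=True)):
                fh.write(f"{i}\t{d['kind']}\t{j}\n")
                edge_rows.append(
                    {
                        "source": i,
                        "target": j,
                        "kind": d["kind"],
                        "gamma_ox": d["gamma_ox"],
                        "gamma_red": d["gamma_red"],
                        "delta": repr(d["delta"]),
                        "display_weight": repr(d["display_weight"]),
                    }
                )
        pd.DataFrame(edge_rows).to_csv(
            path.with_suffix(".edges.tsv"), sep="\t", index=False
        )
        node_rows = [
            {"residue": n, **{k: v for k, v in d.items() if k != "residue"}}
            for n, d in sorted(graph.nodes(data=True))
        ]
        pd.DataFrame(node_rows).to_csv(
            path.with_suffix(".nodes.tsv"), sep="\t", index=False
        )
        return path
    raise ValueError(f"unknown export format '{fmt}'")


def load_graphml(path: str | Path) -> nx.MultiGraph:
    """Re-import an exported GraphML network (attribute types preserved)."""
    g = nx.read_graphml(str(path), force_multigraph=True)
    return nx.relabel_nodes(g, {n: int(n) for n in g.nodes})


def write_drin_tsv(graphs: dict[str, DRINGraph], path: str | Path) -> Path:
    """Serialise per-type DRIN graphs as a TSV (state, kind, i, j, gamma)."""
    rows = []
    for kind in sorted(graphs):
        g = graphs[kind]
        for (i, j), gamma in sorted(g.edges.items()):
            rows.append(
                {
                    "state": g.state,
                    "kind": kind,
                    "res_i": i,
                    "res_j": j,
                    "gamma": gamma,
                    "n_frames": g.n_frames,
                }
            )
    pd.DataFrame(
        rows, columns=["state", "kind", "res_i", "res_j", "gamma", "n_frames"]
    ).to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_drin_tsv(path: str | Path) -> dict[str, DRINGraph]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, DRINGraph] = {}
    for kind, sub in df.groupby("kind"):
        g = DRINGraph(
            state=str(sub["state"].iloc[0]),
            kind=str(kind),
            n_frames=int(sub["n_frames"].iloc[0]),
        )
        for _, row in sub.iterrows():
            g.edges[(int(row.res_i), int(row.res_j))] = int(row.gamma)
        out[str(kind)] = g
    return out
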