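"""Thresholded epistasis graphs: construction, sweeps, components, degrees.

A statistical epistasis network G_t links two SNPs whenever their pair weight
(information gain) is >= t; a vertex is a member only if it has at least one
incident edge, so isolated SNPs are not part of the graph. As t decreases the
graphs nest: every edge and vertex of G_{t2} belongs to G_{t1} for t1 < t2.
The significance-filtered subgraph Ĝ_t keeps only edges whose permutation
p-value is at or below a cutoff (0.01 by default).

Graphs are plain :class:`networkx.Graph` objects carrying a ``threshold``
graph attribute, ``mutual_information`` on vertices and ``information_gain``
(plus ``p_value`` when available) on edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .infotheory import PairWeightTable

__all__ = [
    "build_graph",
    "filter_significant",
    "threshold_sweep",
    "threshold_grid",
    "connected_components",
    "degree_distribution",
    "DegreeDistribution",
    "ThresholdSweep",
    "write_edge_tsv",
    "write_vertex_tsv",
    "write_graphml",
    "write_dot",
]


def build_graph(pairs: PairWeightTable, mains: pd.Series | None,
                t: float) -> nx.Graph:
    """Build G_t: edges are pairs with weight >= t, vertices their endpoints.

    ``mains`` supplies the per-SNP mutual-information vertex weights; pass
    ``None`` to omit them. Ties at exactly ``t`` are included.
    """
    if not np.isfinite(t):
        if t == -np.inf:
            keep = np.ones(pairs.n_pairs, dtype=bool)
        else:
            raise ValueError("threshold must be finite or -inf")
    else:
        keep = pairs.weights >= t
    g = nx.Graph(threshold=float(t))
    ii, jj = pairs.pair_indices()
    ids = np.asarray(pairs.snp_ids, dtype=object)
    sel = np.flatnonzero(keep)
    for k in sel:
        a, b = ids[ii[k]], ids[jj[k]]
        attrs = {"information_gain": float(pairs.weights[k])}
        if pairs.p_values is not None:
            attrs["p_value"] = float(pairs.p_values[k])
        g.add_edge(a, b, **attrs)
    if mains is not None:
        for v in g.nodes:
            g.nodes[v]["mutual_information"] = float(mains[v])
    return g


def filter_significant(g: nx.Graph, alpha: float = 0.01) -> nx.Graph:
    """Ĝ_t: keep only edges with permutation p-value <= alpha.

    Vertices left without any incident edge are dropped (the graph contract
    requires degree >= 1). Idempotent at fixed alpha.
    """
    h = nx.Graph(**g.graph)
    h.graph["alpha"] = float(alpha)
    for a, b, attrs in g.edges(data=True):
        if "p_value" not in attrs:
            raise ValueError(
                f"edge ({a}, {b}) has no p_value; run the permutation "
                "significance step first"
            )
        if attrs["p_value"] <= alpha:
            h.add_edge(a, b, **attrs)
    for v in h.nodes:
        h.nodes[v].update(g.nodes[v])
    return h


def threshold_grid(t_max: float, t_min: float, step: float) -> np.ndarray:
    """Descending grid t_max, t_max - step, ..., down to t_min inclusive.

    Grid points snap to 1e-12 so floating-point drift cannot drop the final
    point.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    k = int(np.floor((t_max - t_min) / step + 1e-9)) + 1
    grid = t_max - step * np.arange(k)
    return np.round(grid / 1e-12) * 1e-12


@dataclass
class ThresholdSweep:
    """Per-threshold network summaries over a descending threshold grid."""

    thresholds: np.ndarray
    n_edges: np.ndarray
    n_vertices: np.ndarray
    lcc_size: np.ndarray
    component_sizes: list[list[int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_edges": self.n_edges,
            "n_vertices": self.n_vertices,
            "lcc_size": self.lcc_size,
        })

    def second_component_sizes(self) -> np.ndarray:
        return np.array([s[1] if len(s) > 1 else 0
                         for s in self.component_sizes])


class _DisjointSet:
    """Union-find over SNP indices with component-size tracking."""

    def __init__(self, m: int) -> None:
        self.parent = np.arange(m)
        self.size = np.ones(m, dtype=np.int64)
        self.member = np.zeros(m, dtype=bool)  # has >= 1 incident edge

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        self.member[a] = self.member[b] = True
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def component_sizes(self) -> list[int]:
        roots = {}
        for v in np.flatnonzero(self.member):
            r = self.find(int(v))
            roots[r] = int(self.size[r])
        return sorted(roots.values(), reverse=True)


def threshold_sweep(pairs: PairWeightTable, t_max: float = 0.02,
                    t_min: float = 0.0, step: float = 0.001) -> ThresholdSweep:
    """Sweep the threshold grid, computing summaries incrementally.

    Edges are sorted by weight once; the sweep walks the grid downward adding
    newly admitted edges to a union-find structure, so the whole sweep costs
    one sort plus one pass over the admitted edges. The result at each grid
    point is identical to an independent :func:`build_graph` there.
    """
    grid = threshold_grid(t_max, t_min, step)
    order = np.argsort(pairs.weights)[::-1]  # descending weight
    ii, jj = pairs.pair_indices()
    sorted_w = pairs.weights[order]
    dsu = _DisjointSet(pairs.n_snps)
    n_edges = np.zeros(grid.size, dtype=np.int64)
    n_vertices = np.zeros(grid.size, dtype=np.int64)
    lcc = np.zeros(grid.size, dtype=np.int64)
    comp_sizes: list[list[int]] = []
    pos = 0
    for gi, t in enumerate(grid):
        while pos < sorted_w.size and sorted_w[pos] >= t:
            k = order[pos]
            dsu.union(int(ii[k]), int(jj[k]))
            pos += 1
        sizes = dsu.component_sizes()
        n_edges[gi] = pos
        n_vertices[gi] = int(dsu.member.sum())
        lcc[gi] = sizes[0] if sizes else 0
        comp_sizes.append(sizes)
    return ThresholdSweep(grid, n_edges, n_vertices, lcc, comp_sizes)


def connected_components(g: nx.Graph) -> list[set]:
    """Connected components as vertex sets, largest first.

    Size ties break deterministically by the lexicographically smallest
    member.
    """
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


@dataclass
class DegreeDistribution:
    """Empirical vertex-degree distribution of an epistasis graph.

    ``counts`` maps degree d >= 1 to the number of vertices n(d);
    ``p(d) = n(d) / n_vertices``. By the handshake lemma
    ``sum_d d * n(d) == 2 * n_edges``.
    """

    counts: dict[int, int]
    n_vertices: int

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.counts):
            raise ValueError("graph vertices have degree >= 1 by contract")
        if sum(self.counts.values()) != self.n_vertices:
            raise ValueError("degree counts must sum to n_vertices")

    @property
    def n_edges(self) -> int:
        return sum(d * n for d, n in self.counts.items()) // 2

    @property
    def max_degree(self) -> int:
        return max(self.counts) if self.counts else 0

    def p(self, d: int) -> float:
        return self.counts.get(d, 0) / self.n_vertices

    def degrees(self) -> np.ndarray:
        """Expanded per-vertex degree array (sorted ascending)."""
        return np.repeat(sorted(self.counts),
                         [self.counts[d] for d in sorted(self.counts)])

    def support(self) -> np.ndarray:
        """Degrees with nonzero counts, ascending."""
        return np.array(sorted(self.counts))

    @classmethod
    def from_probabilities(cls, probs: dict[int, float],
                           n_vertices: int) -> "DegreeDistribution":
        """Reconstruct integer counts from printed fractions p(d).

        Each count is the nearest integer to p(d) * n_vertices; the rounded
        counts must sum back to ``n_vertices``.
        """
        counts = {d: round(p * n_vertices) for d, p in probs.items() if p > 0}
        return cls(counts=counts, n_vertices=n_vertices)


def degree_distribution(g: nx.Graph) -> DegreeDistribution:
    """Degree counts over the graph's member vertices (degree >= 1)."""
    counts: dict[int, int] = {}
    for _, d in g.degree():
        counts[d] = counts.get(d, 0) + 1
    return DegreeDistribution(counts=counts, n_vertices=g.number_of_nodes())


# -- exports ------------------------------------------------------------------

def write_edge_tsv(g: nx.Graph, path: str | Path,
                   header_comment: str = "") -> None:
    rows = [{"snp_a": a, "snp_b": b,
             "information_gain": attrs.get("information_gain", np.nan),
             **({"p_value": attrs["p_value"]} if "p_value" in attrs else {})}
            for a, b, attrs in sorted(g.edges(data=True))]
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.12g")


def write_vertex_tsv(g: nx.Graph, path: str | Path,
                     header_comment: str = "") -> None:
    rows = [{"snp_id": v, "degree": g.degree(v),
             "mutual_information": g.nodes[v].get("mutual_information",
                                                  np.nan)}
            for v in sorted(g.nodes)]
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.12g")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_dot(g: nx.Graph, path: str | Path, max_vertex_size: float = 2.0,
              max_edge_width: float = 8.0) -> None:
    """Graphviz DOT export with vertex size proportional to main effect and
    edge penwidth proportional to information gain.

    Scaling factors are recorded in a header comment so renderings are
    reproducible. Layout itself is left to Graphviz.
    """
    mains = [g.nodes[v].get("mutual_information", 0.0) for v in g.nodes]
    weights = [a.get("information_gain", 0.0) for *_, a in g.edges(data=True)]
    vmax = max(mains, default=0.0) or 1.0
    wmax = max(weights, default=0.0) or 1.0
    vscale = max_vertex_size / vmax
    wscale = max_edge_width / wmax
    with open(path, "w") as fh:
        fh.write("// vertex width = mutual_information * "
                 f"{vscale:.6g} (inches)\n")
        fh.write(f"// edge penwidth = information_gain * {wscale:.6g}\n")
        fh.write("graph epistasis {\n  node [shape=circle, fixedsize=true];\n")
        for v in sorted(g.nodes):
            w = g.nodes[v].get("mutual_information", 0.0) * vscale
            fh.write(f'  "{v}" [width={max(w, 0.05):.4f}];\n')
        for a, b, attrs in sorted(g.edges(data=True)):
            pw = attrs.get("information_gain", 0.0) * wscale
            fh.write(f'  "{a}" -- "{b}" [penwidth={max(pw, 0.1):.4f}];\n')
        fh.write("}\n")
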