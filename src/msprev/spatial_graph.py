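"""Province adjacency and the intrinsic CAR (Besag) spatial prior.

The ICAR prior is an improper Gaussian Markov random field on an undirected
areal graph: conditional on the rest of the field, each node's effect is
normal around the average of its neighbours,

    u_j | u_{-j}  ~  N( mean(u_l : l in delta_j),  1 / (tau * n_j) ),

where ``delta_j`` is the neighbourhood set and ``n_j = |delta_j|``.  The
joint (improper) log-density is the pairwise-difference form

    log p(u | tau)  =  const + (r/2) log tau - (tau/2) * sum_{j~l} (u_j - u_l)^2

with one term per undirected edge and ``r = n_nodes - n_components`` the
rank of the graph Laplacian (the power of tau in the pseudo-determinant).
The conditional variance shrinks with the neighbour count, so edge regions
with few neighbours carry more prior variance — the prior is adaptive to the
irregular adjacency of real province maps.

Impropriety is handled by a sum-to-zero convention per connected component.
Isolated nodes take no part in the ICAR field; policy is to pin their u at 0
and let the area rely on its uncorrelated effect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AdjacencyGraph",
    "SpatialField",
    "IsolatedNodeError",
    "build_adjacency",
    "icar_full_conditional",
    "icar_log_density",
    "icar_pairwise_ss",
    "sample_icar_field",
]


class IsolatedNodeError(ValueError):
    """Raised when an ICAR full conditional is requested for a node with no
    neighbours.  Isolated nodes are pinned at u = 0 by policy; their area's
    heterogeneity is carried entirely by the uncorrelated effect."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric areal adjacency with no self-loops.

    Nodes are 0-based internally; file formats use 1-based ids.  ``edges``
    holds each undirected edge once with ``edges[e,0] < edges[e,1]``.
    """

    n_nodes: int
    neighbors: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.neighbors) != self.n_nodes:
            raise ValueError("neighbors must have one entry per node")
        for j, nbrs in enumerate(self.neighbors):
            if j in nbrs:
                raise ValueError(f"self-loop at node {j}")
            for l in nbrs:
                if not 0 <= l < self.n_nodes:
                    raise ValueError(f"neighbor {l} of node {j} out of range")
                if j not in self.neighbors[l]:
                    raise ValueError(f"asymmetric adjacency between {j} and {l}")
        if self.isolated_nodes:
            warnings.warn(
                f"graph has isolated nodes {self.isolated_nodes}; their spatial "
                "effect is pinned at 0",
                stacklevel=2,
            )

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[int, int]], n_nodes: int | None = None,
        one_based: bool = False,
    ) -> "AdjacencyGraph":
        """Build from an (optionally 1-based) edge list; symmetrises and
        deduplicates, warning if the input was asymmetric or duplicated."""
        off = 1 if one_based else 0
        seen: set[tuple[int, int]] = set()
        raw = 0
        for a, b in edges:
            a, b = int(a) - off, int(b) - off
            if a == b:
                raise ValueError(f"self-loop on node {a + off}")
            raw += 1
            seen.add((min(a, b), max(a, b)))
        if not seen and n_nodes is None:
            raise ValueError("empty edge list and no n_nodes given")
        max_node = max((b for _, b in seen), default=-1)
        if n_nodes is None:
            n_nodes = max_node + 1
        elif max_node >= n_nodes:
            raise ValueError(f"node id {max_node + off} exceeds n_nodes={n_nodes}")
        if min((a for a, _ in seen), default=0) < 0:
            raise ValueError("node ids must be >= " + ("1" if one_based else "0"))
        if raw > len(seen):
            warnings.warn(
                f"{raw - len(seen)} duplicate/asymmetric edges collapsed", stacklevel=2
            )
        nbrs: list[set[int]] = [set() for _ in range(n_nodes)]
        for a, b in seen:
            nbrs[a].add(b)
            nbrs[b].add(a)
        return cls(n_nodes=n_nodes, neighbors=tuple(tuple(sorted(s)) for s in nbrs))

    @classmethod
    def from_edge_list_file(cls, path: str | Path, n_nodes: int | None = None) -> "AdjacencyGraph":
        """Two-column delimited text of 1-based node ids; '#' starts a comment."""
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            pairs.append((int(parts[0]), int(parts[1])))
        return cls.from_edges(pairs, n_nodes=n_nodes, one_based=True)

    @classmethod
    def from_polygons(
        cls, path: str | Path, id_property: str | None = None
    ) -> "AdjacencyGraph":
        """Queen contiguity from a GeoJSON FeatureCollection of polygons.

        Two areas are neighbours when their polygons share at least one
        boundary point (queen rule).  Features are ordered by ``id_property``
        (1-based integer ids) when given, else by file order.
        """
        from shapely.geometry import shape

        with open(path) as fh:
            gj = json.load(fh)
        feats = gj["features"]
        geoms = [shape(f["geometry"]) for f in feats]
        if id_property is not None:
            order = np.argsort([int(f["properties"][id_property]) for f in feats])
            ids = sorted(int(f["properties"][id_property]) for f in feats)
            if ids != list(range(1, len(feats) + 1)):
                raise ValueError("id_property must enumerate 1..n_features")
            geoms = [geoms[i] for i in order]
        edges = []
        for a in range(len(geoms)):
            for b in range(a + 1, len(geoms)):
                if geoms[a].intersects(geoms[b]) and not geoms[a].overlaps(geoms[b]):
                    edges.append((a, b))
                elif geoms[a].overlaps(geoms[b]):  # sloppy digitisation still counts
                    edges.append((a, b))
        return cls.from_edges(edges, n_nodes=len(geoms))

    # -- derived structure --------------------------------------------------

    @property
    def n_neighbors(self) -> np.ndarray:
        return np.array([len(s) for s in self.neighbors], dtype=np.int64)

    @property
    def isolated_nodes(self) -> tuple[int, ...]:
        return tuple(j for j, s in enumerate(self.neighbors) if not s)

    @property
    def edges(self) -> np.ndarray:
        """(n_edges, 2) array, each undirected edge once, col0 < col1."""
        out = [(j, l) for j, s in enumerate(self.neighbors) for l in s if j < l]
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @property
    def components(self) -> tuple[tuple[int, ...], ...]:
        comps = nx.connected_components(self.to_networkx())
        return tuple(tuple(sorted(c)) for c in comps)

    @property
    def rank(self) -> int:
        """Rank of the graph Laplacian: n_nodes - n_components (tau's power
        in the ICAR pseudo-determinant)."""
        return self.n_nodes - len(self.components)

    def laplacian(self) -> np.ndarray:
        """Dense combinatorial Laplacian D - W."""
        L = np.zeros((self.n_nodes, self.n_nodes))
        for j, l in self.edges:
            L[j, j] += 1
            L[l, l] += 1
            L[j, l] -= 1
            L[l, j] -= 1
        return L

    def coloring(self) -> tuple[np.ndarray, ...]:
        """Partition of the nodes into independent sets (greedy colouring),
        used to vectorise single-site ICAR updates."""
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        n_colors = max(colors.values(), default=-1) + 1
        return tuple(
            np.array(sorted(j for j, c in colors.items() if c == col), dtype=np.int64)
            for col in range(n_colors)
        )

    def write_edge_list(self, path: str | Path) -> None:
        """Export as 1-based two-column edge list with a neighbour-count
        comment header."""
        lines = ["# edge list (1-based ids); n_neighbors: "
                 + " ".join(map(str, self.n_neighbors))]
        lines += [f"{a + 1}\t{b + 1}" for a, b in self.edges]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SpatialField:
    """An ICAR field: one real value per node and a precision tau > 0."""

    values: np.ndarray
    precision: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SpatialField values must be finite")
        if not self.precision > 0:
            raise ValueError("SpatialField precision must be positive")


def build_adjacency(
    source: str | Path | Iterable[tuple[int, int]],
    n_nodes: int | None = None,
    id_property: str | None = None,
) -> AdjacencyGraph:
    """Build an :class:`AdjacencyGraph` from a polygon file (GeoJSON, queen
    contiguity), an edge-list file, or an in-memory 1-based edge iterable."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix.lower() in (".geojson", ".json"):
            return AdjacencyGraph.from_polygons(p, id_property=id_property)
        return AdjacencyGraph.from_edge_list_file(p, n_nodes=n_nodes)
    return AdjacencyGraph.from_edges(source, n_nodes=n_nodes, one_based=True)


def icar_full_conditional(
    field: SpatialField, graph: AdjacencyGraph, j: int
) -> tuple[float, float]:
    """Conditional mean and variance of node ``j`` given the rest.

    mean = average of the neighbours' values; variance = 1/(tau * n_j).
    """
    nbrs = graph.neighbors[j]
    if not nbrs:
        raise IsolatedNodeError(
            f"node {j} has no neighbors; by policy its spatial effect is fixed "
            "at 0 and the uncorrelated effect absorbs its heterogeneity"
        )
    vals = field.values[list(nbrs)]
    return float(vals.mean()), 1.0 / (field.precision * len(nbrs))


def icar_pairwise_ss(values: np.ndarray, graph: AdjacencyGraph) -> float:
    """Sum over undirected edges of (u_j - u_l)^2."""
    e = graph.edges
    if len(e) == 0:
        return 0.0
    d = values[e[:, 0]] - values[e[:, 1]]
    return float(d @ d)


def icar_log_density(
    field: SpatialField, graph: AdjacencyGraph, normalized: bool = True
) -> float:
    """Improper ICAR log-density in the pairwise-difference form.

    With ``normalized`` the tau-dependent normalising term
    ``(r/2) log(tau / 2 pi)`` is included (r = Laplacian rank), which is what
    precision updates require; the tau-free pseudo-determinant constant is
    omitted throughout, so densities are comparable across fields and
    precisions on a fixed graph but not across graphs.
    """
    tau = field.precision
    val = -0.5 * tau * icar_pairwise_ss(field.values, graph)
    if normalized:
        val += 0.5 * graph.rank * (np.log(tau) - np.log(2.0 * np.pi))
    return float(val)


def sample_icar_field(
    graph: AdjacencyGraph,
    tau: float,
    seed: int | np.random.Generator | None = None,
) -> SpatialField:
    """Draw one field from the sum-to-zero-constrained ICAR distribution.

    Per connected component the constrained density is a proper Gaussian with
    covariance ``(1/tau) * pinv(L)`` on the component's Laplacian ``L``; the
    draw is formed in the Laplacian eigenbasis using the positive eigenvalues
    only, which enforces the component-wise zero-sum exactly.  Isolated nodes
    get 0.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = np.zeros(graph.n_nodes)
    L = graph.laplacian()
    for comp in graph.components:
        idx = np.array(comp)
        if len(idx) == 1:
            continue
        w, V = np.linalg.eigh(L[np.ix_(idx, idx)])
        pos = w > 1e-10 * w.max()
        z = rng.standard_normal(int(pos.sum()))
        u[idx] = V[:, pos] @ (z / np.sqrt(tau * w[pos]))
        u[idx] -= u[idx].mean()  # exact re-centering against roundoff
    return SpatialField(values=u, precision=tau)
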