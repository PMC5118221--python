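"""Spatial and temporal neighbourhood structures for ICAR priors.

The spatial prior penalises squared differences of the latent field across
areas sharing a boundary (binary 0/1 adjacency W); the temporal prior is the
same construction on the path graph over consecutive months (first-order
random walk).  Both reduce to a quadratic form x'Rx with structure matrix
R = diag(degree) - adjacency, which is singular: its null space is spanned by
the indicator of each connected component, hence the per-component
sum-to-zero constraints used throughout the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.sparse as sp


class GraphInputError(ValueError):
    """Raised for malformed edge lists or invalid graph parameters."""


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected, loop-free adjacency over study areas.

    Areas are indexed 0..n_areas-1 in the order of ``labels``; ``edges`` holds
    unordered index pairs (i < j).
    """

    n_areas: int
    edges: frozenset[tuple[int, int]]
    labels: tuple[str, ...]
    degree: np.ndarray = field(repr=False)
    components: tuple[tuple[int, ...], ...] = field(repr=False)

    @property
    def connected(self) -> bool:
        return len(self.components) == 1

    @property
    def n_components(self) -> int:
        return len(self.components)

    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}


@dataclass(frozen=True)
class TemporalGraph:
    """Path graph over consecutive time points (random-walk neighbourhood)."""

    n_times: int

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        return frozenset((t, t + 1) for t in range(self.n_times - 1))

    @property
    def degree(self) -> np.ndarray:
        d = np.full(self.n_times, 2)
        d[0] = d[-1] = 1
        return d

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(str(t) for t in range(self.n_times))

    @property
    def components(self) -> tuple[tuple[int, ...], ...]:
        return (tuple(range(self.n_times)),)

    @property
    def connected(self) -> bool:
        return True


@dataclass(frozen=True)
class IcarStructure:
    """Structure matrix R = D - W of an ICAR prior, with its null space.

    rank = n - n_components; the null space is piecewise constant on the
    connected components, so R @ 1 = 0.
    """

    R: sp.csr_matrix = field(repr=False)
    rank: int
    components: tuple[tuple[int, ...], ...]
    edges: tuple[tuple[int, int], ...] = field(repr=False)

    @property
    def n(self) -> int:
        return self.R.shape[0]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def null_space_basis(self) -> np.ndarray:
        """Orthonormal basis of ker(R): one normalised indicator per component."""
        basis = np.zeros((self.n, self.n_components))
        for k, comp in enumerate(self.components):
            idx = np.asarray(comp)
            basis[idx, k] = 1.0 / np.sqrt(len(idx))
        return basis


def build_spatial_graph(edge_list, area_labels) -> SpatialGraph:
    """Build the area adjacency graph from labelled edges.

    Parameters
    ----------
    edge_list : iterable of (label, label)
        Unordered pairs of areas sharing a boundary.  May be empty (all areas
        isolated — every structured effect then pinned at 0).
    area_labels : sequence
        Ordered labels of all modelled areas; fixes the 0-based indexing.
    """
    labels = tuple(str(a) for a in area_labels)
    if len(set(labels)) != len(labels):
        raise GraphInputError("duplicate area labels")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    edges = set()
    for a, b in edge_list:
        a, b = str(a), str(b)
        if a not in index or b not in index:
            missing = [x for x in (a, b) if x not in index]
            raise GraphInputError(f"edge references unknown label(s): {missing}")
        i, j = index[a], index[b]
        if i == j:
            raise GraphInputError(f"self-loop on area {a!r}")
        edges.add((min(i, j), max(i, j)))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    degree = np.array([g.degree(i) for i in range(n)], dtype=int)
    comps = tuple(tuple(sorted(c)) for c in nx.connected_components(g))
    comps = tuple(sorted(comps, key=lambda c: c[0]))
    return SpatialGraph(
        n_areas=n,
        edges=frozenset(edges),
        labels=labels,
        degree=degree,
        components=comps,
    )


def build_temporal_graph(n_times: int) -> TemporalGraph:
    """Path graph over ``n_times`` consecutive time points."""
    if n_times < 2:
        raise GraphInputError(f"need at least 2 time points, got {n_times}")
    return TemporalGraph(n_times=int(n_times))


def icar_structure(graph) -> IcarStructure:
    """Assemble R = diag(degree) - adjacency for a spatial or temporal graph."""
    n = graph.n_areas if isinstance(graph, SpatialGraph) else graph.n_times
    edges = tuple(sorted(graph.edges))
    rows, cols, vals = [], [], []
    deg = np.zeros(n)
    for i, j in edges:
        rows += [i, j]
        cols += [j, i]
        vals += [-1.0, -1.0]
        deg[i] += 1
        deg[j] += 1
    rows += list(range(n))
    cols += list(range(n))
    vals += list(deg)
    R = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    comps = graph.components
    return IcarStructure(R=R, rank=n - len(comps), components=comps, edges=edges)


def icar_quadform(x, structure: IcarStructure) -> float:
    """x'Rx = sum over graph edges of (x_i - x_j)^2, the ICAR log-kernel core."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != structure.n:
        raise GraphInputError(
            f"vector length {x.shape[-1]} != structure size {structure.n}"
        )
    # row-wise support lets the sampler evaluate many fields at once
    if not structure.edges:
        return 0.0 if x.ndim == 1 else np.zeros(x.shape[0])
    e = np.asarray(structure.edges)
    d = x[..., e[:, 0]] - x[..., e[:, 1]]
    return np.sum(d * d, axis=-1)


def read_edge_list_csv(path) -> list[tuple[str, str]]:
    """Two-column CSV of area-label pairs; header required, '#' comments skipped."""
    edges = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise GraphInputError(f"malformed edge row: {line!r}")
            edges.append((parts[0], parts[1]))
    if header is None:
        raise GraphInputError("edge-list file is empty (header required)")
    return edges


def read_gal(path) -> list[tuple[str, str]]:
    """Neighbour list in GAL-like format: count header, then per area a
    'label n_neigh' line followed by a line of neighbour labels."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise GraphInputError("empty GAL file")
    edges = []
    i = 1  # skip count header
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 2:
            raise GraphInputError(f"malformed GAL header line: {lines[i]!r}")
        label, n_neigh = head[0], int(head[1])
        i += 1
        neighbours = lines[i].split() if n_neigh > 0 else []
        if n_neigh > 0:
            if len(neighbours) != n_neigh:
                raise GraphInputError(
                    f"area {label!r}: expected {n_neigh} neighbours, got {len(neighbours)}"
                )
            i += 1
        for nb in neighbours:
            if nb != label:
                edges.append(tuple(sorted((label, nb))))
    return sorted(set(edges))
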