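"""Block contiguity graphs and the intrinsic CAR (ICAR) precision structure.

The spatial random effect of the BYM model smooths each block's estimate
toward the mean of the blocks it shares a border with.  This module builds
that neighbourhood structure — from polygon geometries (rook or queen
contiguity) or from an explicit edge list — and exposes the ICAR precision
matrix Q with Q_ii = degree(i) and Q_ij = -1 for neighbours.  Q is rank
deficient: the indicator vector of each connected component spans its null
space, which is why ICAR fields are constrained to sum to zero per component.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from shapely.geometry import shape as _shapely_shape
from shapely import set_precision as _set_precision

BlockId = Hashable

__all__ = [
    "BlockGraph",
    "IcarPrecision",
    "build_graph_from_polygons",
    "build_graph_from_edgelist",
    "build_graph_from_geojson",
    "icar_precision",
    "sample_icar_field",
    "make_lattice",
]


@dataclass(frozen=True)
class BlockGraph:
    """Contiguity graph over blocks.

    Parameters
    ----------
    block_ids
        Ordered block identifiers; this order indexes every vector and the
        rows/columns of the ICAR precision matrix.
    edges
        Unordered neighbour pairs, stored as sorted-by-position tuples of
        block ids; symmetric, no self-loops.
    """

    block_ids: tuple[BlockId, ...]
    edges: frozenset[tuple[BlockId, BlockId]]
    components: tuple[frozenset[BlockId], ...] = field(default=())

    def __post_init__(self) -> None:
        ids = self.block_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate block ids")
        known = set(ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on block {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown block")
        if not self.components:
            g = self.to_networkx()
            comps = tuple(
                frozenset(c) for c in sorted(nx.connected_components(g), key=lambda c: min(self.index(b) for b in c))
            )
            object.__setattr__(self, "components", comps)
        covered = set().union(*self.components) if self.components else set()
        if covered != known:
            raise ValueError("components do not partition block_ids")

    # -- convenience -----------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.block_ids)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def index(self, block_id: BlockId) -> int:
        try:
            return self._index[block_id]
        except AttributeError:
            object.__setattr__(self, "_index", {b: i for i, b in enumerate(self.block_ids)})
            return self._index[block_id]

    def edge_index_pairs(self) -> np.ndarray:
        """Edges as an (n_edges, 2) array of integer positions, i < j."""
        pairs = sorted(
            (min(self.index(a), self.index(b)), max(self.index(a), self.index(b))) for a, b in self.edges
        )
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_blocks, dtype=np.int64)
        for i, j in self.edge_index_pairs():
            deg[i] += 1
            deg[j] += 1
        return deg

    def component_labels(self) -> np.ndarray:
        """Integer component label per block, in block order."""
        lab = np.empty(self.n_blocks, dtype=np.int64)
        for k, comp in enumerate(self.components):
            for b in comp:
                lab[self.index(b)] = k
        return lab

    def neighbors(self, block_id: BlockId) -> list[BlockId]:
        out = []
        for a, b in self.edges:
            if a == block_id:
                out.append(b)
            elif b == block_id:
                out.append(a)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.block_ids)
        g.add_edges_from(self.edges)
        return g

    def relabel(self, mapping: dict[BlockId, BlockId]) -> "BlockGraph":
        return BlockGraph(
            block_ids=tuple(mapping[b] for b in self.block_ids),
            edges=frozenset(_norm_edge(mapping[a], mapping[b]) for a, b in self.edges),
        )


@dataclass(frozen=True)
class IcarPrecision:
    """ICAR precision matrix Q (sparse CSR) and its rank deficiency."""

    Q: sp.csr_matrix
    rank_deficiency: int

    @property
    def n_blocks(self) -> int:
        return self.Q.shape[0]


def _norm_edge(a: BlockId, b: BlockId) -> tuple[BlockId, BlockId]:
    # canonical order by string repr so frozenset members are tuples
    return (a, b) if str(a) <= str(b) else (b, a)


def build_graph_from_edgelist(pairs: Iterable[tuple[BlockId, BlockId]], ids: Sequence[BlockId]) -> BlockGraph:
    """Build a :class:`BlockGraph` from explicit neighbour pairs.

    Pairs are symmetrized and deduplicated; self-loops and pairs naming
    unknown blocks are rejected.
    """
    ids = tuple(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate block ids")
    known = set(ids)
    edges = set()
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-loop pair ({a!r}, {b!r})")
        if a not in known or b not in known:
            raise ValueError(f"pair ({a!r}, {b!r}) references a block not in ids")
        edges.add(_norm_edge(a, b))
    return BlockGraph(block_ids=ids, edges=frozenset(edges))


def build_graph_from_polygons(
    geometries: dict[BlockId, object],
    contiguity: str = "rook",
    snap: float = 1e-9,
) -> BlockGraph:
    """Contiguity graph from per-block (multi)polygons.

    Rook contiguity (the default): two blocks are neighbours iff their
    boundaries share a segment of positive length — a border, not a corner
    point.  Queen contiguity additionally links blocks that touch at a point.
    Coordinates are snapped to a grid of size ``snap`` first, so sliver gaps
    from floating-point geometry do not break borders.
    """
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    ids = list(geometries)
    if len(set(ids)) != len(ids):  # dict keys are unique, but keep the contract explicit
        raise ValueError("duplicate block ids")
    geoms = {}
    for bid, g in geometries.items():
        if g is None or getattr(g, "is_empty", True):
            raise ValueError(f"empty geometry for block {bid!r}")
        geoms[bid] = _set_precision(g, snap) if snap else g

    edges = set()
    id_list = list(geoms)
    # bounding-box prefilter via an STRtree would help at scale; n<=~600 here
    for i, a in enumerate(id_list):
        ga = geoms[a]
        for b in id_list[i + 1 :]:
            gb = geoms[b]
            if not ga.intersects(gb):
                continue
            inter = ga.boundary.intersection(gb.boundary)
            shared_border = inter.length > 0
            if contiguity == "rook":
                if shared_border:
                    edges.add(_norm_edge(a, b))
            else:  # queen: any touching counts
                edges.add(_norm_edge(a, b))
    return BlockGraph(block_ids=tuple(id_list), edges=frozenset(edges))


def build_graph_from_geojson(path, id_property: str = "block_id", contiguity: str = "rook") -> BlockGraph:
    """Read a GeoJSON FeatureCollection (one Feature per block) into a graph."""
    with open(path) as fh:
        fc = json.load(fh)
    geoms: dict[BlockId, object] = {}
    for feat in fc["features"]:
        bid = feat["properties"][id_property]
        if bid in geoms:
            raise ValueError(f"duplicate block id {bid!r} in GeoJSON")
        geoms[bid] = _shapely_shape(feat["geometry"])
    return build_graph_from_polygons(geoms, contiguity=contiguity)


def read_edgelist_csv(edges_path, blocks_path=None, ids: Sequence[BlockId] | None = None) -> BlockGraph:
    """Edge-list CSV (`block_a,block_b`) with the id universe from `blocks.csv`
    (column `block_id`) or an explicit id list."""
    if ids is None:
        if blocks_path is None:
            raise ValueError("need either blocks_path or ids for the block universe")
        with open(blocks_path, newline="") as fh:
            ids = [row["block_id"] for row in csv.DictReader(fh)]
    with open(edges_path, newline="") as fh:
        pairs = [(row["block_a"], row["block_b"]) for row in csv.DictReader(fh)]
    return build_graph_from_edgelist(pairs, ids)


def icar_precision(graph: BlockGraph) -> IcarPrecision:
    """ICAR precision matrix: Q_ii = degree(i), Q_ij = -1 iff i ~ j.

    Every row sums to zero; the rank deficiency equals the number of
    connected components.
    """
    n = graph.n_blocks
    pairs = graph.edge_index_pairs()
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        rows = np.concatenate([i, j, np.arange(n)])
        cols = np.concatenate([j, i, np.arange(n)])
        deg = graph.degrees().astype(float)
        vals = np.concatenate([-np.ones(2 * len(pairs)), deg])
    else:
        rows = cols = np.arange(n)
        vals = np.zeros(n)
    Q = sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
    return IcarPrecision(Q=Q, rank_deficiency=graph.n_components)


def _center_per_component(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = x.copy()
    for k in np.unique(labels):
        m = labels == k
        out[m] -= out[m].mean()
    return out


def sample_icar_field(
    precision: IcarPrecision,
    tau_u: float,
    seed: int | np.random.Generator,
    graph: BlockGraph | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw from the intrinsic ICAR density with precision ``tau_u * Q``,
    constrained to sum to zero within each connected component.

    The draw is constructed on the eigenbasis of Q restricted to its row
    space (eigenvalues > 0), which is exactly the sum-to-zero-per-component
    subspace; each retained coordinate is Normal(0, 1/(tau_u * lambda_k)).
    Deterministic given the seed.
    """
    if tau_u <= 0:
        raise ValueError(f"tau_u must be > 0, got {tau_u}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Qd = precision.Q.toarray()
    evals, evecs = np.linalg.eigh(Qd)
    tol = max(Qd.shape[0], 1) * np.finfo(float).eps * max(evals.max(initial=1.0), 1.0)
    keep = evals > tol
    n_draws = 1 if size is None else size
    z = rng.standard_normal((n_draws, keep.sum()))
    fields = (z / np.sqrt(tau_u * evals[keep])) @ evecs[:, keep].T
    if graph is not None:
        labels = graph.component_labels()
        fields = np.stack([_center_per_component(f, labels) for f in fields])
    else:
        fields = fields - fields.mean(axis=1, keepdims=True) if precision.rank_deficiency == 1 else fields
    return fields[0] if size is None else fields


def make_lattice(rows: int, cols: int, drop: Iterable[tuple[int, int]] = ()) -> BlockGraph:
    """Rook-contiguity grid graph with ``rows * cols`` blocks.

    ``drop`` removes (row, col) cells, for carving irregular maps out of a
    rectangle.  Block ids are strings ``"B{row}_{col}"``.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"rows and cols must be >= 1, got ({rows}, {cols})")
    dropped = set(drop)
    ids = [f"B{r}_{c}" for r in range(rows) for c in range(cols) if (r, c) not in dropped]
    idset = set(ids)
    edges = set()
    for r in range(rows):
        for c in range(cols):
            a = f"B{r}_{c}"
            if a not in idset:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                b = f"B{r + dr}_{c + dc}"
                if b in idset:
                    edges.add(_norm_edge(a, b))
    return BlockGraph(block_ids=tuple(ids), edges=frozenset(edges))


def lattice_geojson(rows: int, cols: int, drop: Iterable[tuple[int, int]] = ()) -> dict:
    """Unit-square GeoJSON FeatureCollection matching :func:`make_lattice` ids."""
    dropped = set(drop)
    feats = []
    for r in range(rows):
        for c in range(cols):
            if (r, c) in dropped:
                continue
            ring = [[c, r], [c + 1, r], [c + 1, r + 1], [c, r + 1], [c, r]]
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"block_id": f"B{r}_{c}"},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    return {"type": "FeatureCollection", "features": feats}
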