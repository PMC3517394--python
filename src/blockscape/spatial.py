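"""Queen-contiguity block adjacency and moving-window neighborhoods.

Census blocks are the anchor unit.  Two blocks are adjacent ("queen"
contiguity) when their boundaries share a line segment *or* a single corner
vertex.  Around every block we build overlapping moving-window communities:

* order 0 — the block itself;
* order 1 — the primary adjacency community (PAC): the block plus all
  adjacent blocks;
* order 2 — the secondary adjacency community (SAC): the PAC plus all blocks
  adjacent to any PAC member.

Equivalently, the order-k window is the graph-distance ball of radius k in
the adjacency graph.  Unlike census block groups these windows overlap, so
each block gets its own neighborhood context.

Coordinates are assumed planar/projected.  Because real boundary files carry
small misalignments, contact is detected with a snap tolerance (default
1e-6 map units) rather than exact coordinate equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "Blocks",
    "CommunityWindow",
    "read_blocks",
    "validate_blocks",
    "build_adjacency",
    "community_window",
    "all_windows",
    "assign_points_to_blocks",
    "adjacency_to_frame",
    "windows_to_frame",
]

DEFAULT_TOLERANCE = 1e-6

#: block_id -> polygonal geometry, insertion-ordered.
Blocks = dict

_GEOGRAPHIC_CRS_TOKENS = ("4326", "CRS84", "WGS84", "WGS 84")


class BlockGeometryError(ValueError):
    """A block polygon layer violates the input contract."""


def read_blocks(
    path: Union[str, Path],
    id_property: str = "GEOID",
    allow_geographic: bool = False,
) -> Blocks:
    """Read block polygons from a GeoJSON FeatureCollection.

    ``id_property`` names the feature property holding the block identifier.
    Files that declare a geographic (lon/lat) CRS are rejected unless
    ``allow_geographic`` is set, because the snap tolerance is expressed in
    map units and degrees are hazardous.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BlockGeometryError(f"{path}: not valid GeoJSON ({exc})") from None
    if doc.get("type") != "FeatureCollection":
        raise BlockGeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    crs_name = str(doc.get("crs", {}).get("properties", {}).get("name", ""))
    if not allow_geographic and any(tok in crs_name for tok in _GEOGRAPHIC_CRS_TOKENS):
        raise BlockGeometryError(
            f"{path}: declares geographic CRS {crs_name!r}; project the data or "
            "pass allow_geographic=True"
        )
    blocks: Blocks = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise BlockGeometryError(
                f"feature missing id property {id_property!r}: {sorted(props)}"
            )
        bid = str(props[id_property])
        if bid in blocks:
            raise BlockGeometryError(f"duplicate block_id {bid!r}")
        blocks[bid] = _shape(feat["geometry"])
    validate_blocks(blocks)
    return blocks


def validate_blocks(blocks: Mapping[str, BaseGeometry]) -> None:
    """Reject empty layers, non-polygonal, invalid, or zero-area geometries."""
    if not blocks:
        raise BlockGeometryError("no block geometries supplied")
    for bid, geom in blocks.items():
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise BlockGeometryError(f"block {bid!r}: {geom.geom_type} is not polygonal")
        if not geom.is_valid:
            raise BlockGeometryError(
                f"block {bid!r}: invalid ring ({shapely.is_valid_reason(geom)})"
            )
        if geom.area <= 0:
            raise BlockGeometryError(f"block {bid!r}: zero or negative area")


def build_adjacency(
    blocks: Mapping[str, BaseGeometry],
    tolerance: float = DEFAULT_TOLERANCE,
) -> nx.Graph:
    """Queen-contiguity adjacency graph over a block layer.

    An edge joins blocks a and b iff their geometries come within
    ``tolerance`` of touching — a shared boundary segment and a shared corner
    vertex both qualify.  Multipart blocks are adjacent if any part touches
    any part.  Returns an undirected :class:`networkx.Graph` whose nodes are
    block ids; the tolerance used is stored in ``graph.graph["tolerance"]``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    validate_blocks(blocks)
    ids = list(blocks)
    geoms = [blocks[b] for b in ids]
    graph = nx.Graph(tolerance=float(tolerance))
    graph.add_nodes_from(ids)
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="dwithin", distance=float(tolerance))
    for i, j in zip(left.tolist(), right.tolist()):
        if i < j:
            graph.add_edge(ids[i], ids[j])
    return graph


@dataclass(frozen=True)
class CommunityWindow:
    """A focal block plus its order-k queen-contiguity neighborhood."""

    focal: str
    order: int
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.focal not in self.members:
            raise ValueError("focal block must be a member of its own window")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, block_id: str) -> bool:
        return block_id in self.members


_LEVEL_ORDERS = {"block": 0, "pac": 1, "sac": 2}
_ORDER_LEVELS = {v: k for k, v in _LEVEL_ORDERS.items()}


def _check_order(order) -> int:
    if isinstance(order, str):
        try:
            order = _LEVEL_ORDERS[order.lower()]
        except KeyError:
            raise ValueError(
                f"unknown level {order!r}; expected block, pac, or sac"
            ) from None
    order = int(order)
    if order not in (0, 1, 2):
        raise ValueError(
            f"order must be 0 (block), 1 (PAC), or 2 (SAC); got {order}"
        )
    return order


def community_window(graph: nx.Graph, focal: str, order: Union[int, str]) -> CommunityWindow:
    """The moving-window community of ``focal`` at the given order.

    Members are every block at graph distance <= order: order 1 is the PAC
    (the block and all adjacent blocks), order 2 the SAC (the PAC plus all
    blocks adjacent to the PAC).  Orders beyond 2 are rejected.
    """
    order = _check_order(order)
    if focal not in graph:
        raise KeyError(f"unknown focal block {focal!r}")
    members = frozenset(nx.single_source_shortest_path_length(graph, focal, cutoff=order))
    return CommunityWindow(focal=focal, order=order, members=members)


def all_windows(graph: nx.Graph, order: Union[int, str]) -> dict[str, CommunityWindow]:
    """One :class:`CommunityWindow` per block (windows overlap)."""
    order = _check_order(order)
    return {b: community_window(graph, b, order) for b in graph.nodes}


def assign_points_to_blocks(
    xs: Sequence[float],
    ys: Sequence[float],
    blocks: Mapping[str, BaseGeometry],
) -> list[Optional[str]]:
    """Point-in-polygon assignment of planar points to blocks.

    Points on a shared boundary go to the lexicographically smallest
    block_id (deterministic tie-break); points outside every block map to
    None.
    """
    validate_blocks(blocks)
    ids = list(blocks)
    tree = STRtree([blocks[b] for b in ids])
    points = shapely.points(np.column_stack([np.asarray(xs, float), np.asarray(ys, float)]))
    assigned: list[Optional[str]] = [None] * len(points)
    pt_idx, blk_idx = tree.query(points, predicate="intersects")
    for p, b in zip(pt_idx.tolist(), blk_idx.tolist()):
        bid = ids[b]
        if assigned[p] is None or bid < assigned[p]:
            assigned[p] = bid
    return assigned


def adjacency_to_frame(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (block_a, block_b), each pair once, sorted."""
    rows = sorted(tuple(sorted(e)) for e in graph.edges)
    return pd.DataFrame(rows, columns=["block_a", "block_b"])


def windows_to_frame(windows: Mapping[str, CommunityWindow]) -> pd.DataFrame:
    """Long-format membership table (focal, order, member)."""
    rows = [
        (w.focal, w.order, member)
        for w in windows.values()
        for member in sorted(w.members)
    ]
    return pd.DataFrame(rows, columns=["focal", "order", "member"])
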