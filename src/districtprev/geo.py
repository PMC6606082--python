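"""District geometries, contiguity graphs and displaced-cluster assignment.

Survey clusters carry deliberately displaced GPS coordinates (up to 2 km for
urban clusters, 5 km for rural ones), so a point-in-polygon lookup can place
a cluster in the wrong district.  The standard remedy implemented here is to
buffer each displaced location by the displacement cap and link the cluster
to the district with the greatest buffer overlap.

All coordinates are planar metres; callers must project before ingest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

ID_PROPERTY_CANDIDATES = ("district_id", "id", "DISTRICT_ID", "ID")


class SchemaError(ValueError):
    """Input file lacks a required field."""


class GeometryValidationError(ValueError):
    """One or more geometries are invalid; offending ids are listed."""


class UnassignedClusterError(ValueError):
    """A cluster's buffer overlaps no district polygon."""


@dataclass(frozen=True)
class District:
    district_id: str
    polygon: BaseGeometry
    name: str = ""


@dataclass
class DistrictMap:
    districts: list[District]

    def __post_init__(self) -> None:
        ids = [d.district_id for d in self.districts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GeometryValidationError(f"duplicate district ids: {dupes}")
        bad = [d.district_id for d in self.districts if not d.polygon.is_valid]
        if bad:
            raise GeometryValidationError(f"invalid geometries for ids: {bad}")
        self._check_overlap()

    def _check_overlap(self, rel_tol: float = 1e-9) -> None:
        total = sum(d.polygon.area for d in self.districts)
        if total <= 0:
            raise GeometryValidationError("district map has zero total area")
        tree = STRtree([d.polygon for d in self.districts])
        for i, d in enumerate(self.districts):
            for j in tree.query(d.polygon):
                if j <= i:
                    continue
                inter = d.polygon.intersection(self.districts[j].polygon)
                if inter.area > rel_tol * total:
                    raise GeometryValidationError(
                        "interior overlap between districts "
                        f"{d.district_id!r} and {self.districts[j].district_id!r}"
                    )

    @property
    def ids(self) -> list[str]:
        return [d.district_id for d in self.districts]

    def __len__(self) -> int:
        return len(self.districts)

    def __getitem__(self, district_id: str) -> District:
        for d in self.districts:
            if d.district_id == district_id:
                return d
        raise KeyError(district_id)

    def total_area(self) -> float:
        return sum(d.polygon.area for d in self.districts)

    def to_geojson(self, path: str | Path, extra_properties: Mapping[str, Mapping] | None = None) -> None:
        feats = []
        for d in self.districts:
            props = {"district_id": d.district_id, "name": d.name}
            if extra_properties and d.district_id in extra_properties:
                props.update(extra_properties[d.district_id])
            feats.append({"type": "Feature", "geometry": mapping(d.polygon), "properties": props})
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": feats}, sort_keys=True)
        )


@dataclass
class AdjacencyGraph:
    """Symmetric, loop-free district contiguity structure for the ICAR prior."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on district {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown district")
            norm.add((a, b) if a < b else (b, a))
        self.edges = norm

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def components(self) -> list[list[str]]:
        order = {n: i for i, n in enumerate(self.nodes)}
        comps = nx.connected_components(self.to_networkx())
        return sorted((sorted(c, key=order.get) for c in comps), key=lambda c: order[c[0]])

    def laplacian(self) -> np.ndarray:
        """ICAR structure matrix Q = D - W in the node order of ``nodes``."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        q = np.zeros((len(self.nodes), len(self.nodes)))
        for a, b in self.edges:
            i, j = idx[a], idx[b]
            q[i, j] -= 1.0
            q[j, i] -= 1.0
            q[i, i] += 1.0
            q[j, j] += 1.0
        return q

    def neighbours(self, node: str) -> list[str]:
        return sorted({b if a == node else a for a, b in self.edges if node in (a, b)})

    def to_edge_csv(self, path: str | Path) -> None:
        lines = ["district_a,district_b"]
        lines += [f"{a},{b}" for a, b in sorted(self.edges)]
        Path(path).write_text("\n".join(lines) + "\n")


def read_district_geometries(path: str | Path) -> DistrictMap:
    """Read a GeoJSON FeatureCollection of district polygons.

    Each feature must carry a district-id property (one of
    ``district_id``/``id``).  Coordinates are taken as planar metres.
    """
    path = Path(path)
    if path.suffix.lower() in {".shp", ".shx", ".dbf"}:
        raise SchemaError(
            "ESRI shapefiles are not supported; convert to GeoJSON "
            "(planar-projected) before ingest"
        )
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path} is not valid GeoJSON: {exc}") from exc
    feats = payload.get("features")
    if payload.get("type") != "FeatureCollection" or feats is None:
        raise SchemaError(f"{path} is not a GeoJSON FeatureCollection")
    districts = []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        did = None
        for cand in ID_PROPERTY_CANDIDATES:
            if cand in props:
                did = str(props[cand])
                break
        if did is None and "id" in feat:
            did = str(feat["id"])
        if did is None:
            raise SchemaError(
                f"feature {k} lacks a district-id property "
                f"(expected one of {ID_PROPERTY_CANDIDATES})"
            )
        districts.append(District(did, shape(feat["geometry"]), str(props.get("name", ""))))
    return DistrictMap(districts)


def build_adjacency(dmap: DistrictMap, rule: Literal["queen", "rook"] = "queen") -> AdjacencyGraph:
    """Polygon contiguity: queen = any shared boundary point, rook = shared
    boundary of positive length."""
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    geoms = [d.polygon for d in dmap.districts]
    ids = dmap.ids
    tree = STRtree(geoms)
    edges: set[tuple[str, str]] = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "rook" and inter.length <= 0:
                continue
            a, b = ids[i], ids[int(j)]
            edges.add((a, b) if a < b else (b, a))
    graph = AdjacencyGraph(nodes=list(ids), edges=edges)
    islands = [n for n in graph.nodes if not graph.neighbours(n)]
    if islands:
        log.warning("districts with no neighbours (unstructured effect only): %s", islands)
    return graph


def assign_clusters(
    clusters: Sequence,
    dmap: DistrictMap,
    urban_radius_m: float = 2000.0,
    rural_radius_m: float = 5000.0,
    buffer_resolution: int = 64,
) -> dict[str, str]:
    """Greatest-overlap assignment of displaced clusters to districts.

    Each cluster's displaced location is buffered by its displacement cap and
    the cluster is linked to the district whose polygon intersects the disc
    with the largest area.  Exact area ties break to the smallest district id.
    """
    if urban_radius_m <= 0 or rural_radius_m <= 0:
        raise ValueError("buffer radii must be positive")
    geoms = [d.polygon for d in dmap.districts]
    ids = dmap.ids
    tree = STRtree(geoms)
    out: dict[str, str] = {}
    orphans: list[str] = []
    for c in clusters:
        x, y = c.displaced_x_m, c.displaced_y_m
        radius = urban_radius_m if c.urban else rural_radius_m
        disc = Point(x, y).buffer(radius, quad_segs=buffer_resolution)
        best_id, best_area = None, 0.0
        for j in tree.query(disc):
            area = disc.intersection(geoms[int(j)]).area
            if area > best_area or (
                area == best_area and best_id is not None and ids[int(j)] < best_id and area > 0
            ):
                best_id, best_area = ids[int(j)], area
        if best_id is None or best_area <= 0:
            orphans.append(c.cluster_id)
        else:
            out[c.cluster_id] = best_id
    if orphans:
        raise UnassignedClusterError(f"clusters overlapping no district: {orphans}")
    return out


def disc_polygon_overlap_grid(
    cx: float, cy: float, radius: float, polygon: BaseGeometry, n: int = 400
) -> float:
    """Grid-sampling estimate of the disc/polygon intersection area.

    Independent oracle for the geometric overlap computation: lays an n x n
    lattice of points over the disc's bounding square and counts points that
    fall in both the disc and the polygon.
    """
    xs = np.linspace(cx - radius, cx + radius, n)
    ys = np.linspace(cy - radius, cy + radius, n)
    gx, gy = np.meshgrid(xs, ys)
    in_disc = (gx - cx) ** 2 + (gy - cy) ** 2 <= radius**2
    pts = np.column_stack([gx[in_disc], gy[in_disc]])
    from shapely import contains_xy

    inside = contains_xy(polygon, pts[:, 0], pts[:, 1])
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return float(inside.sum() * cell)
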