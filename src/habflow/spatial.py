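"""Habitat patch aggregation and per-period landscape metrics.

Given a schedule and a habitat-area flow, the habitat stands of a period are
those whose flow value under the assigned regime is positive. Habitat stands
are aggregated into patches — connected components of an adjacency graph —
under one of two movement modes:

* ``terrestrial``: two stands connect iff they share a boundary segment of
  positive length (corner contact does not count: a point is not
  traversable, and linework barriers such as roads split patches).
* ``avian``: two stands connect iff the minimum boundary-to-boundary
  distance between their polygons is at most ``dist`` meters (inclusive);
  a flying species can cross gaps up to its travel distance.

Patch areas are summed from the flow values (stand acreages), keeping patch
tables in the same units as the habitat flows; polygon geometry (meters) is
used for adjacency and for the geometric patch metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .core import FlowTable, Schedule, StandInfo

__all__ = [
    "StandGeometry",
    "SpatialParams",
    "PatchSet",
    "adjacency_graph",
    "patches_per_period",
    "patch_summary",
    "patch_metrics",
    "read_geojson",
    "write_geojson",
    "write_patches_geojson",
]

#: Minimum shared-boundary length (m) counted as terrestrial adjacency;
#: filters point contacts and floating-point slivers.
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class StandGeometry:
    """A stand's footprint: a planar (multi)polygon in meters."""

    stand_id: str
    polygon: Polygon | MultiPolygon

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError(f"stand {self.stand_id!r}: empty or zero-area geometry")
        if not self.polygon.is_valid:
            raise ValueError(f"stand {self.stand_id!r}: invalid geometry")


@dataclass(frozen=True)
class SpatialParams:
    """Patch aggregation settings.

    mode : "terrestrial" (shared-boundary adjacency) or "avian"
        (within-``dist`` connectivity).
    dist : travel distance in meters; required for (and only used by) the
        avian mode.
    level : reporting level for :func:`patch_metrics`.
    """

    mode: str = "terrestrial"
    dist: float | None = None
    level: str = "patch"

    def __post_init__(self) -> None:
        if self.mode not in ("terrestrial", "avian"):
            raise ValueError(f"mode must be 'terrestrial' or 'avian', got {self.mode!r}")
        if self.mode == "avian":
            if self.dist is None or self.dist < 0:
                raise ValueError("avian mode requires dist >= 0 (meters)")
        elif self.dist is not None:
            raise ValueError("dist is only meaningful in avian mode")
        if self.level not in ("patch", "class", "landscape"):
            raise ValueError(f"unknown level {self.level!r}")


@dataclass(frozen=True)
class PatchSet:
    """Habitat patches of one period."""

    period: int
    patches: tuple[tuple[int, frozenset[str], float], ...]  # (id, members, area)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def total_area(self) -> float:
        return float(sum(a for _, _, a in self.patches))

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for _, _, a in self.patches])

    def members(self) -> set[str]:
        out: set[str] = set()
        for _, m, _ in self.patches:
            out |= m
        return out


def adjacency_graph(
    geoms: Sequence[StandGeometry], params: SpatialParams
) -> nx.Graph:
    """Build the stand connectivity graph for a movement mode.

    Nodes are stand IDs; an edge joins two stands that can belong to the
    same patch. Symmetric, no self-edges. Candidate pairs are pruned with
    an STR tree before exact geometry tests.
    """
    g = nx.Graph()
    for sg in geoms:  # validation happens in StandGeometry.__post_init__
        g.add_node(sg.stand_id)
    polys = [sg.polygon for sg in geoms]
    tree = STRtree(polys)
    for i, sg in enumerate(geoms):
        if params.mode == "terrestrial":
            candidates = tree.query(sg.polygon, predicate="intersects")
        else:
            candidates = tree.query(sg.polygon, predicate="dwithin", distance=params.dist)
        for j in candidates:
            j = int(j)
            if j <= i:
                continue
            other = geoms[j]
            if params.mode == "terrestrial":
                inter = sg.polygon.intersection(other.polygon)
                if inter.length > _EDGE_TOL:
                    g.add_edge(sg.stand_id, other.stand_id)
            else:
                g.add_edge(sg.stand_id, other.stand_id)
    return g


def patches_per_period(
    schedule: Schedule,
    habitat_flow: FlowTable,
    geoms: Sequence[StandGeometry],
    params: SpatialParams,
    nperiods: int | None = None,
) -> list[PatchSet]:
    """Aggregate habitat stands into patches, one PatchSet per period.

    A stand is habitat in period t when its flow value under the assigned
    regime is positive (habitat flows carry 0 or the stand acreage). The
    patches are the connected components of the adjacency graph restricted
    to that period's habitat stands; patch area sums the member flow values.
    """
    geo_ids = {g.stand_id for g in geoms}
    flow_stands = habitat_flow.stand_ids()
    missing = flow_stands - geo_ids
    if missing:
        raise ValueError(f"stands in flow without geometry: {sorted(missing)[:5]}")
    if nperiods is None:
        nperiods = max(habitat_flow.periods(), default=0)
    graph = adjacency_graph(geoms, params)

    # habitat membership and acreage per period under the schedule
    by_period: dict[int, dict[str, float]] = {t: {} for t in range(1, nperiods + 1)}
    for (sid, rid, per), v in habitat_flow.values.items():
        if v > 0 and schedule.assignment.get(sid) == rid:
            by_period[per][sid] = v

    out: list[PatchSet] = []
    for t in range(1, nperiods + 1):
        habitat = by_period[t]
        sub = graph.subgraph(habitat)
        patches = []
        comps = sorted(nx.connected_components(sub), key=lambda c: sorted(c)[0])
        for pid, comp in enumerate(comps, start=1):
            # sum in sorted member order: reproducible across processes
            area = float(sum(habitat[s] for s in sorted(comp)))
            patches.append((pid, frozenset(comp), area))
        out.append(PatchSet(period=t, patches=tuple(patches)))
    return out


def patch_summary(patchsets: Sequence[PatchSet]) -> pd.DataFrame:
    """Per-period patch summary plus across-period aggregate rows.

    One row per period with ``n_patches``, ``min_area``, ``max_area``,
    ``mean_area`` and ``total_area`` (habitat-flow units, i.e. acres);
    empty periods report zero patches and NaN area statistics. Two trailing
    rows give the across-period mean and range (min-max) of each column.
    """
    rows = []
    for ps in patchsets:
        areas = ps.areas
        rows.append(
            {
                "period": ps.period,
                "n_patches": ps.n_patches,
                "min_area": float(areas.min()) if len(areas) else np.nan,
                "max_area": float(areas.max()) if len(areas) else np.nan,
                "mean_area": float(areas.mean()) if len(areas) else np.nan,
                "total_area": ps.total_area,
            }
        )
    df = pd.DataFrame(rows)
    stats = df.drop(columns="period")
    agg = pd.DataFrame(
        [
            {"period": "mean", **stats.mean().to_dict()},
            {
                "period": "range",
                **{
                    c: f"{stats[c].min():g}-{stats[c].max():g}" for c in stats.columns
                },
            },
        ]
    )
    return pd.concat([df, agg], ignore_index=True)


def _dissolved(patch_members: frozenset[str], geo_map: dict[str, Polygon]):
    return unary_union([geo_map[s] for s in sorted(patch_members)])


def patch_metrics(
    patchsets: Sequence[PatchSet],
    geoms: Sequence[StandGeometry],
    level: str = "patch",
) -> pd.DataFrame:
    """Geometric landscape metrics at patch, class or landscape level.

    All geometric quantities are in map units (meters / square meters),
    computed on the dissolved union of each patch's member polygons.

    * ``patch``: per patch — ``area`` (m2), ``perimeter`` (m), and
      ``para`` = perimeter / area (1/m).
    * ``class``: per period over all habitat patches — ``n_patches``,
      ``total_area`` (m2), ``mean_patch_area`` (m2), and ``lpi`` =
      largest patch area / total landscape area (0-1).
    * ``landscape``: identical to ``class`` here, since habitat forms a
      single class.
    """
    if level not in ("patch", "class", "landscape"):
        raise ValueError(f"unknown level {level!r}")
    geo_map = {g.stand_id: g.polygon for g in geoms}
    landscape_area = float(sum(p.area for p in geo_map.values()))
    rows = []
    for ps in patchsets:
        if level == "patch":
            for pid, members, _acres in ps.patches:
                geom = _dissolved(members, geo_map)
                rows.append(
                    {
                        "period": ps.period,
                        "patch_id": pid,
                        "area": geom.area,
                        "perimeter": geom.length,
                        "para": geom.length / geom.area,
                    }
                )
        else:
            areas = [
                _dissolved(members, geo_map).area for _, members, _ in ps.patches
            ]
            total = float(sum(areas))
            rows.append(
                {
                    "period": ps.period,
                    "n_patches": ps.n_patches,
                    "total_area": total,
                    "mean_patch_area": total / len(areas) if areas else np.nan,
                    "lpi": max(areas) / landscape_area if areas else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GeoJSON I/O


def read_geojson(path: str | Path) -> list[StandGeometry]:
    """Read stand polygons from a GeoJSON FeatureCollection.

    Each feature needs a ``stand_id`` property (or an ``id``) and a Polygon
    or MultiPolygon geometry in planar meter coordinates.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for k, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        sid = props.get("stand_id", feat.get("id"))
        if sid is None:
            raise ValueError(f"{path}: feature {k} lacks a stand_id")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"{path}: feature {k} has non-polygon geometry {geom.geom_type}"
            )
        out.append(StandGeometry(stand_id=str(sid), polygon=geom))
    return out


def write_geojson(
    geoms: Sequence[StandGeometry], path: str | Path, info: StandInfo | None = None
) -> None:
    features = []
    for sg in geoms:
        props: dict = {"stand_id": sg.stand_id}
        if info is not None:
            props["area_acres"] = info.areas.get(sg.stand_id)
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(sg.polygon),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_patches_geojson(
    patchsets: Sequence[PatchSet],
    geoms: Sequence[StandGeometry],
    path: str | Path,
) -> None:
    """Export dissolved patch polygons per period for mapping."""
    geo_map = {g.stand_id: g.polygon for g in geoms}
    features = []
    for ps in patchsets:
        for pid, members, acres in ps.patches:
            geom = _dissolved(members, geo_map)
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "period": ps.period,
                        "patch_id": pid,
                        "area_acres": acres,
                        "n_stands": len(members),
                    },
                    "geometry": mapping(geom),
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
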