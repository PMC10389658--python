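"""Constrained Voronoi sampling regions around language point locations.

Each language's environmental catchment is built in four steps:

1. a 100 km radius buffer around the language point, constructed in the
   world-sinusoidal equal-area projection so its area is latitude-
   independent, then transformed back to lon/lat;
2. the buffer is clipped to the coastline to exclude off-shore area;
3. a planar Voronoi diagram over all language points partitions a global
   rectangular bounding box in lon/lat degrees;
4. each Voronoi cell is intersected with the *combined* union of all
   clipped buffers.

Step 4 deliberately intersects with the union rather than the language's
own buffer: where a neighbour's buffer pokes across the shared Voronoi
boundary, a language's final region can exceed its own 100 km buffer.
This inflation artifact is retained for fidelity to the original workflow
and quantified by :func:`inflation_report`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, box, mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError
from .projection import area_km2, project_geometry, unproject_geometry

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_KM = 100.0
#: Quarter-circle segment count for buffer construction (128 per circle).
BUFFER_QUAD_SEGS = 32
WORLD_BOX = (-180.0, -90.0, 180.0, 90.0)

#: Ratios above 1 + this tolerance count as inflated in diagnostics.
INFLATION_TOL = 1e-3


@dataclass(frozen=True)
class GeoPoint:
    """A language point location in WGS84 degrees."""

    id: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise GeometryError(f"{self.id}: coordinates out of range")


@dataclass
class SamplingRegion:
    """A language's constrained Voronoi cell and its area diagnostics.

    Areas are in km², measured in the equal-area projection.
    ``inflation_ratio`` is region area over the language's own land-clipped
    buffer area; ratios above 1 mark the combined-buffer artifact.
    """

    language_id: str
    polygon: BaseGeometry  # lon/lat degrees
    base_buffer_area: float
    clipped_buffer_area: float
    region_area: float

    @property
    def inflation_ratio(self) -> float:
        if self.clipped_buffer_area == 0:
            return math.nan
        return self.region_area / self.clipped_buffer_area


def _check_points(points: Sequence[GeoPoint]) -> None:
    if not points:
        raise GeometryError("no points supplied")
    ids = [p.id for p in points]
    if len(set(ids)) != len(ids):
        raise GeometryError("duplicate point ids")
    for i, a in enumerate(points):
        for b in points[i + 1 :]:
            if abs(a.lon - b.lon) < 1e-6 and abs(a.lat - b.lat) < 1e-6:
                raise GeometryError(
                    f"coincident points {a.id} and {b.id}; resolve upstream"
                )


def build_buffers(
    points: Sequence[GeoPoint], radius_km: float = DEFAULT_RADIUS_KM
) -> dict[str, BaseGeometry]:
    """Equal-area circular buffers around each point, returned in lon/lat.

    Each buffer is a 128-gon of radius ``radius_km`` constructed in the
    sinusoidal plane, so its area is within a fraction of a percent of
    pi r^2 at any latitude.  Points so close to a pole that the buffer
    would cross it are rejected; points within 2 degrees of the
    antimeridian get a warning (no wraparound is performed).
    """
    if radius_km <= 0:
        raise GeometryError(f"radius must be positive, got {radius_km}")
    _check_points(points)
    radius_deg = math.degrees(radius_km / 6371.0)
    buffers: dict[str, BaseGeometry] = {}
    for p in points:
        if abs(p.lat) + radius_deg >= 90.0:
            raise GeometryError(f"{p.id}: buffer would cross a pole")
        if abs(abs(p.lon) - 180.0) < 2.0:
            warnings.warn(
                f"{p.id}: within 2 deg of the antimeridian; buffers do not wrap",
                stacklevel=2,
            )
        centre = project_geometry(Point(p.lon, p.lat))
        disc = centre.buffer(radius_km, quad_segs=BUFFER_QUAD_SEGS)
        geom = unproject_geometry(disc)
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
            logger.warning("%s: buffer required repair after unprojection", p.id)
        buffers[p.id] = geom
    return buffers


def clip_to_land(
    buffers: Mapping[str, BaseGeometry], coastline: BaseGeometry
) -> dict[str, BaseGeometry]:
    """Intersect each buffer with the land multipolygon.

    Buffers that end up empty (point off all land) are retained as empty
    geometries and flagged with a warning so downstream stages can carry
    the language with missing environmental data.
    """
    if coastline.is_empty:
        raise GeometryError("empty coastline geometry")
    if not coastline.is_valid:
        raise GeometryError("invalid coastline geometry")
    clipped = {}
    for lang_id, buf in buffers.items():
        geom = buf.intersection(coastline)
        if geom.is_empty:
            warnings.warn(f"{lang_id}: buffer has no on-land area", stacklevel=2)
        clipped[lang_id] = geom
    return clipped


def build_voronoi(
    points: Sequence[GeoPoint],
    bounding_box: tuple[float, float, float, float] = WORLD_BOX,
) -> dict[str, BaseGeometry]:
    """Planar Voronoi cells in lon/lat degrees, clipped to a box.

    Adjacency is computed on raw degree coordinates (not great-circle
    distance), mirroring the rectangular-box Voronoi of the original GIS
    workflow; the distortion this implies at high latitude is a documented
    fidelity choice.  Cell i contains point i.
    """
    _check_points(points)
    minx, miny, maxx, maxy = bounding_box
    bbox = box(minx, miny, maxx, maxy)
    for p in points:
        if not (minx <= p.lon <= maxx and miny <= p.lat <= maxy):
            raise GeometryError(f"{p.id}: outside the bounding box")

    if len(points) == 1:
        return {points[0].id: bbox}

    seeds = MultiPoint([(p.lon, p.lat) for p in points])
    raw = shapely.voronoi_polygons(seeds, extend_to=bbox)
    cells: dict[str, BaseGeometry] = {}
    pieces = list(raw.geoms)
    tree = shapely.STRtree(pieces)
    for p in points:
        pt = Point(p.lon, p.lat)
        for idx in tree.query(pt, predicate="intersects"):
            piece = pieces[idx]
            if piece.covers(pt):
                cells[p.id] = piece.intersection(bbox)
                break
        else:
            raise GeometryError(f"{p.id}: no Voronoi cell covers the seed")
    return cells


def constrain_cells(
    cells: Mapping[str, BaseGeometry],
    clipped_buffers: Mapping[str, BaseGeometry],
    radius_km: float = DEFAULT_RADIUS_KM,
) -> list[SamplingRegion]:
    """Intersect each Voronoi cell with the union of ALL clipped buffers.

    The union — not the language's own buffer — is the constraint layer,
    so neighbouring buffer lenses crossing a Voronoi boundary inflate the
    receiving cell's region beyond its own buffer.
    """
    union = shapely.union_all(list(clipped_buffers.values()))
    if union.is_empty:
        raise GeometryError("union of clipped buffers is empty")
    base_area = math.pi * radius_km**2
    regions = []
    for lang_id, cell in cells.items():
        clipped = clipped_buffers.get(lang_id)
        if clipped is None:
            raise GeometryError(f"{lang_id}: no clipped buffer supplied")
        poly = cell.intersection(union)
        regions.append(
            SamplingRegion(
                language_id=lang_id,
                polygon=poly,
                base_buffer_area=base_area,
                clipped_buffer_area=area_km2(clipped),
                region_area=area_km2(poly),
            )
        )
    return regions


def inflation_report(regions: Sequence[SamplingRegion]):
    """Diagnostics for the combined-buffer inflation artifact.

    Returns ``(table, n_inflated, fraction_inflated)`` where the table has
    one ``(language_id, inflation_ratio)`` row sorted by ratio descending.
    """
    import pandas as pd

    rows = sorted(
        ((r.language_id, r.inflation_ratio) for r in regions),
        key=lambda t: (-(t[1] if math.isfinite(t[1]) else -math.inf), t[0]),
    )
    table = pd.DataFrame(rows, columns=["language_id", "inflation_ratio"])
    flagged = int(
        sum(
            1
            for r in regions
            if math.isfinite(r.inflation_ratio)
            and r.inflation_ratio > 1 + INFLATION_TOL
        )
    )
    return table, flagged, flagged / len(regions)


# -- GeoJSON I/O ---------------------------------------------------------

def regions_to_geojson(regions: Sequence[SamplingRegion]) -> dict:
    features = []
    for r in regions:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.polygon),
                "properties": {
                    "language_id": r.language_id,
                    "base_buffer_area_km2": r.base_buffer_area,
                    "clipped_buffer_area_km2": r.clipped_buffer_area,
                    "region_area_km2": r.region_area,
                    "inflation_ratio": r.inflation_ratio,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def regions_from_geojson(obj: dict) -> list[SamplingRegion]:
    regions = []
    for feat in obj["features"]:
        props = feat["properties"]
        regions.append(
            SamplingRegion(
                language_id=props["language_id"],
                polygon=shape(feat["geometry"]),
                base_buffer_area=props["base_buffer_area_km2"],
                clipped_buffer_area=props["clipped_buffer_area_km2"],
                region_area=props["region_area_km2"],
            )
        )
    return regions


def build_regions(
    points: Sequence[GeoPoint],
    coastline: BaseGeometry,
    radius_km: float = DEFAULT_RADIUS_KM,
    bounding_box: tuple[float, float, float, float] = WORLD_BOX,
) -> list[SamplingRegion]:
    """Full pipeline: buffers -> coastline clip -> Voronoi -> constraint."""
    buffers = build_buffers(points, radius_km)
    clipped = clip_to_land(buffers, coastline)
    cells = build_voronoi(points, bounding_box)
    return constrain_cells(cells, clipped, radius_km)
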