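"""World-sinusoidal equal-area projection on the authalic sphere.

The sinusoidal projection ``x = R * lon * cos(lat), y = R * lat`` (angles
in radians, central meridian 0) is exactly equal-area on the sphere, at
the cost of severe shape and direction distortion away from the central
meridian.  Buffers are therefore constructed, and all areas measured, in
this projection, while Voronoi adjacency and all stored geometry remain in
unprojected WGS84 longitude/latitude degrees.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

#: Mean (authalic-scale) Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0088

#: Densification step (degrees) applied to lon/lat edges before projecting
#: for area measurement, so that long straight edges in degree space do not
#: bias planar areas at high latitude.
_DENSIFY_DEG = 0.05


def forward(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degrees lon/lat -> sinusoidal x/y in kilometres."""
    lat_r = np.radians(lat)
    x = EARTH_RADIUS_KM * np.radians(lon) * np.cos(lat_r)
    y = EARTH_RADIUS_KM * lat_r
    return x, y


def inverse(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoidal x/y in kilometres -> degrees lon/lat."""
    lat_r = np.asarray(y) / EARTH_RADIUS_KM
    with np.errstate(divide="ignore", invalid="ignore"):
        lon_r = np.asarray(x) / (EARTH_RADIUS_KM * np.cos(lat_r))
    return np.degrees(lon_r), np.degrees(lat_r)


def project_geometry(geom: BaseGeometry) -> BaseGeometry:
    """Project a lon/lat geometry into sinusoidal kilometres."""
    def _fwd(coords: np.ndarray) -> np.ndarray:
        x, y = forward(coords[:, 0], coords[:, 1])
        return np.column_stack([x, y])

    return shapely.transform(geom, _fwd)


def unproject_geometry(geom: BaseGeometry) -> BaseGeometry:
    """Inverse-project a sinusoidal-kilometre geometry back to lon/lat."""
    def _inv(coords: np.ndarray) -> np.ndarray:
        lon, lat = inverse(coords[:, 0], coords[:, 1])
        return np.column_stack([lon, lat])

    return shapely.transform(geom, _inv)


def area_km2(geom: BaseGeometry) -> float:
    """Area of a lon/lat polygon in km², measured in the equal-area plane.

    Edges are densified in degree space first so the polygon's planar image
    follows the curved image of its edges closely.
    """
    if geom.is_empty:
        return 0.0
    dense = shapely.segmentize(geom, _DENSIFY_DEG)
    return float(project_geometry(dense).area)
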