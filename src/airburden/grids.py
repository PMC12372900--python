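"""Regular latitude-longitude grids and spherical cell areas.

The analysis operates on a regular lat/lon grid like the one a nested
regional chemical-transport simulation produces (e.g. 0.25 deg x 0.3125 deg
over the continental US). Cells are the half-open boxes
``[lat_edge[i], lat_edge[i+1]) x [lon_edge[j], lon_edge[j+1])`` and their
areas come from the exact spherical-zone formula, so cells shrink toward
the poles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius in km (IUGG).
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridDefinition:
    """A regular lat/lon grid defined by its cell edges.

    Parameters
    ----------
    lat_edges, lon_edges
        Strictly increasing cell-edge coordinates in degrees. A grid with
        ``nlat x nlon`` cells has ``nlat + 1`` latitude edges and
        ``nlon + 1`` longitude edges.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat_edges", np.asarray(self.lat_edges, float))
        object.__setattr__(self, "lon_edges", np.asarray(self.lon_edges, float))
        for name, edges in (("lat_edges", self.lat_edges), ("lon_edges", self.lon_edges)):
            if edges.ndim != 1 or edges.size < 2:
                raise ValueError(f"{name} must be 1-D with at least two entries")
            if not np.all(np.diff(edges) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.lat_edges[0] < -90 or self.lat_edges[-1] > 90:
            raise ValueError("latitude edges must lie within [-90, 90]")

    @classmethod
    def regular(
        cls,
        nlat: int,
        nlon: int,
        origin: tuple[float, float],
        resolution: tuple[float, float],
    ) -> "GridDefinition":
        """Build a grid of ``nlat x nlon`` cells from a south-west origin.

        ``origin`` is the (lat, lon) of the south-west corner;
        ``resolution`` is the (dlat, dlon) cell size in degrees.
        """
        if nlat < 1 or nlon < 1:
            raise ValueError("grid dimensions must be at least 1x1")
        dlat, dlon = resolution
        if dlat <= 0 or dlon <= 0:
            raise ValueError("grid resolution must be positive")
        lat0, lon0 = origin
        return cls(
            lat_edges=lat0 + dlat * np.arange(nlat + 1),
            lon_edges=lon0 + dlon * np.arange(nlon + 1),
        )

    @property
    def nlat(self) -> int:
        return self.lat_edges.size - 1

    @property
    def nlon(self) -> int:
        return self.lon_edges.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def cell_areas_km2(self) -> np.ndarray:
        """Cell areas in km^2 from the spherical-zone formula.

        The area of the cell between latitudes phi1 < phi2 and spanning a
        longitude width dlam (radians) is R^2 * dlam * (sin phi2 - sin phi1).
        """
        phi = np.deg2rad(self.lat_edges)
        band = np.sin(phi[1:]) - np.sin(phi[:-1])  # (nlat,)
        dlam = np.deg2rad(np.diff(self.lon_edges))  # (nlon,)
        areas = EARTH_RADIUS_KM**2 * band[:, None] * dlam[None, :]
        return areas

    def total_area_km2(self) -> float:
        return float(self.cell_areas_km2().sum())

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Index of the cell containing a point (half-open edge convention)."""
        i = int(np.searchsorted(self.lat_edges, lat, side="right")) - 1
        j = int(np.searchsorted(self.lon_edges, lon, side="right")) - 1
        if not (0 <= i < self.nlat and 0 <= j < self.nlon):
            raise ValueError(f"point ({lat}, {lon}) lies outside the grid")
        return i, j

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridDefinition):
            return NotImplemented
        return np.array_equal(self.lat_edges, other.lat_edges) and np.array_equal(
            self.lon_edges, other.lon_edges
        )
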