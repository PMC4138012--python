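"""North-up geographic rasters: the precipitation isoscape and probability maps.

Grids are plain geographic (WGS84 lat/lon) with square cells given in
arc-minutes, row 0 at the northern edge.  No-data cells are NaN in memory and
are round-tripped through the ESRI ASCII grid format, which any GIS reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0

__all__ = ["Raster", "Isoscape", "ProbabilityMap", "minmax_standardize", "NODATA"]


@dataclass
class Raster:
    """A north-up geographic grid of float values with NaN as no-data.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.
    lat_max, lon_min
        North and west *edges* of the grid, decimal degrees.
    cell_arcmin
        Square cell size in arc-minutes (> 0).
    """

    values: np.ndarray
    lat_max: float
    lon_min: float
    cell_arcmin: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.cell_arcmin <= 0:
            raise ValueError("cell size must be positive")

    # -- georeferencing ----------------------------------------------------
    @property
    def cell_deg(self) -> float:
        return self.cell_arcmin / 60.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.shape[0] * self.cell_deg

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.shape[1] * self.cell_deg

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, northernmost first (matching row order)."""
        n = self.shape[0]
        return self.lat_max - self.cell_deg * (np.arange(n) + 0.5)

    def lon_centers(self) -> np.ndarray:
        n = self.shape[1]
        return self.lon_min + self.cell_deg * (np.arange(n) + 0.5)

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) 2-D center-coordinate grids aligned with ``values``."""
        lat = self.lat_centers()[:, None] * np.ones((1, self.shape[1]))
        lon = np.ones((self.shape[0], 1)) * self.lon_centers()[None, :]
        return lat, lon

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is no-data."""
        return ~np.isfinite(self.values)

    def contains(self, lat: float, lon: float) -> bool:
        return (self.lat_min <= lat <= self.lat_max) and (
            self.lon_min <= lon <= self.lon_max
        )

    def index_of(self, lat: float, lon: float) -> tuple[int, int]:
        if not self.contains(lat, lon):
            raise ValueError(f"point ({lat}, {lon}) outside raster extent")
        i = int(np.clip((self.lat_max - lat) / self.cell_deg, 0, self.shape[0] - 1))
        j = int(np.clip((lon - self.lon_min) / self.cell_deg, 0, self.shape[1] - 1))
        return i, j

    def value_at(self, lat: float, lon: float) -> float:
        i, j = self.index_of(lat, lon)
        return float(self.values[i, j])

    # -- I/O (ESRI ASCII grid, a plain-text GIS interchange format) --------
    def to_ascii(self, path) -> None:
        vals = np.where(self.mask, NODATA, self.values)
        header = (
            f"ncols {self.shape[1]}\n"
            f"nrows {self.shape[0]}\n"
            f"xllcorner {self.lon_min:.10g}\n"
            f"yllcorner {self.lat_min:.10g}\n"
            f"cellsize {self.cell_deg:.10g}\n"
            f"NODATA_value {NODATA:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6f")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = header.get("nodata_value", NODATA)
        vals[vals == nodata] = np.nan
        cell_deg = header["cellsize"]
        return cls(
            values=vals,
            lat_max=header["yllcorner"] + header["nrows"] * cell_deg,
            lon_min=header["xllcorner"],
            cell_arcmin=cell_deg * 60.0,
        )

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.lat_max, other.lat_max)
            and np.isclose(self.lon_min, other.lon_min)
            and np.isclose(self.cell_arcmin, other.cell_arcmin)
        )


class Isoscape(Raster):
    """Georeferenced raster of mean-annual precipitation delta2H_p (permil)."""


@dataclass
class ProbabilityMap(Raster):
    """An origin-probability raster aligned with an isoscape.

    ``role`` distinguishes the isotope-based map (``PM_Iso``), the
    bearing-based map (``PM_Ang``) and their combination, the refined
    breeding-origin map (``PM_Breed``).  ``provenance`` records the
    contributing site IDs and their normalized merge weights.
    """

    role: str = "PM_Iso"
    stratum: str = "all"
    provenance: dict = field(default_factory=dict)

    def with_values(self, values: np.ndarray, **changes) -> "ProbabilityMap":
        return dataclasses.replace(self, values=values, **changes)

    @classmethod
    def like(cls, template: Raster, values: np.ndarray, role: str = "PM_Iso",
             stratum: str = "all", provenance: dict | None = None) -> "ProbabilityMap":
        return cls(
            values=values,
            lat_max=template.lat_max,
            lon_min=template.lon_min,
            cell_arcmin=template.cell_arcmin,
            role=role,
            stratum=stratum,
            provenance=provenance or {},
        )


def minmax_standardize(pmap: ProbabilityMap) -> ProbabilityMap:
    """Rescale unmasked cells linearly so they span exactly [0, 1].

    A constant map (max == min) maps to all ones; no-data cells stay NaN.
    """
    vals = pmap.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("cannot standardize an all-masked map")
    lo = np.nanmin(vals)
    hi = np.nanmax(vals)
    if hi == lo:
        out = np.where(finite, 1.0, np.nan)
    else:
        out = (vals - lo) / (hi - lo)
    return pmap.with_values(out)
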