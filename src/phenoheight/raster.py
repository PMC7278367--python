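"""Single-band georeferenced elevation rasters (crop surface models).

A :class:`SurfaceRaster` is a north-up float32 grid with an affine
georeference given by the world coordinate of the top-left corner and a
square pixel size; no-data is IEEE NaN.  GeoTIFF round-tripping is built on
``tifffile``, writing the ModelPixelScale / ModelTiepoint / GeoKeyDirectory
tags plus GDAL's nodata tag, which is sufficient for planar projected
rasters without rotation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import ConfigurationError

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass
class SurfaceRaster:
    """Elevation grid (m) with top-left anchored north-up georeference."""

    data: np.ndarray  # 2D float32, NaN where nodata
    x_origin: float  # world x of the top-left raster corner
    y_origin: float  # world y of the top-left raster corner (max y)
    pixel_size: float
    date: _dt.date | None = None
    crs_epsg: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ConfigurationError("raster grid must be a non-empty 2D array")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel carries a valid elevation."""
        return np.isfinite(self.data)

    def x_centers(self, cols: np.ndarray | slice | None = None) -> np.ndarray:
        cols = np.arange(self.data.shape[1])[cols] if cols is not None else np.arange(self.data.shape[1])
        return self.x_origin + (np.asarray(cols) + 0.5) * self.pixel_size

    def y_centers(self, rows: np.ndarray | slice | None = None) -> np.ndarray:
        rows = np.arange(self.data.shape[0])[rows] if rows is not None else np.arange(self.data.shape[0])
        return self.y_origin - (np.asarray(rows) + 0.5) * self.pixel_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the raster footprint."""
        nrow, ncol = self.data.shape
        return (
            self.x_origin,
            self.y_origin - nrow * self.pixel_size,
            self.x_origin + ncol * self.pixel_size,
            self.y_origin,
        )

    # -- GeoTIFF ----------------------------------------------------------
    def write_geotiff(self, path) -> None:
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (self.pixel_size, self.pixel_size, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.x_origin, self.y_origin, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, "nan"),
        ]
        if self.crs_epsg is not None:
            geokeys = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, self.crs_epsg)
            extratags.append((_TAG_GEO_KEYS, "H", len(geokeys), geokeys))
        dt = None
        if self.date is not None:
            dt = _dt.datetime(self.date.year, self.date.month, self.date.day)
        tifffile.imwrite(path, self.data, extratags=extratags, datetime=dt)

    @classmethod
    def read_geotiff(cls, path) -> "SurfaceRaster":
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray().astype(np.float32)
            tags = page.tags
            try:
                sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value[:3]
                tie = tags[_TAG_MODEL_TIEPOINT].value
            except KeyError as exc:
                raise ConfigurationError(f"{path}: missing georeference tags") from exc
            x0, y0 = float(tie[3]), float(tie[4])
            epsg = None
            if _TAG_GEO_KEYS in tags:
                keys = tags[_TAG_GEO_KEYS].value
                for i in range(4, len(keys), 4):
                    if keys[i] == 3072:
                        epsg = int(keys[i + 3])
            date = None
            if 306 in tags:  # DateTime "YYYY:MM:DD HH:MM:SS"
                s = tags[306].value
                date = _dt.date(int(s[0:4]), int(s[5:7]), int(s[8:10]))
        if abs(float(sx) - float(sy)) > 1e-12:
            raise ConfigurationError(f"{path}: non-square pixels unsupported")
        return cls(data=data, x_origin=x0, y_origin=y0, pixel_size=float(sx), date=date, crs_epsg=epsg)
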