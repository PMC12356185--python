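"""Raster grid geometry and GeoTIFF input/output.

A :class:`GridSpec` is a north-up affine grid (no rotation): pixel (row, col)
has its upper-left corner at ``(x0 + col*dx, y0 - row*dy)``. All rasters in a
scene share one projected CRS; reprojection is deliberately out of scope.

GeoTIFFs are written with :mod:`tifffile`, carrying the standard GeoTIFF
georeferencing tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the
GDAL sidecar tags used by the wider geospatial toolchain: GDAL_NODATA for the
nodata sentinel and GDAL_METADATA for ``scale_factor`` / ``units`` items, so
files open correctly in GDAL, QGIS and rasterio.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import tifffile

# TIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_METADATA = 42112
_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """North-up raster grid in a single projected CRS.

    Parameters
    ----------
    x0, y0
        Coordinates of the upper-left corner of the upper-left pixel.
    dx, dy
        Pixel size in CRS units; both positive (dy is the southward step).
    width, height
        Pixel counts.
    crs
        CRS label, e.g. ``"EPSG:32632"``. Informational; no reprojection.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    width: int
    height: int
    crs: str = "EPSG:32632"

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.width) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.y0 - (np.arange(self.height) + 0.5) * self.dy

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of all pixel centers, shape (height, width)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        return (
            self.x0,
            self.y0 - self.height * self.dy,
            self.x0 + self.width * self.dx,
            self.y0,
        )

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid covering the same origin with ``factor``-times larger pixels."""
        if factor < 1:
            raise ValueError("coarse_factor must be >= 1")
        return replace(
            self,
            dx=self.dx * factor,
            dy=self.dy * factor,
            width=-(-self.width // factor),
            height=-(-self.height // factor),
        )

    def window(self, row0: int, col0: int, height: int, width: int) -> "GridSpec":
        """Subgrid starting at pixel (row0, col0)."""
        return replace(
            self,
            x0=self.x0 + col0 * self.dx,
            y0=self.y0 - row0 * self.dy,
            width=width,
            height=height,
        )


def _epsg_code(crs: str) -> int:
    m = re.fullmatch(r"(?i)epsg:(\d+)", crs.strip())
    return int(m.group(1)) if m else 32767  # 32767 = user-defined


def _gdal_metadata_xml(meta: dict[str, object]) -> str:
    items = "".join(
        f'<Item name="{k}" sample="0">{v}</Item>' for k, v in meta.items()
    )
    return f"<GDALMetadata>{items}</GDALMetadata>"


def write_geotiff(
    path,
    data: np.ndarray,
    grid: GridSpec,
    *,
    nodata: float | int | None = None,
    scale_factor: float | None = None,
    units: str | None = None,
    extra_metadata: dict[str, object] | None = None,
) -> None:
    """Write a single-band GeoTIFF with georeferencing and GDAL metadata tags."""
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    meta: dict[str, object] = dict(extra_metadata or {})
    if scale_factor is not None:
        meta["scale_factor"] = repr(float(scale_factor))
    if units is not None:
        meta["units"] = units

    geokeys = (
        1, 1, 0, 3,                    # version, rev, minor, number of keys
        1024, 0, 1, 1,                 # GTModelType = projected
        1025, 0, 1, 1,                 # GTRasterType = PixelIsArea
        3072, 0, 1, _epsg_code(grid.crs),
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.dx, grid.dy, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
    ]
    if meta:
        extratags.append((_GDAL_METADATA, "s", 0, _gdal_metadata_xml(meta)))
    if nodata is not None:
        extratags.append((_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, np.ascontiguousarray(data), extratags=extratags)


def read_geotiff(path, crs: str = "EPSG:32632"):
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or GDAL).

    Returns
    -------
    (data, grid, meta)
        ``meta`` holds ``nodata`` (float or None) and any GDAL metadata items
        (``scale_factor`` parsed to float when present).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value if _MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_MODEL_TIEPOINT].value if _MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0)
        meta: dict[str, object] = {"nodata": None}
        if _GDAL_NODATA in tags:
            meta["nodata"] = float(tags[_GDAL_NODATA].value)
        if _GDAL_METADATA in tags:
            xml = tags[_GDAL_METADATA].value
            for name, val in re.findall(r'<Item name="([^"]+)"[^>]*>([^<]*)</Item>', xml):
                meta[name] = val
            if "scale_factor" in meta:
                meta["scale_factor"] = float(meta["scale_factor"])  # type: ignore[arg-type]
    grid = GridSpec(
        x0=float(tie[3]),
        y0=float(tie[4]),
        dx=float(scale[0]),
        dy=float(scale[1]),
        width=data.shape[1],
        height=data.shape[0],
        crs=crs,
    )
    return data, grid, meta
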