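"""ESRI ASCII grid reader/writer.

The plain-text grid format carries a 6-line header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by row-major values,
top row first. NODATA cells map to the inactive mask. GeoTIFF input is
rejected with a pointer to the supported format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridData", "read_raster", "write_raster"]

DEFAULT_NODATA = -9999.0


@dataclass
class GridData:
    values: np.ndarray  # float array; NODATA cells hold the nodata value
    nodata: float
    cellsize: float = 100.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    @property
    def mask(self) -> np.ndarray:
        """True where data is valid."""
        return ~np.isclose(self.values, self.nodata)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        return np.where(self.mask, self.values, fill)


def read_raster(path) -> GridData:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raise NotImplementedError(
            "GeoTIFF input is not supported in this build; convert to an "
            "ESRI ASCII grid (.asc)"
        )
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} is missing header field {key}")
    values = np.array([v for r in rows for v in r], dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.size != ncols * nrows:
        raise ValueError(
            f"ASCII grid {path}: expected {ncols * nrows} values, got {values.size}"
        )
    return GridData(
        values.reshape(nrows, ncols),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        cellsize=header.get("cellsize", 100.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
    )


def write_raster(grid: GridData | np.ndarray, path, nodata: float | None = None, cellsize: float | None = None) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raise NotImplementedError(
            "GeoTIFF output is not supported in this build; use .asc"
        )
    if isinstance(grid, np.ndarray):
        grid = GridData(grid.astype(float), nodata=nodata if nodata is not None else DEFAULT_NODATA)
    if nodata is not None and nodata != grid.nodata:
        grid = GridData(
            np.where(grid.mask, grid.values, nodata), nodata,
            grid.cellsize, grid.xllcorner, grid.yllcorner,
        )
    if cellsize is not None:
        grid.cellsize = cellsize
    nrows, ncols = grid.values.shape
    integral = np.all(np.mod(grid.values, 1.0) == 0)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:g}\n")
        fh.write(f"yllcorner {grid.yllcorner:g}\n")
        fh.write(f"cellsize {grid.cellsize:g}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        fmt = "%d" if integral else "%.8g"
        for row in grid.values:
            fh.write(" ".join(fmt % v for v in row) + "\n")
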