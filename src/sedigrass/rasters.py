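"""Plain-text raster I/O (ESRI ASCII grid).

A deliberately minimal reader/writer for single-band planar grids: six header
lines (ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows of whitespace-separated values, north row first.  NaN cells are written
as the NODATA value.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

NODATA = -9999.0


def write_ascii_grid(path: str | Path, data: np.ndarray, cell_size: float = 100.0) -> None:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("raster must be 2-D")
    out = np.where(np.isfinite(data), data, NODATA)
    header = (
        f"ncols {data.shape[1]}\n"
        f"nrows {data.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Return (array with NaN at NODATA, cell_size)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != expected:
        raise ValueError(f"raster body {data.shape} does not match header {expected}")
    nodata = header.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return data, header["cellsize"]
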