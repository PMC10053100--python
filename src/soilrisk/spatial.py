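"""Inverse distance weighted interpolation onto a regular grid.

Cell values are weighted means of site values with weights d^(-power);
a cell sitting on a site (d < 1e-9) takes the site's value exactly. The
surface is written as an ESRI-style ASCII grid, so no GIS stack is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .io_model import SampleTable, ValidationError

__all__ = ["GridSpec", "GridSurface", "grid_from_bounds", "idw_interpolate",
           "write_ascii_grid", "read_ascii_grid"]

_COINCIDENT = 1e-9
NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: lower-left corner, square cell size, row/column counts."""

    x0: float
    y0: float
    cell: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.cell <= 0:
            raise ValidationError("grid must have positive cell size and dimensions")

    def centers(self) -> np.ndarray:
        """Cell-center coordinates, row-major from the top-left cell."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class GridSurface:
    """Interpolated values on a :class:`GridSpec` (row 0 = northernmost)."""

    spec: GridSpec
    values: np.ndarray
    metal: str = ""
    nodata: float = NODATA


def grid_from_bounds(samples: SampleTable, cell: float, padding: float = 0.0) -> GridSpec:
    """Smallest grid of square cells covering the sample bounding box."""
    x0, x1 = samples.x.min() - padding, samples.x.max() + padding
    y0, y1 = samples.y.min() - padding, samples.y.max() + padding
    n_cols = max(int(np.ceil((x1 - x0) / cell)), 1)
    n_rows = max(int(np.ceil((y1 - y0) / cell)), 1)
    return GridSpec(x0=float(x0), y0=float(y0), cell=float(cell),
                    n_rows=n_rows, n_cols=n_cols)


def idw_interpolate(
    samples: SampleTable,
    metal: str,
    grid: GridSpec,
    power: float = 2.0,
    max_neighbors: Optional[int] = None,
) -> GridSurface:
    """Interpolate one metal's concentrations onto a grid.

    Weights are d^(-power) over the ``max_neighbors`` nearest sites
    (default: all sites). IDW is a convex combination, so every cell lies
    within the range of the input values and sample locations are honoured
    exactly.
    """
    if samples.n_sites < 1:
        raise ValidationError("need at least one sample")
    if not (power > 0):
        raise ValidationError("power must be > 0")
    z = samples.conc[metal].to_numpy(float)
    pts = np.column_stack([samples.x, samples.y])
    cells = grid.centers()
    d = cdist(cells, pts)

    if max_neighbors is not None and max_neighbors < len(z):
        # keep only the nearest max_neighbors sites per cell
        cut = np.partition(d, max_neighbors - 1, axis=1)[:, max_neighbors - 1]
        mask = d > cut[:, None]
    else:
        mask = np.zeros_like(d, dtype=bool)

    out = np.empty(len(cells))
    coincident = d < _COINCIDENT
    hit = coincident.any(axis=1)
    if hit.any():
        out[hit] = z[np.argmax(coincident[hit], axis=1)]
    rest = ~hit
    if rest.any():
        with np.errstate(divide="ignore"):
            w = d[rest] ** (-power)
        w[mask[rest]] = 0.0
        out[rest] = (w @ z) / w.sum(axis=1)
    return GridSurface(spec=grid, metal=metal,
                       values=out.reshape(grid.n_rows, grid.n_cols))


def write_ascii_grid(surface: GridSurface, path) -> None:
    s = surface.spec
    vals = np.where(np.isfinite(surface.values), surface.values, surface.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {s.x0!r}\n")
        fh.write(f"yllcorner {s.y0!r}\n")
        fh.write(f"cellsize {s.cell!r}\n")
        fh.write(f"NODATA_value {surface.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> GridSurface:
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(header) < 6 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    spec = GridSpec(
        x0=header["xllcorner"], y0=header["yllcorner"], cell=header["cellsize"],
        n_rows=int(header["nrows"]), n_cols=int(header["ncols"]),
    )
    values = np.array(rows)
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    return GridSurface(spec=spec, values=values, nodata=nodata)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
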