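"""Regular lat-lon grids and plain-text raster I/O.

All spatial layers in the pipeline live on a single regular geographic
grid described by :class:`GridGeometry`: cell identity is ``(row, col)``
with the origin at the north-west corner and half-open cell intervals.
Rasters are serialized as ESRI ASCII grids (``.asc``), a plain-text
format readable by standard GIS tooling.

Cell area is carried explicitly (m² per cell) rather than derived from
latitude; the toy worlds use a constant-area grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StructuralError

NODATA = -9999


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular geographic grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost band.
    resolution_arcmin
        Cell edge length in arc minutes (5 arcmin by default elsewhere).
    x_origin, y_origin
        Longitude/latitude of the north-west corner, in degrees.
    cell_area_m2
        Area of one cell in m².  Kept constant across the grid.
    """

    n_rows: int
    n_cols: int
    resolution_arcmin: float = 5.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_area_m2: float = 8.6e7

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def same_grid(self, other: "GridGeometry") -> bool:
        """True when two geometries describe the identical grid."""
        return (
            self.shape == other.shape
            and np.isclose(self.resolution_arcmin, other.resolution_arcmin)
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
        )

    def require_same_grid(self, other: "GridGeometry", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise StructuralError(f"{what} does not share the grid geometry")


def write_ascii_grid(path, data: np.ndarray, geometry: GridGeometry) -> None:
    """Write a 2-D array as an ESRI ASCII grid.

    Boolean arrays are written as 0/1 integers; float arrays with full
    ``repr`` precision so that a read-back round-trips exactly.
    """
    data = np.asarray(data)
    if data.shape != geometry.shape:
        raise StructuralError(
            f"array shape {data.shape} does not match geometry {geometry.shape}"
        )
    cellsize = geometry.resolution_arcmin / 60.0
    yll = geometry.y_origin - geometry.n_rows * cellsize
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {cellsize!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    if data.dtype == bool or np.issubdtype(data.dtype, np.integer):
        body = "\n".join(
            " ".join(str(int(v)) for v in row) for row in data.astype(np.int64)
        )
    else:
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in data)
    with open(path, "w") as fh:
        fh.write(header + body + "\n")


def read_ascii_grid(path, cell_area_m2: float = 8.6e7):
    """Read an ESRI ASCII grid; returns ``(array, GridGeometry)``.

    The ASCII-grid header does not carry cell area, so it is supplied by
    the caller (the world manifest records it).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, value = line.split()
        header[key.lower()] = float(value)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cellsize = header["cellsize"]
    data = np.array(
        [[float(v) for v in line.split()] for line in lines[6:] if line.strip()]
    )
    if data.shape != (n_rows, n_cols):
        raise StructuralError(f"ASCII grid body of {path} does not match its header")
    geometry = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        resolution_arcmin=cellsize * 60.0,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cellsize,
        cell_area_m2=cell_area_m2,
    )
    return data, geometry
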