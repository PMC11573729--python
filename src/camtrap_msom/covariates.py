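"""Site covariates: terrain ruggedness, buffered raster means, disturbance
counts, and the standardized design matrix.

Covariates enter the occupancy model on the logit scale after
standardization, so slopes are comparable across covariates.  The design
matrix carries a quadratic elevation term (the square of *standardized*
elevation) to allow a mid-elevation richness peak.

Rasters are plain in-memory grids in a planar, metre-unit CRS with an
ESRI ASCII grid (.asc) text serialization; geographic rasters must be
projected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "read_ascii_grid",
    "DesignMatrix",
    "terrain_ruggedness_index",
    "buffer_mean",
    "disturbance_count",
    "standardize",
    "unstandardize",
    "build_design_matrix",
]

BASE_COLUMNS = ("elevation", "tri", "canopy", "disturbance")
DESIGN_COLUMNS = ("elevation", "elevation_sq", "tri", "canopy", "disturbance")


@dataclass
class RasterGrid:
    """A single-band raster: 2-D values (NaN = missing) plus georeferencing.

    ``xll, yll`` are the coordinates of the lower-left corner of the
    lower-left cell; ``cell_size`` is the square cell edge in CRS units
    (metres).  Row 0 of ``values`` is the *top* row, as in the .asc format.
    """

    values: np.ndarray
    xll: float
    yll: float
    cell_size: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self):
        return self.values.shape

    def cell_centers(self):
        """(X, Y) arrays of cell-center coordinates, same shape as values."""
        nrow, ncol = self.values.shape
        x = self.xll + (np.arange(ncol) + 0.5) * self.cell_size
        y = self.yll + (nrow - np.arange(nrow) - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def contains(self, x: float, y: float) -> bool:
        nrow, ncol = self.values.shape
        return (self.xll <= x <= self.xll + ncol * self.cell_size
                and self.yll <= y <= self.yll + nrow * self.cell_size)

    def to_ascii(self, path, nodata: float = -9999.0) -> None:
        nrow, ncol = self.values.shape
        vals = np.where(np.isnan(self.values), nodata, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {ncol}\nnrows {nrow}\n"
                     f"xllcorner {self.xll}\nyllcorner {self.yll}\n"
                     f"cellsize {self.cell_size}\nNODATA_value {nodata}\n")
            for row in vals:
                fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc); NODATA cells become NaN."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing .asc header field {key}")
    values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return RasterGrid(values=values, xll=header["xllcorner"],
                      yll=header["yllcorner"], cell_size=header["cellsize"])


def terrain_ruggedness_index(elev: RasterGrid) -> RasterGrid:
    """Riley et al. terrain ruggedness index.

    TRI(cell) = sqrt( sum over the 8 neighbours (e_nbr - e_center)^2 ).
    Border cells use the neighbours that exist; missing (NaN) neighbours
    are excluded from the sum.  A NaN centre stays NaN.
    """
    v = elev.values
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValueError("TRI needs a grid of at least 3x3 cells")
    acc = np.zeros_like(v)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nbr = np.full_like(v, np.nan)
            src_r = slice(max(di, 0), v.shape[0] + min(di, 0))
            dst_r = slice(max(-di, 0), v.shape[0] + min(-di, 0))
            src_c = slice(max(dj, 0), v.shape[1] + min(dj, 0))
            dst_c = slice(max(-dj, 0), v.shape[1] + min(-dj, 0))
            nbr[dst_r, dst_c] = v[src_r, src_c]
            sq = (nbr - v) ** 2
            acc += np.where(np.isnan(sq), 0.0, sq)
    tri = np.sqrt(acc)
    tri[np.isnan(v)] = np.nan
    return RasterGrid(values=tri, xll=elev.xll, yll=elev.yll,
                      cell_size=elev.cell_size)


def buffer_mean(raster: RasterGrid, x: float, y: float,
                radius: float = 100.0) -> float:
    """Mean of non-missing cells whose *center* lies within ``radius``
    metres of (x, y); NaN when no cell qualifies."""
    if not raster.contains(x, y):
        raise ValueError(f"point ({x}, {y}) is outside the raster extent")
    cx, cy = raster.cell_centers()
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius ** 2
    vals = raster.values[inside]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def disturbance_count(independent_records: pd.DataFrame,
                      sites=None) -> pd.Series:
    """Independent human + livestock records per site (sites with none
    get 0).  Input must already be independence-filtered."""
    mask = independent_records["kind"].isin(("human", "livestock"))
    counts = independent_records.loc[mask].groupby("site").size()
    if sites is None:
        sites = sorted(set(independent_records["site"]))
    out = counts.reindex(list(sites), fill_value=0).astype(int)
    out.name = "disturbance"
    return out


def standardize(columns, ddof: int = 1):
    """Center and scale each column to mean 0, sample sd 1.

    Returns ``(standardized, means, sds)``; the constants allow applying
    the same transform to new sites.  Raises on a zero-variance column.
    """
    df = pd.DataFrame(columns).astype(float)
    means = df.mean()
    sds = df.std(ddof=ddof)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    out = (df - means) / sds
    if isinstance(columns, np.ndarray):
        return out.to_numpy(), means.to_numpy(), sds.to_numpy()
    return out, means, sds


def unstandardize(standardized, means, sds):
    """Inverse of :func:`standardize`."""
    return pd.DataFrame(standardized).astype(float) * sds + means


@dataclass
class DesignMatrix:
    """Standardized covariate matrix for the occupancy model.

    Column order is fixed: elevation, elevation_sq, tri, canopy,
    disturbance.  ``elevation_sq`` is the square of the *standardized*
    elevation and is not itself re-standardized.
    """

    X: np.ndarray
    column_names: list
    site_ids: list
    means: pd.Series
    sds: pd.Series

    def select(self, columns) -> "DesignMatrix":
        """Restrict to a subset of columns (order preserved as given)."""
        unknown = [c for c in columns if c not in self.column_names]
        if unknown:
            raise ValueError(f"unknown design column(s): {unknown}")
        idx = [self.column_names.index(c) for c in columns]
        return DesignMatrix(X=self.X[:, idx], column_names=list(columns),
                            site_ids=self.site_ids, means=self.means,
                            sds=self.sds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.column_names,
                            index=pd.Index(self.site_ids, name="site"))


def build_design_matrix(cov: pd.DataFrame) -> DesignMatrix:
    """Standardize the four base covariates and append squared elevation.

    ``cov`` needs columns site, elevation, tri, canopy, disturbance.
    """
    missing = [c for c in ("site", *BASE_COLUMNS) if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate table is missing column(s): {missing}")
    if len(cov) < 2:
        raise ValueError("need at least 2 sites to standardize")
    base, means, sds = standardize(cov[list(BASE_COLUMNS)])
    X = np.column_stack([
        base["elevation"], base["elevation"] ** 2, base["tri"],
        base["canopy"], base["disturbance"]])
    return DesignMatrix(X=X, column_names=list(DESIGN_COLUMNS),
                        site_ids=list(cov["site"]), means=means, sds=sds)
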