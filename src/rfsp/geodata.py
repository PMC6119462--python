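"""Point and grid data model, delimited-text / GeoTIFF I/O, and point-on-grid overlay.

Coordinates are planar (projected) throughout: distances are computed in
coordinate units.  Grids are north-up with square cells; cell membership uses
half-open intervals so every in-extent point maps to exactly one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "PointSet",
    "CovariateStack",
    "read_points",
    "write_points",
    "read_grid",
    "write_grid",
    "overlay",
    "SchemaError",
    "InputError",
]

# GeoTIFF tag codes (pixel scale, tiepoint, GDAL no-data)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113

_NODATA = -3.4028235e38  # lowest float32, conventional GDAL fill


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class InputError(ValueError):
    """An input is structurally valid but unusable (empty, out of range...)."""


@dataclass(frozen=True)
class GridSpec:
    """Regular north-up grid of square cells.

    ``origin`` is the outer corner of the top-left cell (its north-west
    corner).  Cell centers are ``origin_x + (j + 0.5) * cell_size`` easting
    and ``origin_y - (i + 0.5) * cell_size`` northing, row-major.
    """

    origin: tuple[float, float]
    cell_size: float
    nrows: int
    ncols: int
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("nrows and ncols must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) center coordinate arrays, each nrows x ncols."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column index of the cell containing each point.

        Membership is half-open: a point on a shared edge belongs to the
        cell to its east/south.  Out-of-extent points get index -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        j = np.floor((x - x0) / self.cell_size).astype(int)
        i = np.floor((y0 - y) / self.cell_size).astype(int)
        inside = (i >= 0) & (i < self.nrows) & (j >= 0) & (j < self.ncols)
        i = np.where(inside, i, -1)
        j = np.where(inside, j, -1)
        return i, j

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid's outer boundary."""
        x0, y0 = self.origin
        return (x0, x0 + self.ncols * self.cell_size,
                y0 - self.nrows * self.cell_size, y0)


def _check_units(coords: np.ndarray) -> None:
    # heuristic degree detection: warn, never reject
    if coords.size and np.all(np.abs(coords[:, 0]) <= 180) and np.all(np.abs(coords[:, 1]) <= 90):
        warnings.warn(
            "coordinates look like lon/lat degrees; distances are computed "
            "in coordinate units — project your data for metric distances",
            stacklevel=3,
        )


@dataclass
class PointSet:
    """Observation locations with target values and optional metadata.

    target is either all-numeric (regression) or all-categorical
    (class labels held as a string array); meas_sd holds per-point
    measurement-error standard deviations in target units.
    """

    coords: np.ndarray
    target: np.ndarray
    ids: np.ndarray | None = None
    time: np.ndarray | None = None
    meas_sd: np.ndarray | None = None
    type_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all coordinates must be finite")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("PointSet needs at least one point")
        self.target = np.asarray(self.target)
        if self.target.shape != (n,):
            raise ValueError("target length must match number of points")
        if self.target.dtype.kind in "fiu":
            self.target = self.target.astype(float)
        else:
            self.target = self.target.astype(object)
        if self.ids is None:
            self.ids = np.array([str(k + 1) for k in range(n)], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
        if self.meas_sd is not None:
            self.meas_sd = np.asarray(self.meas_sd, dtype=float)
            if not np.all(self.meas_sd > 0):
                raise ValueError("meas_sd must be > 0 for every point")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype="datetime64[D]")
        if self.type_label is not None:
            self.type_label = np.asarray(self.type_label, dtype=object)
        if self.duplicate_mask().any():
            warnings.warn(
                "duplicate coordinates present; zero-nugget kriging systems "
                "will be singular for these points",
                stacklevel=2,
            )
        _check_units(self.coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def is_categorical(self) -> bool:
        return self.target.dtype.kind not in "fiu"

    def duplicate_mask(self) -> np.ndarray:
        """True for every point that shares coordinates with an earlier one."""
        _, first = np.unique(self.coords, axis=0, return_index=True)
        mask = np.ones(self.n, dtype=bool)
        mask[first] = False
        return mask

    def subset(self, idx) -> "PointSet":
        idx = np.asarray(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PointSet(
                coords=self.coords[idx],
                target=self.target[idx],
                ids=self.ids[idx],
                time=None if self.time is None else self.time[idx],
                meas_sd=None if self.meas_sd is None else self.meas_sd[idx],
                type_label=None if self.type_label is None else self.type_label[idx],
            )


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid, with a validity mask.

    roles tags each layer geographic | reflectance | process; the mask is
    True on valid cells — masked-out cells are excluded from prediction
    and overlay.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match grid")
        for name, arr in self.layers.items():
            self.layers[name] = self._check_layer(name, arr)

    def _check_layer(self, name: str, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} has shape {arr.shape}, grid is {self.grid.shape}"
            )
        return arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def add_layer(self, name: str, values: np.ndarray, role: str = "process") -> None:
        if name in self.layers:
            raise ValueError(f"layer {name!r} already present")
        if role not in ("geographic", "reflectance", "process"):
            raise ValueError(f"unknown role {role!r}")
        self.layers[name] = self._check_layer(name, values)
        self.roles[name] = role

    def to_array(self) -> np.ndarray:
        """(n_layers, nrows, ncols) array in layer order."""
        return np.stack([self.layers[k] for k in self.layers])

    def table(self, valid_only: bool = True) -> pd.DataFrame:
        """Flatten valid cells to a DataFrame (one row per cell, row-major)."""
        flat = {k: v.ravel() for k, v in self.layers.items()}
        df = pd.DataFrame(flat)
        if valid_only:
            df = df[self.mask.ravel()].reset_index(drop=True)
        return df


_DEFAULT_SCHEMA = {"x": "x", "y": "y", "value": "value"}


def read_points(path, schema: Mapping[str, str] | None = None) -> PointSet:
    """Read a delimited-text point table into a PointSet.

    schema maps roles to column names: {x, y, value} required,
    {date, sd, class, type, id} optional.  'value' and 'class' are
    exclusive ways to name the target (numeric vs. categorical).
    Rows with unparseable coordinates are dropped with a warning count.
    """
    schema = dict(_DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise InputError(f"{path}: table has no data rows")
    for role in ("x", "y"):
        col = schema.get(role)
        if col is None or col not in df.columns:
            raise SchemaError(f"{path}: missing mapped column {col or role!r} for {role!r}")
    target_role = "class" if "class" in schema else "value"
    tcol = schema.get(target_role)
    if tcol is None or tcol not in df.columns:
        raise SchemaError(f"{path}: missing mapped column {tcol or target_role!r} for target")
    for role in ("date", "sd", "type", "id"):
        if role in schema and schema[role] not in df.columns:
            raise SchemaError(f"{path}: missing mapped column {schema[role]!r} for {role!r}")

    xs = pd.to_numeric(df[schema["x"]], errors="coerce")
    ys = pd.to_numeric(df[schema["y"]], errors="coerce")
    good = xs.notna() & ys.notna()
    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} rows with unparseable coordinates")
    df = df[good]
    if df.empty:
        raise InputError(f"{path}: no rows with valid coordinates")

    target = (
        df[tcol].astype(str).to_numpy(dtype=object)
        if target_role == "class"
        else pd.to_numeric(df[tcol], errors="coerce").to_numpy()
    )
    return PointSet(
        coords=np.column_stack([xs[good], ys[good]]),
        target=target,
        ids=df[schema["id"]].astype(str).to_numpy(dtype=object) if "id" in schema else None,
        time=pd.to_datetime(df[schema["date"]]).to_numpy(dtype="datetime64[D]")
        if "date" in schema
        else None,
        meas_sd=pd.to_numeric(df[schema["sd"]]).to_numpy() if "sd" in schema else None,
        type_label=df[schema["type"]].astype(str).to_numpy(dtype=object)
        if "type" in schema
        else None,
    )


def write_points(ps: PointSet, path) -> None:
    """Write a PointSet as CSV at full precision (17 significant digits)."""
    cols: dict[str, object] = {
        "id": ps.ids,
        "x": ps.coords[:, 0],
        "y": ps.coords[:, 1],
    }
    if ps.time is not None:
        cols["date"] = np.datetime_as_string(ps.time, unit="D")
    cols["class" if ps.is_categorical else "value"] = ps.target
    if ps.meas_sd is not None:
        cols["sd"] = ps.meas_sd
    if ps.type_label is not None:
        cols["type"] = ps.type_label
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g",
                              quoting=2 if ps.is_categorical else 0)


def default_schema_for(ps: PointSet) -> dict[str, str]:
    """Schema matching write_points output, for symmetric round-trips."""
    schema = {"x": "x", "y": "y", "id": "id"}
    schema["class" if ps.is_categorical else "value"] = (
        "class" if ps.is_categorical else "value"
    )
    if ps.time is not None:
        schema["date"] = "date"
    if ps.meas_sd is not None:
        schema["sd"] = "sd"
    if ps.type_label is not None:
        schema["type"] = "type"
    return schema


def write_grid(stack: CovariateStack, path) -> None:
    """Write a CovariateStack as a multiband GeoTIFF.

    One page per layer; layer names stored as page descriptions; mask
    encoded through the GDAL no-data convention.  Values are float64.
    """
    grid = stack.grid
    x0, y0 = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_NODATA, "s", 0, repr(_NODATA)),
    ]
    with tifffile.TiffWriter(path) as tw:
        for name in stack.layers:
            arr = stack.layers[name].astype(np.float64).copy()
            arr[~stack.mask] = _NODATA
            tw.write(arr, description=name, extratags=extratags, metadata=None)


def read_grid(path) -> CovariateStack:
    """Read a multiband GeoTIFF into a CovariateStack.

    Band descriptions become layer names (fallback band_1..band_k); the
    no-data value is mapped to the mask.  Requires pixel-scale and
    tiepoint georeferencing tags and identical shapes across bands.
    """
    layers: dict[str, np.ndarray] = {}
    grid: GridSpec | None = None
    mask: np.ndarray | None = None
    with tifffile.TiffFile(path) as tf:
        for k, page in enumerate(tf.pages):
            arr = page.asarray().astype(float)
            if grid is None:
                scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
                tie_tag = page.tags.get(_TAG_TIEPOINT)
                if scale_tag is None or tie_tag is None:
                    raise InputError(f"{path}: missing georeferencing tags")
                sx, sy = scale_tag.value[0], scale_tag.value[1]
                if not np.isclose(sx, sy):
                    raise InputError(f"{path}: non-square cells ({sx} x {sy})")
                tie = tie_tag.value
                origin = (tie[3] - tie[0] * sx, tie[4] + tie[1] * sy)
                grid = GridSpec(origin=origin, cell_size=float(sx),
                                nrows=arr.shape[0], ncols=arr.shape[1])
                mask = np.ones(arr.shape, dtype=bool)
            elif arr.shape != grid.shape:
                raise InputError(
                    f"{path}: band {k + 1} shape {arr.shape} != {grid.shape}"
                )
            nodata_tag = page.tags.get(_TAG_NODATA)
            if nodata_tag is not None:
                nodata = float(nodata_tag.value)
                bad = np.isclose(arr, nodata) | np.isnan(arr)
            else:
                bad = np.isnan(arr)
            mask &= ~bad
            name = page.description or f"band_{k + 1}"
            arr = arr.copy()
            arr[bad] = np.nan
            layers[name] = arr
    if grid is None:
        raise InputError(f"{path}: no raster bands")
    return CovariateStack(grid=grid, layers=layers, mask=mask)


def overlay(ps: PointSet, stack: CovariateStack) -> pd.DataFrame:
    """Covariate values at the cell containing each point (nearest-cell).

    Returns one row per point in point order; points outside the grid or
    on masked cells get NaN rows.  The number of such rows is reported in
    ``df.attrs['n_missing']`` and as a warning.  All points outside is an
    error.
    """
    i, j = stack.grid.cell_index(ps.coords[:, 0], ps.coords[:, 1])
    inside = i >= 0
    if not inside.any():
        raise InputError("all points fall outside the grid extent")
    valid = inside.copy()
    valid[inside] &= stack.mask[i[inside], j[inside]]
    out = np.full((ps.n, stack.n_layers), np.nan)
    if valid.any():
        out[valid] = np.column_stack(
            [stack.layers[name][i[valid], j[valid]] for name in stack.layers]
        ) if stack.n_layers else np.empty((valid.sum(), 0))
    n_missing = int((~valid).sum())
    if n_missing:
        warnings.warn(f"{n_missing} points outside grid or on masked cells")
    df = pd.DataFrame(out, columns=stack.layer_names)
    df.attrs["n_missing"] = n_missing
    return df
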