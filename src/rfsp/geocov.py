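"""Geographical covariates: buffer distances, coordinate layers, temporal
covariates, and principal-component compression of covariate stacks.

Buffer distances are the geographic covariates X_G of the RFsp model: one
raster per observation point (or per class) whose cell values are exact
Euclidean distances from cell centers to the point, in coordinate units.
They let a tree ensemble reproduce the geographical-proximity information
that kriging encodes through the variogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .geodata import CovariateStack, GridSpec, InputError, PointSet

__all__ = [
    "BufferDistanceStack",
    "TemporalCovariates",
    "buffer_distances",
    "class_buffer_distances",
    "coordinate_grids",
    "temporal_covariates",
    "pca_covariates",
]

#: refuse to build more buffer layers than this without explicit override;
#: with very many training points, per-class or binned-value distances are
#: the practical alternative
DEFAULT_LAYER_CAP = 1000


@dataclass
class BufferDistanceStack:
    """A CovariateStack of distance layers plus what each layer refers to."""

    stack: CovariateStack
    source_ids: list[str]

    @property
    def n_layers(self) -> int:
        return self.stack.n_layers


@dataclass
class TemporalCovariates:
    """Calendar covariates for spatiotemporal forests.

    cdate: whole days elapsed since 1970-01-01 (a monotone time axis that
    lets the forest fit day-to-day shifts); doy: day-of-year 1..366
    (a seasonality axis).
    """

    cdate: np.ndarray
    doy: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cdate": self.cdate, "doy": self.doy})


def _distance_layers(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """(k, nrows, ncols) exact center-to-point Euclidean distances."""
    X, Y = grid.cell_centers()
    dx = X[None, :, :] - points[:, 0, None, None]
    dy = Y[None, :, :] - points[:, 1, None, None]
    return np.sqrt(dx * dx + dy * dy)


def buffer_distances(
    ps: PointSet, grid: GridSpec, cap: int = DEFAULT_LAYER_CAP
) -> BufferDistanceStack:
    """One Euclidean-distance layer per observation point.

    Layer ``dist_<id>`` holds, at each cell, the distance from the cell
    center to point <id>.  Refuses to build more than ``cap`` layers:
    with thousands of points, use class_buffer_distances or bin the
    target into 10-15 value classes and take per-class distances instead.
    """
    if ps.n > cap:
        raise InputError(
            f"{ps.n} points would produce {ps.n} buffer layers (cap {cap}); "
            "use class_buffer_distances or value-binned classes, or raise cap="
        )
    dists = _distance_layers(ps.coords, grid)
    stack = CovariateStack(grid=grid)
    ids = [str(i) for i in ps.ids]
    for name, layer in zip(ids, dists):
        stack.add_layer(f"dist_{name}", layer, role="geographic")
    return BufferDistanceStack(stack=stack, source_ids=ids)


def class_buffer_distances(ps: PointSet, grid: GridSpec) -> BufferDistanceStack:
    """One layer per class: distance to the nearest observation of the class.

    Requires a categorical target.  Classes with zero observations cannot
    occur by construction (classes are taken from the data), but an
    explicit requested class list may name absent classes — those are
    omitted with a warning.
    """
    if not ps.is_categorical:
        raise InputError("class_buffer_distances needs a categorical target")
    classes = [c for c in pd.unique(ps.target)]
    stack = CovariateStack(grid=grid)
    kept: list[str] = []
    for c in classes:
        sel = ps.target == c
        if not sel.any():  # defensive: pd.unique only yields present classes
            warnings.warn(f"class {c!r} has no observations; layer omitted")
            continue
        layer = _distance_layers(ps.coords[sel], grid).min(axis=0)
        stack.add_layer(f"dist_cls_{c}", layer, role="geographic")
        kept.append(str(c))
    return BufferDistanceStack(stack=stack, source_ids=kept)


def coordinate_grids(grid: GridSpec) -> CovariateStack:
    """Coordinate layers s1 (easting) and s2 (northing) of cell centers.

    Using coordinates alone as predictors is known to produce blocky
    tree-boundary artifacts; they are meant as a supplement to buffer
    distances, not a replacement.
    """
    X, Y = grid.cell_centers()
    stack = CovariateStack(grid=grid)
    stack.add_layer("s1", X, role="geographic")
    stack.add_layer("s2", Y, role="geographic")
    return stack


def temporal_covariates(dates) -> TemporalCovariates:
    """cdate (whole days since 1970-01-01) and doy (1..366) per date.

    Dates are parsed as ISO; doy follows the proleptic Gregorian calendar,
    so Dec 31 of a leap year is day 366.
    """
    try:
        ts = pd.DatetimeIndex(pd.to_datetime(np.asarray(dates)))
    except (ValueError, TypeError) as exc:
        raise InputError(f"unparseable date in input: {exc}") from exc
    epoch = pd.Timestamp("1970-01-01")
    cdate = ((ts - epoch) // pd.Timedelta(days=1)).to_numpy()
    return TemporalCovariates(cdate=cdate.astype(int), doy=ts.dayofyear.to_numpy())


def pca_covariates(
    stack: CovariateStack, n_components: int | None = None
) -> tuple[CovariateStack, pd.DataFrame, np.ndarray]:
    """Compress a covariate stack into principal-component layers.

    Computed on centered, unit-variance layer values over valid cells;
    constant layers are dropped with a warning before decomposition.
    Returns (PC stack, loadings table, explained-variance fractions over
    ALL components of the standardized stack).  Each component's sign is
    fixed so its largest-magnitude loading is positive.
    """
    if stack.n_layers < 2:
        raise InputError("pca_covariates needs at least 2 layers")
    names = stack.layer_names
    valid = stack.mask
    data = np.column_stack([stack.layers[k][valid] for k in names])
    sds = data.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant layers before PCA: {dropped}")
        names = [n for n, k in zip(names, keep) if k]
        data = data[:, keep]
        sds = sds[keep]
    if len(names) < 2:
        raise InputError("fewer than 2 non-constant layers; nothing to decompose")
    z = (data - data.mean(axis=0)) / sds

    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_  # (k, p)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]

    k = loadings.shape[0] if n_components is None else min(n_components, loadings.shape[0])
    out = CovariateStack(grid=stack.grid, mask=stack.mask.copy())
    for c in range(k):
        layer = np.full(stack.grid.shape, np.nan)
        layer[valid] = scores[:, c]
        out.add_layer(f"PC{c + 1}", layer, role="process")
    load_df = pd.DataFrame(
        loadings[:k].T, index=names, columns=[f"PC{c + 1}" for c in range(k)]
    )
    return out, load_df, pca.explained_variance_ratio_
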