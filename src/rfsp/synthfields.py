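"""Synthetic spatial and spatiotemporal data with known generating models.

Gaussian random fields are simulated by dense Cholesky factorization of the
covariance matrix over grid-cell centers — exact for any valid covariance
at desk scale (a guard refuses grids too large to factor densely).  On top
of the plain field the module builds the sampling regimes the package is
exercised against: skewed (lognormal) fields, covariate-driven trends,
heteroscedastic two-source samples with recorded measurement errors,
multinomial class maps via argmax of latent fields, and zero-inflated
seasonal daily fields observed at fixed stations.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky
from scipy.spatial.distance import cdist, squareform, pdist

from .geodata import CovariateStack, GridSpec, InputError, PointSet
from .krige import VariogramModel

__all__ = [
    "FieldSpec",
    "SpaceTimeSpec",
    "simulate_grf",
    "simulate_grf_at",
    "sample_design",
    "make_dataset",
    "make_categorical",
    "make_spacetime",
]

MAX_DENSE_CELLS = 6000
_JITTER = 1e-10


@dataclass
class FieldSpec:
    """One Gaussian-random-field realization recipe.

    trend applies coefficients to named layers of ``trend_covariates``
    before noise; transform 'exp' exponentiates the field (lognormal,
    emulating skewed concentration data).  Realized variance over many
    replicates approximates nugget + psill (pre-transform).
    """

    grid: GridSpec
    vgm: VariogramModel
    mean: float = 0.0
    trend: dict[str, float] | None = None
    trend_covariates: CovariateStack | None = None
    transform: str = "none"  # none | exp
    seed: int = 0


@dataclass
class SpaceTimeSpec:
    """Daily seasonal fields with AR(1) temporal persistence and censoring.

    Daily field = seasonal mean (sinusoid in day-of-year) + AR(1)-evolving
    spatial GRF + nugget; values below zero_threshold are censored to 0,
    producing the zero-inflation of daily precipitation records.
    """

    grid: GridSpec
    spatial_vgm: VariogramModel
    seasonal_amplitude: float = 1.0
    seasonal_phase: float = 0.0  # doy (days) of the seasonal peak
    temporal_corr: float = 0.5   # lag-1 autocorrelation of the latent field
    zero_threshold: float = 0.0
    seed: int = 0


def _chol_factor(coords: np.ndarray, vgm: VariogramModel) -> np.ndarray:
    """Lower Cholesky factor of the structured (no-nugget) covariance."""
    if vgm.psill == 0:
        return np.zeros((len(coords), len(coords)))
    C = vgm.psill * np.ones((len(coords), len(coords)))
    if vgm.family != "pure-nugget":
        d = squareform(pdist(coords))
        C = np.where(d == 0, vgm.psill, np.asarray(
            VariogramModel(vgm.family, 0.0, vgm.psill, vgm.range_param).covariance(d)
        ))
    C[np.diag_indices_from(C)] += _JITTER * vgm.total_sill
    try:
        return cholesky(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise InputError(f"covariance not positive definite: {exc}") from exc


def _draw_field(L: np.ndarray, vgm: VariogramModel, rng: np.random.Generator) -> np.ndarray:
    z = L @ rng.standard_normal(L.shape[0])
    if vgm.nugget > 0:
        z = z + np.sqrt(vgm.nugget) * rng.standard_normal(L.shape[0])
    return z


def simulate_grf(spec: FieldSpec) -> CovariateStack:
    """Unconditional GRF realization on the grid, one layer named 'field'."""
    grid = spec.grid
    if grid.n_cells > MAX_DENSE_CELLS:
        raise InputError(
            f"{grid.n_cells} cells exceeds the dense-factorization guard "
            f"({MAX_DENSE_CELLS}); use a coarser grid"
        )
    X, Y = grid.cell_centers()
    coords = np.column_stack([X.ravel(), Y.ravel()])
    rng = np.random.default_rng(spec.seed)
    z = spec.mean + _draw_field(_chol_factor(coords, spec.vgm), spec.vgm, rng)
    z = z.reshape(grid.shape)
    if spec.trend:
        if spec.trend_covariates is None:
            raise InputError("trend coefficients given without trend_covariates")
        for name, beta in spec.trend.items():
            z = z + beta * spec.trend_covariates.layers[name]
    if spec.transform == "exp":
        z = np.exp(z)
    elif spec.transform != "none":
        raise InputError(f"unknown transform {spec.transform!r}")
    stack = CovariateStack(grid=grid)
    stack.add_layer("field", z, role="process")
    return stack


def simulate_grf_at(
    coords: np.ndarray, vgm: VariogramModel, seed: int, mean: float = 0.0
) -> np.ndarray:
    """GRF values at arbitrary coordinates (for point-support simulations)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) > MAX_DENSE_CELLS:
        raise InputError("too many points for dense factorization")
    rng = np.random.default_rng(seed)
    return mean + _draw_field(_chol_factor(coords, vgm), vgm, rng)


def sample_design(
    grid: GridSpec,
    n: int,
    design: str = "uniform",
    seed: int = 0,
    n_clusters: int = 5,
    cluster_radius: float | None = None,
    return_parents: bool = False,
):
    """Sampling locations: 'uniform' over the extent or parent-offspring
    'clustered' (emulating survey bias, where training points over-represent
    some regions).

    Clustered: n_clusters uniform parents; each point is a parent plus an
    isotropic Gaussian offset with SD cluster_radius/2, redrawn until it
    falls inside the extent (so >= 80% land within cluster_radius of a
    parent).  Default radius is 1/8 of the shorter grid side.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = grid.extent()
    if design == "uniform":
        xs = rng.uniform(xmin, xmax, n)
        ys = rng.uniform(ymin, ymax, n)
        pts = np.column_stack([xs, ys])
        return (pts, pts) if return_parents else pts
    if design != "clustered":
        raise InputError(f"unknown design {design!r}")
    if cluster_radius is None:
        cluster_radius = min(xmax - xmin, ymax - ymin) / 8.0
    parents = np.column_stack(
        [rng.uniform(xmin, xmax, n_clusters), rng.uniform(ymin, ymax, n_clusters)]
    )
    pts = np.empty((n, 2))
    for k in range(n):
        parent = parents[rng.integers(n_clusters)]
        for _ in range(1000):
            cand = parent + rng.normal(0.0, cluster_radius / 2.0, 2)
            if xmin <= cand[0] < xmax and ymin <= cand[1] < ymax:
                break
        pts[k] = cand
    return (pts, parents) if return_parents else pts


def make_dataset(
    field: CovariateStack,
    locations: np.ndarray,
    noise_sd: float | list[float] = 0.0,
    source_fractions: list[float] | None = None,
    seed: int = 0,
    layer: str = "field",
) -> PointSet:
    """Sample a field at locations with per-source Gaussian measurement noise.

    With several sources (e.g. accurate lab analyses vs. a larger, noisier
    field survey), each point is assigned a source by source_fractions and
    gets that source's noise SD; meas_sd records the generating SD
    truthfully so downstream case weights 1/meas_sd^2 are available.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    rng = np.random.default_rng(seed)
    i, j = field.grid.cell_index(locations[:, 0], locations[:, 1])
    if np.any(i < 0):
        raise InputError("sampling locations outside the field grid")
    truth = field.layers[layer][i, j]

    sds = np.atleast_1d(np.asarray(noise_sd, dtype=float))
    if np.any(sds < 0):
        raise InputError("noise SDs must be >= 0")
    if len(sds) == 1:
        point_sd = np.full(len(locations), sds[0])
    else:
        if source_fractions is None or len(source_fractions) != len(sds):
            raise InputError("source_fractions must match the number of noise SDs")
        fr = np.asarray(source_fractions, dtype=float)
        if not np.isclose(fr.sum(), 1.0):
            raise InputError("source_fractions must sum to 1")
        src = rng.choice(len(sds), size=len(locations), p=fr)
        point_sd = sds[src]
    values = truth + rng.normal(0.0, 1.0, len(locations)) * point_sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicates / degree heuristics
        return PointSet(
            coords=locations,
            target=values,
            meas_sd=point_sd if np.all(point_sd > 0) else None,
        )


def make_categorical(
    grid: GridSpec,
    K: int,
    spatial_vgm: VariogramModel,
    seed: int = 0,
    n_points: int = 150,
) -> tuple[PointSet, np.ndarray]:
    """Multinomial class map: argmax of K latent GRFs, plus a point sample.

    Returns (points with categorical target, true class map).  Errors if
    the realization collapses to fewer than 2 classes — a symptom of too
    little structured variance relative to the latents' spread.
    """
    if K < 2:
        raise InputError("K must be >= 2")
    rng = np.random.default_rng(seed)
    latents = np.stack([
        simulate_grf(FieldSpec(grid=grid, vgm=spatial_vgm,
                               seed=int(rng.integers(2**31)))).layers["field"]
        for _ in range(K)
    ])
    class_map = latents.argmax(axis=0)
    present = np.unique(class_map)
    if len(present) < 2:
        raise InputError(
            "latent fields collapsed to a single class; increase the "
            "partial sill or shrink the range"
        )
    if len(present) < K:
        warnings.warn(f"only {len(present)}/{K} classes occupy cells")
    locs = sample_design(grid, n_points, "uniform", seed=int(rng.integers(2**31)))
    i, j = grid.cell_index(locs[:, 0], locs[:, 1])
    labels = np.array([f"class_{c}" for c in class_map[i, j]], dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = PointSet(coords=locs, target=labels)
    return ps, class_map


def make_spacetime(
    spec: SpaceTimeSpec,
    n_days: int,
    n_stations: int,
    start: str = "2014-01-01",
) -> tuple[PointSet, np.ndarray]:
    """Zero-inflated seasonal daily fields at fixed stations.

    Latent daily field: seasonal sinusoid in day-of-year plus an AR(1)
    chain of spatial GRFs (lag-1 correlation temporal_corr) plus nugget;
    observed value = max(latent, 0) after left-censoring at
    zero_threshold.  Returns one PointSet with n_days * n_stations rows
    (time column set) and the (n_days, n_stations) latent matrix.
    """
    if n_days < 2:
        raise InputError("n_days must be >= 2")
    a = spec.temporal_corr
    if not (-1 < a < 1):
        raise InputError("temporal_corr must satisfy |a| < 1")
    rng = np.random.default_rng(spec.seed)
    stations = sample_design(spec.grid, n_stations, "uniform",
                             seed=int(rng.integers(2**31)))
    L = _chol_factor(stations, spec.spatial_vgm)

    def innov():
        return _draw_field(L, spec.spatial_vgm, rng)

    dates = np.arange(np.datetime64(start), np.datetime64(start) + n_days)
    doy = (
        (dates - dates.astype("datetime64[Y]").astype("datetime64[D]"))
        .astype(int) + 1
    )
    season = spec.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - spec.seasonal_phase) / 365.25
    )

    latent = np.empty((n_days, n_stations))
    z = innov()
    latent[0] = season[0] + z
    scale = np.sqrt(1 - a * a)
    for t in range(1, n_days):
        z = a * z + scale * innov()
        latent[t] = season[t] + z

    observed = np.where(latent <= spec.zero_threshold, 0.0, latent)
    coords = np.tile(stations, (n_days, 1))
    times = np.repeat(dates, n_stations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # repeated station coordinates
        ps = PointSet(coords=coords, target=observed.ravel(), time=times)
    return ps, latent
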