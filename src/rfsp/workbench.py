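"""Scenario orchestration: method recipes for cross-validation, a declarative
scenario configuration, and the end-to-end pipeline
(simulate -> covariates -> fit -> predict -> cross-validate -> compare).

The recipes give ordinary kriging, regression kriging and RFsp a common
fit/predict surface so :func:`rfsp.evalcv.cross_validate` can refit any of
them per fold.  The RFsp recipe rebuilds buffer-distance layers from
training-fold points only, so held-out locations never leak into the
covariates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError
from scipy.stats import norm

from . import evalcv, forest, geocov, geodata, krige, synthfields
from .geodata import CovariateStack, GridSpec, InputError, PointSet

__all__ = [
    "OKRecipe",
    "RKRecipe",
    "RFspRecipe",
    "ScenarioConfig",
    "run_pipeline",
]

log = logging.getLogger("rfsp")


# ---------------------------------------------------------------------------
# method recipes

@dataclass
class OKRecipe:
    """Ordinary kriging: variogram fitted per training fold (or fixed).

    sigma_scale multiplies the reported error SD — a deliberate
    miscalibration knob for z-score experiments, default 1.
    """

    family: str = "exponential"
    n_bins: int = 15
    vgm: krige.VariogramModel | None = None  # fixed model, skips refitting
    eta: float | None = None                 # Box-Cox; 0 = log-normal kriging
    sigma_scale: float = 1.0

    def fit(self, ps_train: PointSet, stacks=None):
        y = ps_train.target.astype(float)
        if self.eta is not None:
            y = krige.boxcox(y, self.eta)
            ps_train = PointSet(coords=ps_train.coords, target=y, ids=ps_train.ids)
        vgm = self.vgm
        if vgm is None:
            emp = krige.empirical_variogram(ps_train, n_bins=self.n_bins)
            vgm = krige.fit_variogram(emp, family=self.family)
        return (ps_train, vgm)

    def predict(self, model, coords):
        ps_train, vgm = model
        res = krige.ok_predict(ps_train, coords, vgm)
        pred, var = res.predictions, res.variances
        if self.eta == 0:
            pred, var = krige.lognormal_backtransform(pred, var)
        elif self.eta is not None:
            pred = krige.boxcox_inverse(pred, self.eta)
        return pred, self.sigma_scale * np.sqrt(var)

    def predict_quantiles(self, model, coords, qs):
        """Gaussian intervals from the kriging mean and SD (transformed
        scale when eta is set, back-transformed per quantile)."""
        ps_train, vgm = model
        res = krige.ok_predict(ps_train, coords, vgm)
        sd = self.sigma_scale * np.sqrt(res.variances)
        out = {}
        for q in qs:
            v = res.predictions + norm.ppf(q) * sd
            if self.eta == 0:
                v = np.exp(v)
            elif self.eta is not None:
                v = krige.boxcox_inverse(v, self.eta)
            out[q] = v
        return out


@dataclass
class RKRecipe:
    """Regression kriging on the supplied covariate stacks."""

    family: str = "exponential"
    n_bins: int = 15
    eta: float | None = None

    def fit(self, ps_train: PointSet, stacks):
        if not stacks:
            raise InputError("RK needs at least one covariate stack")
        return (ps_train, stacks)

    def predict(self, model, coords):
        ps_train, stacks = model
        stack = stacks[0]
        if len(stacks) > 1:
            stack = CovariateStack(grid=stacks[0].grid,
                                   mask=np.logical_and.reduce([s.mask for s in stacks]))
            for s in stacks:
                for name in s.layers:
                    stack.add_layer(name, s.layers[name], s.roles.get(name, "process"))
        res = krige.rk_predict(ps_train, stack, coords,
                               family=self.family, n_bins=self.n_bins, eta=self.eta)
        return res.predictions, np.sqrt(res.variances)


@dataclass
class RFspRecipe:
    """RFsp: buffer distances from training points (+ optional thematic
    stacks) feed a quantile forest; sigma from the 68.27% interval.

    mtry_fraction resolves mtry per fold as round(fraction * p).  For
    buffer-distance-only models a high fraction (~0.85, i.e. most of the
    distance layers as split candidates) matches how such models are run
    in practice; the generic p/3 default applies when it is None.
    """

    params: forest.ForestParams = dc_field(default_factory=forest.ForestParams)
    use_buffers: bool = True
    use_coordinates: bool = False
    grid: GridSpec | None = None
    mtry_fraction: float | None = None

    def _stacks_for(self, ps_train, stacks):
        grid = self.grid
        if grid is None:
            if stacks:
                grid = stacks[0].grid
            else:
                raise InputError("RFspRecipe needs a grid (explicit or via stacks)")
        used = list(stacks or [])
        if self.use_buffers:
            used.insert(0, geocov.buffer_distances(ps_train, grid).stack)
        if self.use_coordinates:
            used.append(geocov.coordinate_grids(grid))
        return used

    def fit(self, ps_train: PointSet, stacks=None):
        used = self._stacks_for(ps_train, stacks)
        design, w = forest.build_design(ps_train, used)
        params = self.params
        if w is not None and params.case_weights is None:
            params = dataclass_replace(params, case_weights=w)
        if self.mtry_fraction is not None and params.mtry is None:
            p = design.shape[1] - 1
            params = dataclass_replace(
                params, mtry=max(1, round(self.mtry_fraction * p)))
        model = forest.fit_forest(design, params)
        return (model, used)

    def _rows(self, used, coords):
        coords = np.atleast_2d(coords)
        dummy = PointSet(coords=coords, target=np.zeros(len(coords)))
        dfs = [geodata.overlay(dummy, s) for s in used]
        return pd.concat(dfs, axis=1)

    def predict(self, model, coords):
        rf, used = model
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X0 = self._rows(used, coords)
        qp = forest.predict_quantiles(rf, X0, qs=(0.5,), sigma=True)
        return qp.mean, qp.sigma

    def predict_quantiles(self, model, coords, qs):
        rf, used = model
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X0 = self._rows(used, coords)
        qp = forest.predict_quantiles(rf, X0, qs=qs, sigma=False)
        return qp.quantiles


def dataclass_replace(params: forest.ForestParams, **kw) -> forest.ForestParams:
    import dataclasses
    return dataclasses.replace(params, **kw)


# ---------------------------------------------------------------------------
# scenario configuration

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    nrows: int = 20
    ncols: int = 20
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float | None = None  # default: nrows * cell_size (y grows up)

    def build(self) -> GridSpec:
        oy = self.origin_y if self.origin_y is not None else self.nrows * self.cell_size
        return GridSpec(origin=(self.origin_x, oy), cell_size=self.cell_size,
                        nrows=self.nrows, ncols=self.ncols)


class FieldConfig(_Strict):
    family: str = "exponential"
    nugget: float = 0.1
    psill: float = 1.0
    range_param: float = 5.0
    mean: float = 0.0
    transform: str = "none"

    def vgm(self) -> krige.VariogramModel:
        return krige.VariogramModel(self.family, self.nugget, self.psill,
                                    self.range_param)


class SampleConfig(_Strict):
    n: int = 60
    design: str = "uniform"
    noise_sd: float = 0.0


class OKConfig(_Strict):
    family: str = "exponential"
    n_bins: int = 15
    eta: float | None = None


class RFspConfig(_Strict):
    num_trees: int = 300
    mtry: int | None = None
    min_node_size: int | None = None
    sample_fraction: float = 1.0
    use_coordinates: bool = False


class MethodsConfig(_Strict):
    ok: OKConfig | None = None
    rk: OKConfig | None = None
    rfsp: RFspConfig | None = None


class CVConfig(_Strict):
    k: int = 5


class DataConfig(_Strict):
    points: str  # CSV path
    x: str = "x"
    y: str = "y"
    value: str = "value"


class ScenarioConfig(_Strict):
    """Declarative scenario: synthetic field or point file, methods, CV.

    Unknown keys are rejected; the fully resolved config (defaults
    filled) is emitted alongside every run's outputs.
    """

    seed: int = 0
    out_dir: str = "rfsp_run"
    grid: GridConfig = GridConfig()
    field: FieldConfig = FieldConfig()
    sample: SampleConfig = SampleConfig()
    data: DataConfig | None = None
    methods: MethodsConfig = MethodsConfig(ok=OKConfig(), rfsp=RFspConfig())
    cv: CVConfig = CVConfig()

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except ValidationError as exc:
            raise InputError(f"invalid scenario config: {exc}") from exc


# ---------------------------------------------------------------------------
# pipeline

def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: ScenarioConfig) -> Path:
    """Execute a scenario end to end; returns the output directory.

    Writes: resolved config, sampled points CSV, truth GeoTIFF (synthetic
    runs), per-method prediction/sigma GeoTIFFs and CV reports
    (JSON + per-point CSV), a side-by-side comparison table, and a run
    summary with per-stage timings.  A single global seed deterministically
    derives all stage seeds.
    """
    t_all = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.model_dump()
    cfg_text = json.dumps(resolved, indent=1, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:12]
    (out / "config_resolved.json").write_text(cfg_text)
    seeds = _stage_seeds(config.seed, ["field", "sample", "noise", "cv", "fit"])
    timings: dict[str, float] = {}

    grid = config.grid.build()
    vgm_true = config.field.vgm()

    t0 = time.time()
    if config.data is not None:
        ps = geodata.read_points(config.data.points,
                                 {"x": config.data.x, "y": config.data.y,
                                  "value": config.data.value})
        truth = None
    else:
        truth = synthfields.simulate_grf(synthfields.FieldSpec(
            grid=grid, vgm=vgm_true, mean=config.field.mean,
            transform=config.field.transform, seed=seeds["field"]))
        locs = synthfields.sample_design(grid, config.sample.n,
                                         config.sample.design, seed=seeds["sample"])
        ps = synthfields.make_dataset(truth, locs, noise_sd=config.sample.noise_sd,
                                      seed=seeds["noise"])
        geodata.write_grid(truth, out / "truth.tif")
    geodata.write_points(ps, out / "points.csv")
    timings["data"] = time.time() - t0
    log.info("data stage: n=%d (%.2fs)", ps.n, timings["data"])

    recipes: dict[str, object] = {}
    m = config.methods
    if m.ok is not None:
        recipes["ok"] = OKRecipe(family=m.ok.family, n_bins=m.ok.n_bins, eta=m.ok.eta)
    if m.rk is not None:
        recipes["rk"] = RKRecipe(family=m.rk.family, n_bins=m.rk.n_bins, eta=m.rk.eta)
    if m.rfsp is not None:
        recipes["rfsp"] = RFspRecipe(
            params=forest.ForestParams(
                num_trees=m.rfsp.num_trees, mtry=m.rfsp.mtry,
                min_node_size=m.rfsp.min_node_size,
                sample_fraction=m.rfsp.sample_fraction, seed=seeds["fit"]),
            use_coordinates=m.rfsp.use_coordinates, grid=grid)

    thematic: list[CovariateStack] = []
    if "rk" in recipes:
        # RK needs covariates; in synthetic runs give it the coordinate layers
        thematic = [geocov.coordinate_grids(grid)]

    rows = []
    X, Y = grid.cell_centers()
    cell_coords = np.column_stack([X.ravel(), Y.ravel()])
    for name, recipe in recipes.items():
        t0 = time.time()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evalcv.cross_validate(recipe, ps, thematic or None,
                                           k=config.cv.k, seed=seeds["cv"])
            model = recipe.fit(ps, thematic or None)
            pred, sigma = recipe.predict(model, cell_coords)
        surf = CovariateStack(grid=grid)
        surf.add_layer("prediction", pred.reshape(grid.shape))
        surf.add_layer("sigma", sigma.reshape(grid.shape))
        geodata.write_grid(surf, out / f"{name}_surface.tif")
        report.to_json(out / f"{name}_cv.json")
        report.per_point().to_csv(out / f"{name}_cv_points.csv", index=False)
        timings[name] = time.time() - t0
        rows.append({"method": name, **{k: v for k, v in report.metrics.items()}})
        log.info("method %s: rmse=%.4g (%.2fs)", name,
                 report.metrics["rmse"], timings[name])

    comparison = pd.DataFrame(rows)
    comparison.to_csv(out / "comparison.csv", index=False)
    summary = {
        "config_hash": cfg_hash,
        "seeds": seeds,
        "n_points": int(ps.n),
        "methods": {r["method"]: {k: (None if isinstance(v, float) and not np.isfinite(v)
                                      else v)
                                  for k, v in r.items() if k != "method"}
                    for r in rows},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_all, 3),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
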