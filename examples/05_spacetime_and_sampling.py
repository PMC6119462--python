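"""Spatiotemporal prediction and error-guided second-stage sampling.

Part 1: daily zero-inflated fields at fixed stations; the forest uses
buffer distances plus calendar covariates (days-since-1970, day-of-year),
with high mtry so the dominant temporal axes are never missed at splits.
Part 2: where to sample next — pick the highest-sigma cells subject to a
minimum spacing.
"""

import numpy as np

from rfsp import GridSpec, PointSet, VariogramModel
from rfsp import forest, geocov
from rfsp.evalcv import compute_metrics, propose_second_stage
from rfsp.geodata import CovariateStack
from rfsp.synthfields import (
    FieldSpec, SpaceTimeSpec, make_dataset, make_spacetime, sample_design,
    simulate_grf,
)

grid = GridSpec(origin=(0.0, 25.0), cell_size=1.0, nrows=25, ncols=25)
vgm = VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=6.0)

# --- space-time -------------------------------------------------------------
spec = SpaceTimeSpec(grid=grid, spatial_vgm=vgm, seasonal_amplitude=1.0,
                     temporal_corr=0.6, zero_threshold=0.3, seed=51)
ps, latent = make_spacetime(spec, n_days=90, n_stations=25)
zero_frac = (ps.target == 0.0).mean()
print(f"space-time sample: {ps.n} rows, zero-inflation {zero_frac:.1%}")

# leave-stations-out: train on 20 stations, predict the other 5 on all days
station_coords = ps.coords[:25]  # first day's block, fixed across days
test_stations = station_coords[20:]
is_test = np.isin(ps.coords[:, 0], test_stations[:, 0])
ps_tr, ps_te = ps.subset(np.where(~is_test)[0]), ps.subset(np.where(is_test)[0])

# buffer distances from TRAINING stations only
train_stations = PointSet(coords=station_coords[:20], target=np.zeros(20))
bd = geocov.buffer_distances(train_stations, grid)
design, _ = forest.build_design(ps_tr, bd.stack)  # adds cdate/doy from time
p = design.shape[1] - 1
model = forest.fit_forest(design, forest.ForestParams(
    num_trees=200, seed=1, mtry=round(0.85 * p)))  # keep mtry > p/2

design_te, _ = forest.build_design(ps_te, bd.stack)
pred = forest.predict_mean(model, design_te.drop(columns="target"))
m = compute_metrics(ps_te.target.astype(float), pred)
print(f"held-out stations, all days: RMSE={m['rmse']:.3f}  CCC={m['ccc']:.3f}")
print("top covariates:", list(model.importance.index[:3]))
# calendar covariates usually rank among the most important: they let the
# forest re-shape the surface day by day

# --- second-stage sampling --------------------------------------------------
field = simulate_grf(FieldSpec(grid=grid, vgm=vgm, seed=61))
first = make_dataset(field, sample_design(grid, 60, "clustered", seed=62), seed=63)
from rfsp.workbench import RFspRecipe

recipe = RFspRecipe(params=forest.ForestParams(num_trees=150, seed=2),
                    grid=grid, mtry_fraction=0.85)
mdl = recipe.fit(first, None)
X, Y = grid.cell_centers()
_, sigma = recipe.predict(mdl, np.column_stack([X.ravel(), Y.ravel()]))
err_map = CovariateStack(grid=grid)
err_map.add_layer("sigma", sigma.reshape(grid.shape))
new_pts = propose_second_stage(err_map, n_new=10, min_spacing=4.0)
print(f"second stage: {len(new_pts)} new locations, first at "
      f"({new_pts[0, 0]:.1f}, {new_pts[0, 1]:.1f}) where predicted error is highest")
# clustered first-stage designs leave high-sigma gaps; the proposal fills
# them while keeping the new points spread out
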