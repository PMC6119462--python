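"""Reproducible synthetic benchmark battery.

Each function runs one self-contained experiment on simulated Gaussian
random fields with known generating parameters and returns the measured
quantities — solver agreement, estimator recovery, calibration, and the
head-to-head comparison of the forest-based predictor against kriging.
These are the package's own verification experiments: the same battery
backs the test suite and the reproduction script.

All experiments are pure functions of their seed; problem sizes are kept
at desk scale (grids of at most a few thousand cells, samples of a few
hundred points) so the full battery runs in minutes on one CPU.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from . import evalcv, forest, geocov
from .geodata import GridSpec, PointSet
from .krige import (
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    lognormal_backtransform,
    ok_predict,
)
from .synthfields import FieldSpec, make_dataset, sample_design, simulate_grf, simulate_grf_at
from .workbench import OKRecipe, RFspRecipe

__all__ = [
    "ok_solver_agreement",
    "ok_exact_interpolation",
    "variogram_estimator_agreement",
    "lognormal_moments_check",
    "variogram_recovery",
    "zscore_calibration",
    "rfsp_vs_ok_comparison",
    "qrf_interval_calibration",
    "residual_decorrelation",
    "caseweight_benefit",
    "metric_identities",
    "multivariate_stacking",
]

warnings.filterwarnings("ignore", message=".*lon/lat degrees.*")


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def ok_solver_agreement(seed: int = 0, n_configs: int = 50) -> dict:
    """Kriging solver vs. an independent dense solve of the augmented
    system, over random small configurations, plus the unit-sum check."""
    rng = np.random.default_rng(seed)
    max_pred_diff = max_var_diff = max_wsum_dev = 0.0
    for _ in range(n_configs):
        n = rng.integers(3, 11)
        coords = rng.uniform(0, 10, (n, 2))
        y = rng.normal(size=n)
        fam = rng.choice(["exponential", "spherical", "gaussian"])
        vgm = VariogramModel(fam, nugget=rng.uniform(0.01, 0.5),
                             psill=rng.uniform(0.3, 2.0),
                             range_param=rng.uniform(0.5, 8.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = PointSet(coords=coords, target=y)
        targets = rng.uniform(-1, 11, (4, 2))
        res = ok_predict(ps, targets, vgm, keep_weights=True)
        # independent dense solve, one target at a time
        C = vgm.covariance(squareform(pdist(coords)))
        for t in range(4):
            c0 = vgm.covariance(cdist(targets[t:t + 1], coords))[0]
            A = np.zeros((n + 1, n + 1))
            A[:n, :n] = C
            A[n, :n] = A[:n, n] = 1.0
            sol = np.linalg.solve(A, np.append(c0, 1.0))
            w, phi = sol[:n], sol[n]
            max_pred_diff = max(max_pred_diff, abs(res.predictions[t] - w @ y))
            var = max(vgm.total_sill - w @ c0 - phi, 0.0)
            max_var_diff = max(max_var_diff, abs(res.variances[t] - var))
            max_wsum_dev = max(max_wsum_dev, abs(res.weights[t].sum() - 1.0))
    return {"max_pred_diff": max_pred_diff, "max_var_diff": max_var_diff,
            "max_weight_sum_dev": max_wsum_dev, "n": n_configs}


def ok_exact_interpolation(seed: int = 0, n: int = 30) -> dict:
    """Zero-nugget OK evaluated at the data locations reproduces them."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 20, (n, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = PointSet(coords=coords, target=rng.normal(size=n))
    vgm = VariogramModel("exponential", nugget=0.0, psill=1.0, range_param=5.0)
    res = ok_predict(ps, coords, vgm)
    return {"max_abs_diff": float(np.max(np.abs(res.predictions - ps.target))),
            "max_variance": float(res.variances.max()), "n": n}


def variogram_estimator_agreement(seed: int = 0, n: int = 100) -> dict:
    """Binned estimator vs. an all-pairs double loop (should be exact)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 50, (n, 2))
    y = rng.normal(size=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = PointSet(coords=coords, target=y)
    emp = empirical_variogram(ps, n_bins=12)
    edges = np.linspace(0, emp.max_dist, emp.n_bins + 1)
    sums = np.zeros(emp.n_bins)
    counts = np.zeros(emp.n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d == 0 or d > emp.max_dist:
                continue
            b = min(max(int(np.searchsorted(edges, d, side="left")) - 1, 0),
                    emp.n_bins - 1)
            sums[b] += (y[i] - y[j]) ** 2
            counts[b] += 1
    nz = counts > 0
    max_dev = float(np.max(np.abs(emp.gamma_hat[nz] - sums[nz] / (2 * counts[nz]))))
    count_dev = int(np.abs(emp.pair_counts - counts).max())
    return {"max_gamma_dev": max_dev, "max_count_dev": count_dev, "n": n}


def lognormal_moments_check(seed: int = 0, n_draws: int = 10**6) -> dict:
    """Back-transform vs. closed-form lognormal moments and Monte Carlo."""
    rng = np.random.default_rng(seed)
    mu, s2 = 0.3, 0.25
    mean, var = lognormal_backtransform(mu, s2)
    cf_mean = np.exp(mu + s2 / 2)
    cf_var = np.exp(2 * mu + s2) * (np.exp(s2) - 1)
    draws = np.exp(rng.normal(mu, np.sqrt(s2), n_draws))
    return {
        "closed_form_mean_rel_err": abs(mean - cf_mean) / cf_mean,
        "closed_form_var_rel_err": abs(var - cf_var) / cf_var,
        "mc_mean_rel_err": abs(mean - draws.mean()) / draws.mean(),
        "mc_var_rel_err": abs(var - draws.var()) / draws.var(),
        "n": n_draws,
    }


def variogram_recovery(seed: int = 0, n_fields: int = 20, n: int = 300) -> dict:
    """WLS fit on simulated exponential fields: median relative errors of
    the range parameter and the total sill."""
    true = VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=10.0)
    seeds = _spawn(seed, n_fields)
    range_err, sill_err = [], []
    rng = np.random.default_rng(seed)
    for s in seeds:
        coords = rng.uniform(0, 100, (n, 2))
        y = simulate_grf_at(coords, true, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = PointSet(coords=coords, target=y)
            fit = fit_variogram(empirical_variogram(ps), family="exponential")
        range_err.append(abs(fit.range_param - true.range_param) / true.range_param)
        sill_err.append(abs(fit.total_sill - true.total_sill) / true.total_sill)
    return {"median_range_rel_err": float(np.median(range_err)),
            "median_sill_rel_err": float(np.median(sill_err)), "n": n_fields}


def zscore_calibration(seed: int = 0, n_reps: int = 10, n: int = 150) -> dict:
    """OK with the TRUE variogram under fivefold CV on simulated fields:
    z-scores should have mean ~0 and variance ~1; doubling the reported
    error SD must quarter the z variance."""
    true = VariogramModel("exponential", nugget=0.2, psill=1.0, range_param=10.0)
    seeds = _spawn(seed, n_reps)
    rng = np.random.default_rng(seed)
    z_means, z_vars, z_vars_doubled = [], [], []
    for s in seeds:
        coords = rng.uniform(0, 50, (n, 2))
        y = simulate_grf_at(coords, true, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = PointSet(coords=coords, target=y)
            rep = evalcv.cross_validate(OKRecipe(vgm=true), ps, None, k=5,
                                        seed=s, diagnostics=False)
            rep2 = evalcv.cross_validate(OKRecipe(vgm=true, sigma_scale=2.0),
                                         ps, None, k=5, seed=s, diagnostics=False)
        z_means.append(rep.metrics["z_mean"])
        z_vars.append(rep.metrics["z_var"])
        z_vars_doubled.append(rep2.metrics["z_var"])
    return {"z_mean": float(np.mean(z_means)), "z_var": float(np.mean(z_vars)),
            "z_var_doubled_sigma": float(np.mean(z_vars_doubled)), "n": n_reps}


def _grf_sample(grid, vgm, n, seed, noise_sd=0.0):
    field = simulate_grf(FieldSpec(grid=grid, vgm=vgm, seed=seed))
    locs = sample_design(grid, n, seed=seed + 1)
    ps = make_dataset(field, locs, noise_sd=noise_sd, seed=seed + 2)
    return field, ps


def rfsp_vs_ok_comparison(seed: int = 0, n: int = 150, num_trees: int = 300) -> dict:
    """Head-to-head on one field: correlation of the two prediction maps
    and the ratio of cross-validated RMSEs (forest over kriging)."""
    grid = GridSpec(origin=(0.0, 40.0), cell_size=1.0, nrows=40, ncols=40)
    vgm = VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=8.0)
    field, ps = _grf_sample(grid, vgm, n, seed * 10 + 1)

    X, Y = grid.cell_centers()
    cells = np.column_stack([X.ravel(), Y.ravel()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ok_recipe = OKRecipe()
        ok_model = ok_recipe.fit(ps, None)
        ok_map, _ = ok_recipe.predict(ok_model, cells)

        rf_recipe = RFspRecipe(
            params=forest.ForestParams(num_trees=num_trees, seed=seed), grid=grid)
        rf_model = rf_recipe.fit(ps, None)
        rf_map, _ = rf_recipe.predict(rf_model, cells)

        rep_ok = evalcv.cross_validate(ok_recipe, ps, None, k=5, seed=seed,
                                       diagnostics=False)
        rep_rf = evalcv.cross_validate(rf_recipe, ps, None, k=5, seed=seed,
                                       diagnostics=False)
    return {
        "map_correlation": float(np.corrcoef(ok_map, rf_map)[0, 1]),
        "rmse_ratio": rep_rf.metrics["rmse"] / rep_ok.metrics["rmse"],
        "rmse_ok": rep_ok.metrics["rmse"],
        "rmse_rfsp": rep_rf.metrics["rmse"],
        "n": n,
    }


def qrf_interval_calibration(seed: int = 0, n_train: int = 200,
                             n_test: int = 500, num_trees: int = 300) -> dict:
    """Coverage of forest prediction intervals on held-out locations of the
    same field, plus monotonicity of coverage in the nominal level."""
    grid = GridSpec(origin=(0.0, 40.0), cell_size=1.0, nrows=40, ncols=40)
    vgm = VariogramModel("exponential", nugget=0.25, psill=1.0, range_param=8.0)
    field = simulate_grf(FieldSpec(grid=grid, vgm=vgm, seed=seed * 10 + 3))
    locs_tr = sample_design(grid, n_train, seed=seed * 10 + 4)
    locs_te = sample_design(grid, n_test, seed=seed * 10 + 5)
    ps_tr = make_dataset(field, locs_tr, seed=seed * 10 + 6)
    ps_te = make_dataset(field, locs_te, seed=seed * 10 + 7)

    recipe = RFspRecipe(params=forest.ForestParams(num_trees=num_trees, seed=seed),
                        grid=grid)
    levels = (0.1, 0.3, 0.5, 0.7, 0.9)
    qs = sorted({(1 - L) / 2 for L in levels} | {(1 + L) / 2 for L in levels})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = recipe.fit(ps_tr, None)
        qpred = recipe.predict_quantiles(model, ps_te.coords, qs)
    cov = evalcv.coverage_table(ps_te.target.astype(float), qpred,
                                nominal_levels=levels)
    cov_seq = [cov[L] for L in levels]
    return {
        "coverage_90": cov[0.9],
        "coverage_50": cov[0.5],
        "coverage_monotone": bool(np.all(np.diff(cov_seq) >= 0)),
        "n": n_test,
    }


def residual_decorrelation(seed: int = 0, n_reps: int = 20, n: int = 250,
                           num_trees: int = 150) -> dict:
    """Fraction of replicates whose CV residuals show no remaining spatial
    structure (structured fraction < 0.2), for kriging and for the forest
    on well-specified fields."""
    grid = GridSpec(origin=(0.0, 40.0), cell_size=1.0, nrows=40, ncols=40)
    vgm = VariogramModel("exponential", nugget=0.2, psill=1.0, range_param=8.0)
    seeds = _spawn(seed, n_reps)
    hits_ok = hits_rf = 0
    for k, s in enumerate(seeds):
        field, ps = _grf_sample(grid, vgm, n, s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_ok = evalcv.cross_validate(OKRecipe(), ps, None, k=5, seed=s)
            rf = RFspRecipe(params=forest.ForestParams(num_trees=num_trees, seed=s),
                            grid=grid, mtry_fraction=0.85)
            rep_rf = evalcv.cross_validate(rf, ps, None, k=5, seed=s)
        hits_ok += rep_ok.structure_fraction < 0.2
        hits_rf += rep_rf.structure_fraction < 0.2
    return {"ok_hits": int(hits_ok), "rfsp_hits": int(hits_rf), "n": n_reps}


def caseweight_benefit(seed: int = 0, n_reps: int = 20, n: int = 200,
                       num_trees: int = 150) -> dict:
    """Two measurement sources with noise SD ratio 3: does weighting the
    bootstrap by inverse error variance beat the unweighted forest against
    the noise-free truth?"""
    grid = GridSpec(origin=(0.0, 30.0), cell_size=1.0, nrows=30, ncols=30)
    vgm = VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=6.0)
    seeds = _spawn(seed, n_reps)
    wins = 0
    for s in seeds:
        field = simulate_grf(FieldSpec(grid=grid, vgm=vgm, seed=s))
        locs = sample_design(grid, n, seed=s + 1)
        # a small accurate source (lab-grade, noise var ~0.15 sill) and a
        # large noisy one (field-estimate-grade, noise var above the sill);
        # weighting only matters when the poor source's error is material
        # relative to the field's own variability
        ps = make_dataset(field, locs, noise_sd=[0.4, 1.2],
                          source_fractions=[0.25, 0.75], seed=s + 2)
        truth = field.layers["field"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bd = geocov.buffer_distances(ps, grid)
            design, w = forest.build_design(ps, bd.stack)
            X0 = bd.stack.table()
            m_w = forest.fit_forest(design, forest.ForestParams(
                num_trees=num_trees, seed=s, case_weights=w))
            m_u = forest.fit_forest(design, forest.ForestParams(
                num_trees=num_trees, seed=s))
            pred_w = forest.predict_mean(m_w, X0)
            pred_u = forest.predict_mean(m_u, X0)
        rmse_w = np.sqrt(np.mean((pred_w - truth.ravel()) ** 2))
        rmse_u = np.sqrt(np.mean((pred_u - truth.ravel()) ** 2))
        wins += rmse_w < rmse_u
    return {"weighted_wins": int(wins), "win_fraction": wins / n_reps, "n": n_reps}


def metric_identities(seed: int = 0, n_vectors: int = 50) -> dict:
    """Metric battery vs. direct formula evaluation on random vectors, the
    unit-shift concordance value, and the CCC <= |rho| bound."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    ccc_bound_ok = True
    for _ in range(n_vectors):
        y = rng.normal(rng.normal(), abs(rng.normal()) + 0.5, size=60)
        yh = 0.6 * y + rng.normal(size=60) + rng.normal()
        m = evalcv.compute_metrics(y, yh)
        err = yh - y
        direct = {
            "rmse": np.sqrt(np.mean(err**2)),
            "me": np.mean(err),
            "r2": 1 - np.sum(err**2) / np.sum((y - y.mean()) ** 2),
            "rho": np.corrcoef(y, yh)[0, 1],
        }
        direct["ccc"] = (2 * direct["rho"] * y.std() * yh.std()
                         / (y.std() ** 2 + yh.std() ** 2
                            + (yh.mean() - y.mean()) ** 2))
        for k, v in direct.items():
            max_dev = max(max_dev, abs(m[k] - v))
        ccc_bound_ok &= abs(m["ccc"]) <= abs(m["rho"]) + 1e-12
    y = rng.normal(size=100000)
    y = (y - y.mean()) / y.std()
    ccc_shift = evalcv.compute_metrics(y, y + 1.0)["ccc"]
    return {"max_formula_dev": max_dev, "ccc_unit_shift": float(ccc_shift),
            "ccc_bound_holds": bool(ccc_bound_ok), "n": n_vectors}


def multivariate_stacking(seed: int = 0, n: int = 120, num_trees: int = 200,
                          n_reps: int = 3) -> dict:
    """One stacked two-variable model vs. separate per-variable models:
    held-out R^2 gap per variable type, averaged over field realizations.

    The two fields share a dominant common spatial component (correlation
    ~0.8, emulating strongly cross-correlated element pairs in
    multi-element surveys, where a single stacked model is attractive)."""
    grid = GridSpec(origin=(0.0, 30.0), cell_size=1.0, nrows=30, ncols=30)
    vgm_common = VariogramModel("exponential", nugget=0.0, psill=0.85, range_param=8.0)
    vgm_indiv = VariogramModel("exponential", nugget=0.02, psill=0.2, range_param=5.0)

    from rfsp.geodata import overlay

    gaps, r2_stacked, r2_single = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            base = seed * 1000 + rep * 100
            common = simulate_grf(FieldSpec(grid=grid, vgm=vgm_common, seed=base + 1))
            fa = common.layers["field"] + simulate_grf(
                FieldSpec(grid=grid, vgm=vgm_indiv, seed=base + 2)).layers["field"]
            fb = common.layers["field"] + simulate_grf(
                FieldSpec(grid=grid, vgm=vgm_indiv, seed=base + 3)).layers["field"]

            locs = {t: sample_design(grid, n, seed=base + 10 + k)
                    for k, t in enumerate("AB")}
            test_locs = sample_design(grid, 300, seed=base + 20)
            i, j = grid.cell_index(test_locs[:, 0], test_locs[:, 1])
            truth = {"A": fa[i, j], "B": fb[i, j]}

            def values_at(layer, locs_):
                ii, jj = grid.cell_index(locs_[:, 0], locs_[:, 1])
                return layer[ii, jj]

            ps = {t: PointSet(coords=locs[t],
                              target=values_at({"A": fa, "B": fb}[t], locs[t]),
                              type_label=np.full(n, t, dtype=object))
                  for t in "AB"}
            # the union of both samples defines the shared geographic covariates
            anchor = PointSet(coords=np.vstack([locs["A"], locs["B"]]),
                              target=np.zeros(2 * n))
            bd = geocov.buffer_distances(anchor, grid).stack

            design, _ = forest.build_design([ps["A"], ps["B"]], bd,
                                            multivariate=True)
            p = design.shape[1] - 1
            stacked = forest.fit_forest(design, forest.ForestParams(
                num_trees=num_trees, seed=seed, mtry=max(1, round(0.85 * p))))

            test_ps = PointSet(coords=test_locs, target=np.zeros(300))
            X_test = overlay(test_ps, bd)
            for t in "AB":
                X0 = X_test.copy()
                for c in stacked.covariate_names:
                    if c.startswith("TYPE_"):
                        X0[c] = 1.0 if c == f"TYPE_{t}" else 0.0
                    elif c.startswith("METHOD_"):
                        X0[c] = 1.0
                pred_stacked = forest.predict_mean(stacked, X0)

                design_t, _ = forest.build_design(
                    PointSet(coords=ps[t].coords, target=ps[t].target), bd)
                single = forest.fit_forest(design_t, forest.ForestParams(
                    num_trees=num_trees, seed=seed))
                pred_single = forest.predict_mean(single, X_test)

                r2_s = evalcv.compute_metrics(truth[t], pred_stacked)["r2"]
                r2_i = evalcv.compute_metrics(truth[t], pred_single)["r2"]
                gaps.append(abs(r2_i - r2_s))
                r2_stacked.append(r2_s)
                r2_single.append(r2_i)
    return {
        "mean_r2_gap": float(np.mean(gaps)),
        "mean_r2_stacked": float(np.mean(r2_stacked)),
        "mean_r2_single": float(np.mean(r2_single)),
        "n": n_reps,
    }
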