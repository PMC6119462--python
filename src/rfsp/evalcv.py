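"""Model-performance battery: k-fold cross-validation with refitting,
accuracy metrics, uncertainty calibration, residual diagnostics, and
error-guided second-stage sampling.

Four complementary questions are asked of every spatial predictor:

* accuracy — RMSE, mean error (bias, predicted minus observed), R^2 and
  Lin's concordance correlation coefficient (agreement with the 1:1 line,
  penalizing both imprecision and bias);
* reliability of the error model — z-scores (held-out error divided by
  predicted SD) should have mean 0 and variance 1, and symmetric
  prediction intervals should cover at their nominal rates ("accuracy
  plots");
* local spatial bias — the variogram of cross-validation residuals should
  be structureless (pure nugget) if the predictor has absorbed the
  spatial correlation;
* where to sample next — allocate second-stage samples where the
  prediction-error map is highest.

Cross-validation refits everything per fold, including variograms and any
buffer-distance layers, which are rebuilt from training-fold points only —
held-out points never contribute covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import CovariateStack, InputError, PointSet
from .krige import (
    EmpiricalVariogram,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
)

__all__ = [
    "CVReport",
    "kfold_split",
    "cross_validate",
    "compute_metrics",
    "zscore_stats",
    "coverage_table",
    "residual_autocorrelation",
    "propose_second_stage",
    "DEFAULT_COVERAGE_LEVELS",
]

DEFAULT_COVERAGE_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.6827, 0.7, 0.8, 0.9, 0.95)


@dataclass
class CVReport:
    """Per-point held-out predictions plus the full metric battery."""

    fold_of: np.ndarray
    y_obs: np.ndarray
    y_hat: np.ndarray
    sigma_hat: np.ndarray | None
    metrics: dict[str, float]
    coverage: dict[float, float] = field(default_factory=dict)
    residual_vgm: VariogramModel | None = None
    structure_fraction: float | None = None

    def per_point(self) -> pd.DataFrame:
        cols = {"fold": self.fold_of, "y_obs": self.y_obs, "y_hat": self.y_hat}
        if self.sigma_hat is not None:
            cols["sigma_hat"] = self.sigma_hat
        return pd.DataFrame(cols)

    def to_json(self, path=None) -> str:
        doc = {
            "metrics": {k: None if v is None or not np.isfinite(v) else float(v)
                        for k, v in self.metrics.items()},
            "coverage": {str(k): float(v) for k, v in self.coverage.items()},
            "structure_fraction": self.structure_fraction,
            "residual_vgm": None if self.residual_vgm is None
            else json.loads(self.residual_vgm.to_json()),
            "n": int(len(self.y_obs)),
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def kfold_split(n: int, k: int, seed: int = 0, strata=None) -> np.ndarray:
    """Random fold assignment: sizes differ by <= 1, stratified if labels
    are given (each class spread across folds as evenly as possible),
    deterministic per seed."""
    if not (2 <= k <= n):
        raise InputError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        if strata.shape != (n,):
            raise InputError("strata length must equal n")
        groups = [np.where(strata == c)[0] for c in pd.unique(strata)]
    # deal fold ids round-robin, continuing the deal across strata so
    # overall fold sizes stay balanced too
    start = 0
    for g in groups:
        g = rng.permutation(g)
        fold_of[g] = (start + np.arange(len(g))) % k
        start += len(g)
    return fold_of


def compute_metrics(y_obs, y_hat) -> dict[str, float]:
    """RMSE, ME (predicted minus observed), R^2 = 1 - SSE/SST, Lin's CCC,
    and Pearson rho.

    SST is taken about the observed mean of the validation points.  With
    zero variance in y_obs, R^2/CCC/rho are undefined and reported as NaN
    with a warning.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_obs.shape != y_hat.shape or y_obs.ndim != 1 or len(y_obs) < 2:
        raise InputError("y_obs and y_hat must be equal-length vectors, n >= 2")
    err = y_hat - y_obs
    rmse = float(np.sqrt(np.mean(err**2)))
    me = float(np.mean(err))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero variance in observations; R2/CCC/rho undefined")
        return {"rmse": rmse, "me": me, "r2": np.nan, "ccc": np.nan, "rho": np.nan}
    r2 = 1.0 - float(np.sum(err**2)) / sst
    s_o = y_obs.std()
    s_h = y_hat.std()
    if s_h == 0:
        rho = 0.0
    else:
        rho = float(np.corrcoef(y_obs, y_hat)[0, 1])
    ccc = (2.0 * rho * s_h * s_o) / (s_h**2 + s_o**2 + (y_hat.mean() - y_obs.mean()) ** 2)
    return {"rmse": rmse, "me": me, "r2": float(r2), "ccc": float(ccc), "rho": rho}


def zscore_stats(y_obs, y_hat, sigma_hat) -> dict[str, float]:
    """Calibration of the error model: z = (y_hat - y_obs)/sigma_hat.

    Well-calibrated predictors give mean(z) ~ 0 and var(z) ~ 1; var(z)
    substantially below 1 means uncertainty is overestimated, above 1
    underestimated.  Points with sigma_hat = 0 are excluded and counted.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    if np.any(sigma_hat < 0):
        raise InputError("sigma_hat must be >= 0")
    ok = sigma_hat > 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise InputError("all sigma_hat are zero; z-scores undefined")
    z = (y_hat[ok] - y_obs[ok]) / sigma_hat[ok]
    return {
        "z_mean": float(z.mean()),
        "z_var": float(z.var()),
        "n_excluded": n_excluded,
    }


def coverage_table(y_obs, quantile_predictions: dict[float, np.ndarray],
                   nominal_levels=DEFAULT_COVERAGE_LEVELS) -> dict[float, float]:
    """Empirical coverage of symmetric prediction intervals.

    For nominal level L the interval is [q_(1-L)/2, q_(1+L)/2]; coverage
    is the fraction of observations inside.  The required quantiles must
    be present in quantile_predictions (keys matched to 1e-9).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    keys = np.array(sorted(quantile_predictions))

    def get(q):
        hit = np.nonzero(np.abs(keys - q) < 1e-9)[0]
        if len(hit) == 0:
            raise InputError(f"quantile {q:.5g} missing from predictions")
        return np.asarray(quantile_predictions[keys[hit[0]]], dtype=float)

    out: dict[float, float] = {}
    for L in nominal_levels:
        lo = get((1.0 - L) / 2.0)
        hi = get((1.0 + L) / 2.0)
        out[float(L)] = float(np.mean((y_obs >= lo) & (y_obs <= hi)))
    return out


def residual_autocorrelation(
    ps: PointSet,
    n_bins: int = 12,
    min_points: int = 30,
    threshold: float = 0.2,
    family: str = "exponential",
) -> dict:
    """Spatial structure left in CV residuals.

    Fits a variogram to the residuals and reports the structured fraction
    of the variance expressed across the observed lags,
    psill (1 - rho(h_max)) / gamma(h_max); below ``threshold`` the verdict
    is "no residual autocorrelation" — the predictor has absorbed the
    spatial signal.  (The raw psill/(nugget+psill) ratio is not used: it
    is unidentifiable when the fitted range escapes the observed lag
    span.)
    """
    if ps.n < min_points:
        raise InputError(f"need >= {min_points} residuals, got {ps.n}")
    emp = empirical_variogram(ps, n_bins=n_bins)
    vgm = fit_variogram(emp, family=family)
    lags, _, _ = emp.populated()
    frac = (vgm.structured_fraction(float(lags.max()), float(lags.min()))
            if len(lags) else 0.0)
    verdict = ("no residual autocorrelation" if frac < threshold
               else "residual spatial structure present")
    return {"residual_vgm": vgm, "structure_fraction": float(frac),
            "verdict": verdict, "empirical": emp}


def propose_second_stage(
    error_map: CovariateStack,
    n_new: int,
    min_spacing: float,
    layer: str = "sigma",
) -> np.ndarray:
    """Greedy error-guided sampling: pick the n_new highest-sigma cells
    subject to pairwise spacing >= min_spacing (ties broken row-major).

    First-stage samples fix the model; the error map then steers where
    additional observations buy the most accuracy.  If spacing makes
    n_new infeasible, the maximal feasible set is returned with a
    warning.
    """
    if n_new < 1:
        raise InputError("n_new must be >= 1")
    sig = error_map.layers[layer]
    grid = error_map.grid
    X, Y = grid.cell_centers()
    flat = np.column_stack([X.ravel(), Y.ravel()])
    vals = np.where(error_map.mask, sig, -np.inf).ravel()
    # stable sort descending on value, row-major tie-break
    order = np.lexsort((np.arange(len(vals)), -vals))
    chosen: list[int] = []
    for idx in order:
        if not np.isfinite(vals[idx]):
            break
        c = flat[idx]
        if all(np.hypot(*(c - flat[j])) >= min_spacing for j in chosen):
            chosen.append(idx)
            if len(chosen) == n_new:
                break
    if len(chosen) < n_new:
        warnings.warn(
            f"only {len(chosen)} locations satisfy spacing {min_spacing}; "
            f"requested {n_new}"
        )
    return flat[chosen]


# ---------------------------------------------------------------------------
# cross-validation driver

def cross_validate(
    method,
    ps: PointSet,
    stacks: list[CovariateStack] | CovariateStack | None = None,
    k: int = 5,
    seed: int = 0,
    strata=None,
    diagnostics: bool = True,
) -> CVReport:
    """k-fold CV with refitting: per fold the method's entire pipeline —
    variogram or forest AND any training-point-derived covariates such as
    buffer distances — is rebuilt on the training folds only, then the
    held-out points are predicted with an error SD.

    ``method`` is a recipe object with
    ``fit(ps_train, stacks) -> model`` and
    ``predict(model, coords) -> (y_hat, sigma_hat)`` (see
    :mod:`rfsp.workbench` for the OK / RK / RFsp recipes); it may also
    expose ``predict_quantiles(model, coords, qs) -> dict`` to enable the
    coverage table.
    """
    if ps.is_categorical:
        raise InputError("cross_validate needs a numeric target")
    if isinstance(stacks, CovariateStack):
        stacks = [stacks]
    fold_of = kfold_split(ps.n, k, seed=seed, strata=strata)
    y_hat = np.full(ps.n, np.nan)
    sigma_hat = np.full(ps.n, np.nan)
    qpred: dict[float, np.ndarray] = {}
    want_cov = hasattr(method, "predict_quantiles")
    qs_needed = sorted(
        {(1.0 - L) / 2.0 for L in DEFAULT_COVERAGE_LEVELS}
        | {(1.0 + L) / 2.0 for L in DEFAULT_COVERAGE_LEVELS}
    ) if want_cov else []

    for f in range(k):
        test = fold_of == f
        train = ~test
        if train.sum() < 2 or np.unique(ps.target[train].astype(float)).size < 2:
            raise InputError(f"fold {f}: degenerate training data")
        ps_tr = ps.subset(np.where(train)[0])
        try:
            model = method.fit(ps_tr, stacks)
            yh, sh = method.predict(model, ps.coords[test])
        except Exception as exc:
            raise InputError(f"fold {f}: {exc}") from exc
        y_hat[test] = yh
        sigma_hat[test] = sh if sh is not None else np.nan
        if want_cov:
            qd = method.predict_quantiles(model, ps.coords[test], qs_needed)
            for q, v in qd.items():
                qpred.setdefault(q, np.full(ps.n, np.nan))[test] = v

    y_obs = ps.target.astype(float)
    metrics = compute_metrics(y_obs, y_hat)
    have_sigma = np.all(np.isfinite(sigma_hat))
    if have_sigma and np.any(sigma_hat > 0):
        metrics.update({k_: v for k_, v in zscore_stats(y_obs, y_hat, sigma_hat).items()
                        if k_ in ("z_mean", "z_var")})
    coverage = coverage_table(y_obs, qpred) if qpred else {}

    residual_vgm = None
    structure_fraction = None
    if diagnostics and ps.n >= 30:
        res_ps = PointSet(coords=ps.coords, target=y_obs - y_hat, ids=ps.ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag = residual_autocorrelation(res_ps)
        residual_vgm = diag["residual_vgm"]
        structure_fraction = diag["structure_fraction"]

    return CVReport(
        fold_of=fold_of,
        y_obs=y_obs,
        y_hat=y_hat,
        sigma_hat=sigma_hat if have_sigma else None,
        metrics=metrics,
        coverage=coverage,
        residual_vgm=residual_vgm,
        structure_fraction=structure_fraction,
    )


def plot_diagnostics(report: CVReport, path=None):
    """Four-panel CV diagnostic figure: predicted-vs-observed, z-score
    histogram, accuracy (coverage) plot, CV-residual variogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    ax = axes[0, 0]
    ax.scatter(report.y_obs, report.y_hat, s=12, alpha=0.6)
    lims = [min(report.y_obs.min(), report.y_hat.min()),
            max(report.y_obs.max(), report.y_hat.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("observed")
    ax.set_ylabel("predicted")
    ax.set_title(f"RMSE={report.metrics['rmse']:.3g} "
                 f"CCC={report.metrics.get('ccc', float('nan')):.2f}")

    ax = axes[0, 1]
    if report.sigma_hat is not None and np.any(report.sigma_hat > 0):
        ok = report.sigma_hat > 0
        z = (report.y_hat[ok] - report.y_obs[ok]) / report.sigma_hat[ok]
        ax.hist(z, bins=30, density=True)
        ax.set_title(f"z-scores: mean={z.mean():.2f} var={z.var():.2f}")
    ax.set_xlabel("z-score")

    ax = axes[1, 0]
    if report.coverage:
        L = sorted(report.coverage)
        ax.plot(L, [report.coverage[x] for x in L], "o-")
        ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("nominal level")
    ax.set_ylabel("empirical coverage")
    ax.set_title("accuracy plot")

    ax = axes[1, 1]
    if report.residual_vgm is not None:
        v = report.residual_vgm
        h = np.linspace(0, 3 * v.range_param if v.family != "pure-nugget" else 1, 50)
        ax.plot(h, v.semivariance(h))
        ax.set_title(f"residual vgm: structure={report.structure_fraction:.2f}")
    ax.set_xlabel("lag")
    ax.set_ylabel("semivariance")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
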