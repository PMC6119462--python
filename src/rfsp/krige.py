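"""Model-based baselines: MLR trend, variograms, ordinary and regression
kriging, Box-Cox / log-normal transforms.

The variogram decomposes the variance of a spatial field into a nugget
(tau^2, micro-scale plus measurement noise), a partial sill (sigma_p^2,
spatially structured variance) and a range parameter (phi, correlation
length).  Ordinary kriging is the best linear unbiased predictor under a
constant unknown mean: weights come from the covariance model subject to a
unit-sum constraint enforced with a Lagrange multiplier.  Regression
kriging adds an ordinary-least-squares trend on covariates and kriges its
residuals.

The empirical variogram uses the Matheron method-of-moments estimator and
models are fitted by weighted least squares with N(h)/gamma^2 weights —
deterministic and directly checkable, unlike likelihood fitting.  Isotropic
models only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from .geodata import CovariateStack, InputError, PointSet

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "TrendModel",
    "KrigingResult",
    "boxcox",
    "boxcox_inverse",
    "empirical_variogram",
    "fit_variogram",
    "ok_predict",
    "lognormal_backtransform",
    "fit_mlr",
    "predict_mlr",
    "rk_predict",
]

Family = Literal["exponential", "spherical", "gaussian", "pure-nugget"]


# ---------------------------------------------------------------------------
# transforms

def boxcox(y, eta: float):
    """Box-Cox transform: (y^eta - 1)/eta, natural log when eta = 0.

    Requires y > 0.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise InputError("Box-Cox transform requires strictly positive values")
    if eta == 0:
        return np.log(y)
    return (y**eta - 1.0) / eta


def boxcox_inverse(y_t, eta: float):
    """Exact algebraic inverse of :func:`boxcox`."""
    y_t = np.asarray(y_t, dtype=float)
    if eta == 0:
        return np.exp(y_t)
    base = eta * y_t + 1.0
    if np.any(base <= 0):
        raise InputError("inverse Box-Cox undefined: eta*y + 1 must be > 0")
    return base ** (1.0 / eta)


def lognormal_backtransform(yt_hat, var_t):
    """Back-transform log-scale kriging output to the natural scale.

    For a log-normal field, prediction exp(y_T + sigma_T^2/2) and variance
    exp(2 y_T + sigma_T^2) (exp(sigma_T^2) - 1) — the unbiased moments of
    exp(N(y_T, sigma_T^2)).
    """
    yt_hat = np.asarray(yt_hat, dtype=float)
    var_t = np.asarray(var_t, dtype=float)
    if np.any(var_t < 0):
        raise InputError("kriging variance must be >= 0")
    with np.errstate(over="warn"):
        mean = np.exp(yt_hat + 0.5 * var_t)
        var = np.exp(2.0 * yt_hat + var_t) * (np.exp(var_t) - 1.0)
    return mean, var


# ---------------------------------------------------------------------------
# variograms

@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariance estimates.

    gamma_hat[b] = sum over pairs in bin b of (y_i - y_j)^2 / (2 N_b).
    Bins with zero pairs carry NaN and are excluded from fitting.
    """

    lag_centers: np.ndarray
    gamma_hat: np.ndarray
    pair_counts: np.ndarray
    max_dist: float
    n_bins: int

    def populated(self) -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
        ok = self.pair_counts > 0
        return self.lag_centers[ok], self.gamma_hat[ok], self.pair_counts[ok]


def _correlation(family: Family, h: np.ndarray, phi: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if family == "pure-nugget":
        return np.where(h == 0, 1.0, 0.0)
    if phi <= 0:
        raise ValueError("range parameter must be > 0")
    r = h / phi
    if family == "exponential":
        return np.exp(-r)
    if family == "gaussian":
        return np.exp(-(r**2))
    if family == "spherical":
        rho = 1.0 - 1.5 * np.minimum(r, 1.0) + 0.5 * np.minimum(r, 1.0) ** 3
        return np.where(r < 1.0, rho, 0.0)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class VariogramModel:
    """Isotropic variogram/covariance model.

    C(h) = psill * rho(h/range_param) for h > 0, C(0) = nugget + psill;
    gamma(h) = total sill - C(h).  The practical range is the distance at
    which correlation drops to 0.05.
    """

    family: Family
    nugget: float
    psill: float
    range_param: float = 1.0
    eta: float | None = None  # optional Box-Cox parameter carried alongside

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.family != "pure-nugget" and self.range_param <= 0:
            raise ValueError("range_param must be > 0")

    @property
    def total_sill(self) -> float:
        return self.nugget + self.psill

    @property
    def practical_range(self) -> float:
        if self.family == "pure-nugget" or self.psill == 0:
            return 0.0
        if self.family == "exponential":
            return self.range_param * np.log(20.0)
        if self.family == "gaussian":
            return self.range_param * np.sqrt(np.log(20.0))
        # spherical correlation hits exactly 0 at range_param; 0.05 before it
        return brentq(
            lambda h: _correlation("spherical", np.array([h]), self.range_param)[0] - 0.05,
            1e-12 * self.range_param,
            self.range_param,
        )

    def covariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c = self.psill * _correlation(self.family, h, self.range_param or 1.0)
        return np.where(h == 0, self.nugget + self.psill, c)

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return np.where(h == 0, 0.0, self.total_sill - self.covariance(h))

    def structured_fraction(self, h_max: float, h_min: float = 0.0) -> float:
        """Fraction of the variance at scale h_max attributable to spatial
        correlation observable between lags h_min and h_max:
        (gamma(h_max) - gamma(h_min)) / gamma(h_max).

        Unlike the raw psill/(nugget + psill) ratio this stays
        identifiable under the two degeneracies of least-squares fits: a
        range collapsed below the first observed lag (structure
        indistinguishable from nugget there) and a range far beyond the
        last lag (structure never expressed) both correctly score ~0.
        """
        gam_max = float(self.semivariance(np.asarray([h_max]))[0])
        if gam_max <= 0:
            return 0.0
        gam_min = float(self.semivariance(np.asarray([h_min]))[0]) if h_min > 0 else 0.0
        return float(max(gam_max - gam_min, 0.0) / gam_max)

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {"family": self.family, "nugget": self.nugget, "psill": self.psill,
             "range": self.range_param, "eta": self.eta}
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str) -> "VariogramModel":
        d = json.loads(doc)
        return cls(family=d["family"], nugget=d["nugget"], psill=d["psill"],
                   range_param=d["range"], eta=d.get("eta"))


def empirical_variogram(
    ps: PointSet, n_bins: int = 15, max_dist: float | None = None
) -> EmpiricalVariogram:
    """Matheron method-of-moments sample variogram.

    Default max_dist is half the maximum pairwise distance.  Equal-width
    bins on (0, max_dist]; pairs at identical locations (h = 0) are
    excluded (they estimate measurement error, not the variogram).
    """
    if ps.is_categorical or ps.n < 2:
        raise InputError("empirical_variogram needs >= 2 numeric observations")
    d = pdist(ps.coords)
    if np.all(d == 0):
        raise InputError("all points coincide; no variogram is estimable")
    dy2 = pdist(ps.target[:, None], metric="sqeuclidean")
    if max_dist is None:
        max_dist = 0.5 * d.max()
    pos = d > 0
    d, dy2 = d[pos], dy2[pos]
    if np.allclose(d, d[0]):
        warnings.warn("all pair distances identical; returning a single bin")
        n_bins = 1
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    in_range = d <= max_dist
    counts = np.bincount(which[in_range], minlength=n_bins)
    sums = np.bincount(which[in_range], weights=dy2[in_range], minlength=n_bins)
    gamma = np.full(n_bins, np.nan)
    nz = counts > 0
    gamma[nz] = sums[nz] / (2.0 * counts[nz])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        lag_centers=centers, gamma_hat=gamma, pair_counts=counts,
        max_dist=float(max_dist), n_bins=n_bins,
    )


def fit_variogram(
    emp: EmpiricalVariogram,
    family: Family = "exponential",
    initial: tuple[float, float, float] | None = None,
) -> VariogramModel:
    """Weighted-least-squares variogram fit.

    Minimizes sum_h N(h)/gamma_model(h)^2 (gamma_hat(h) - gamma_model(h))^2
    over (nugget, psill, range) with nonnegativity bounds, multi-starting
    from data-driven initials.  Deterministic given inputs.  Falls back to
    a pure-nugget model if every start fails.
    """
    lags, gam, counts = emp.populated()
    if family == "pure-nugget":
        sill = float(np.average(gam, weights=counts))
        return VariogramModel("pure-nugget", nugget=sill, psill=0.0)
    if len(lags) < 3:
        raise InputError("need >= 3 populated bins to fit a 3-parameter model")

    sill0 = float(np.average(gam, weights=counts))
    span = float(lags.max())

    def resid(theta):
        nug, ps_, rng = theta
        m = VariogramModel(family, max(nug, 0.0), max(ps_, 0.0),
                           max(rng, 1e-12)).semivariance(lags)
        m = np.maximum(m, 1e-12 * max(sill0, 1e-300))
        return np.sqrt(counts) / m * (gam - m)

    starts = []
    if initial is not None:
        starts.append(tuple(initial))
    for frac_n in (0.0, 0.25, 0.5):
        for frac_r in (0.1, 0.3, 0.6):
            starts.append((frac_n * sill0, (1 - frac_n) * sill0, frac_r * span))

    best, best_cost = None, np.inf
    for s0 in starts:
        try:
            sol = least_squares(
                resid, x0=np.maximum(s0, [0.0, 1e-10 * sill0, 1e-6 * span]),
                bounds=([0.0, 0.0, 1e-9 * span], [np.inf, np.inf, 100 * span]),
                method="trf", max_nfev=2000,
            )
        except Exception:  # singular jacobian etc. on a bad start
            continue
        if sol.cost < best_cost and np.all(np.isfinite(sol.x)):
            best, best_cost = sol.x, sol.cost
    if best is None:
        warnings.warn("variogram optimization failed on all starts; "
                      "falling back to pure nugget")
        return VariogramModel("pure-nugget", nugget=sill0, psill=0.0)
    nug, ps_, rng = best
    # structure with a range below the first observed lag is unresolvable:
    # it behaves exactly like nugget at the data's resolution, so report it
    # as nugget rather than as spurious spatial structure
    if rng < 0.5 * lags.min():
        nug, ps_, rng = nug + ps_, 0.0, float(lags.min())
    return VariogramModel(family, nugget=float(nug), psill=float(ps_),
                          range_param=float(rng))


# ---------------------------------------------------------------------------
# ordinary kriging

@dataclass
class KrigingResult:
    """Predictions, variances and (optionally) the kriging weights."""

    predictions: np.ndarray
    variances: np.ndarray
    weights: np.ndarray | None = None       # (n_targets, n_obs)
    lagrange: np.ndarray | None = None      # (n_targets,)


def ok_predict(
    ps: PointSet,
    targets: np.ndarray,
    vgm: VariogramModel,
    n_neighbors: int | None = None,
    keep_weights: bool = False,
) -> KrigingResult:
    """Ordinary kriging with variance at target locations.

    Per target s0 solves [[C, 1],[1^T, 0]] [w, phi] = [C0, 1]; prediction
    w^T y, variance C(0) - w^T C0 - phi.  Global neighborhood by default;
    n_neighbors switches to the nearest-m subset per target.
    """
    if ps.is_categorical:
        raise InputError("ok_predict needs a numeric target")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    dup = ps.duplicate_mask()
    if dup.any() and vgm.nugget == 0:
        bad = [str(i) for i in ps.ids[dup]]
        raise InputError(
            f"duplicate coordinates with zero nugget make the kriging system "
            f"singular (points {bad}); add a nugget or deduplicate"
        )
    if n_neighbors is not None and n_neighbors < ps.n:
        return _ok_local(ps, targets, vgm, n_neighbors, keep_weights)

    n = ps.n
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vgm.covariance(squareform(pdist(ps.coords)))
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    d0 = cdist(targets, ps.coords)
    B = np.empty((n + 1, targets.shape[0]))
    B[:n] = vgm.covariance(d0).T
    B[n] = 1.0
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise InputError(f"kriging system is singular: {exc}") from exc
    w, phi = sol[:n], sol[n]
    pred = w.T @ ps.target
    var = vgm.total_sill - np.einsum("ij,ij->j", w, B[:n]) - phi
    var = np.maximum(var, 0.0)  # clip tiny negative round-off
    return KrigingResult(
        predictions=pred, variances=var,
        weights=w.T if keep_weights else None,
        lagrange=phi if keep_weights else None,
    )


def _ok_local(ps, targets, vgm, m, keep_weights):
    """Nearest-m-neighborhood OK, one small solve per target."""
    d0 = cdist(targets, ps.coords)
    preds = np.empty(targets.shape[0])
    vars_ = np.empty(targets.shape[0])
    W = np.full((targets.shape[0], ps.n), np.nan) if keep_weights else None
    phis = np.empty(targets.shape[0]) if keep_weights else None
    for t in range(targets.shape[0]):
        idx = np.argsort(d0[t])[:m]
        sub = ps.subset(idx)
        res = ok_predict(sub, targets[t:t + 1], vgm, keep_weights=keep_weights)
        preds[t] = res.predictions[0]
        vars_[t] = res.variances[0]
        if keep_weights:
            W[t, idx] = res.weights[0]
            phis[t] = res.lagrange[0]
    return KrigingResult(predictions=preds, variances=vars_, weights=W, lagrange=phis)


# ---------------------------------------------------------------------------
# trend + regression kriging

@dataclass
class TrendModel:
    """OLS trend fit with the classical prediction-variance bookkeeping."""

    beta: np.ndarray
    mse: float
    p: int
    columns: list[str] = field(default_factory=list)
    xtx_inv: np.ndarray | None = None
    kept: np.ndarray | None = None  # columns retained after rank filtering


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_mlr(X: np.ndarray, y: np.ndarray, columns: list[str] | None = None) -> TrendModel:
    """Ordinary-least-squares trend: beta = (X^T X)^-1 X^T y, with intercept.

    Rank-deficient designs drop the dependent columns with a warning.
    n <= p is a hard error — the forest side of the package is the tool
    for wide designs.
    """
    Xd = _design(X)
    y = np.asarray(y, dtype=float)
    n, p = Xd.shape
    if n <= p:
        raise InputError(
            f"n={n} <= p={p}: OLS is underdetermined; use the rfsp forest, "
            "which tolerates more covariates than observations"
        )
    kept = np.ones(p, dtype=bool)
    rank = np.linalg.matrix_rank(Xd)
    if rank < p:
        # greedy drop of trailing dependent columns
        for j in range(p - 1, 0, -1):
            trial = kept.copy()
            trial[j] = False
            if np.linalg.matrix_rank(Xd[:, trial]) == rank:
                kept = trial
            if kept.sum() == rank:
                break
        warnings.warn(f"design rank-deficient; dropped {int((~kept).sum())} columns")
    Xk = Xd[:, kept]
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    beta = xtx_inv @ Xk.T @ y
    resid = y - Xk @ beta
    dof = n - Xk.shape[1]
    mse = float(resid @ resid / dof) if dof > 0 else 0.0
    return TrendModel(
        beta=beta, mse=mse, p=int(kept.sum()),
        columns=columns or [f"x{j}" for j in range(p - 1)],
        xtx_inv=xtx_inv, kept=kept,
    )


def predict_mlr(tm: TrendModel, X0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trend prediction with variance MSE * (1 + x0^T (X^T X)^-1 x0).

    The variance is smallest where covariates sit at the center of the
    training feature space and grows with leverage (extrapolation).
    """
    X0d = _design(X0)[:, tm.kept]
    pred = X0d @ tm.beta
    lev = np.einsum("ij,jk,ik->i", X0d, tm.xtx_inv, X0d)
    return pred, tm.mse * (1.0 + lev)


def rk_predict(
    ps: PointSet,
    stack: CovariateStack,
    targets: np.ndarray,
    family: Family = "exponential",
    n_bins: int = 15,
    eta: float | None = None,
    vgm: VariogramModel | None = None,
) -> KrigingResult:
    """Regression kriging: OLS trend on overlaid covariates + OK of residuals.

    Steps: overlay covariates -> fit MLR -> residuals -> residual variogram
    (WLS fit, unless a model is supplied) -> trend prediction at targets ->
    OK of residuals -> sum.  Variance adds the trend and residual-kriging
    components without their cross-term (an approximation; the integrated
    universal-kriging solver is out of scope).  With eta set, the target is
    Box-Cox transformed first and predictions are back-transformed
    (log-normal moments when eta = 0, plug-in inverse otherwise).
    """
    from .geodata import overlay  # local import to avoid cycle at module load

    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    Xdf = overlay(ps, stack)
    good = ~Xdf.isna().any(axis=1).to_numpy()
    if not good.all():
        ps = ps.subset(np.where(good)[0])
        Xdf = Xdf[good]
    y = ps.target.astype(float)
    if eta is not None:
        y = boxcox(y, eta)

    tm = fit_mlr(Xdf.to_numpy(), y, columns=list(Xdf.columns))
    Xk = _design(Xdf.to_numpy())[:, tm.kept]
    resid = y - Xk @ tm.beta

    res_ps = PointSet(coords=ps.coords, target=resid, ids=ps.ids)
    if vgm is None:
        emp = empirical_variogram(res_ps, n_bins=n_bins)
        vgm = fit_variogram(emp, family=family)

    i, j = stack.grid.cell_index(targets[:, 0], targets[:, 1])
    if np.any(i < 0):
        raise InputError("target locations outside the covariate grid")
    X0 = np.column_stack([stack.layers[k][i, j] for k in stack.layers])
    trend_pred, trend_var = predict_mlr(tm, X0)
    okr = ok_predict(res_ps, targets, vgm)
    pred_t = trend_pred + okr.predictions
    var_t = trend_var + okr.variances
    if eta is None:
        return KrigingResult(predictions=pred_t, variances=var_t)
    if eta == 0:
        mean, var = lognormal_backtransform(pred_t, var_t)
        return KrigingResult(predictions=mean, variances=var)
    return KrigingResult(predictions=boxcox_inverse(pred_t, eta), variances=var_t)
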