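"""RFsp core: tree ensembles on geographic + thematic covariates, with
quantile-regression-forest uncertainty.

The model is Y(s) = f(X_G, X_R, X_P): a random forest whose covariates
include buffer-distance layers (X_G), so that geographical proximity enters
the model the way the variogram does in kriging.  Fitted only on X_G the
predictions resemble ordinary kriging; with thematic covariates added they
resemble regression kriging.

Individual base learners are scikit-learn decision trees; the ensemble —
case-weighted bootstrap, out-of-bag statistics, and the quantile machinery —
is implemented here because it needs explicit bootstrap and leaf
bookkeeping.  A forest prediction is a weighted linear combination of the
training observations, y_hat(s0) = sum_i alpha_i(s0) y(s_i); replacing y_i
by the indicator 1{y_i <= t} in the same combination gives the conditional
CDF estimate F_hat(t) whose inversion yields per-location quantiles,
prediction intervals, and a prediction-error map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .geocov import TemporalCovariates
from .geodata import CovariateStack, InputError, PointSet, overlay

__all__ = [
    "ForestParams",
    "RFspModel",
    "QuantilePrediction",
    "build_design",
    "fit_forest",
    "predict_mean",
    "predict_quantiles",
    "sigma_from_interval",
    "predict_probabilities",
    "predict_multivariate",
    "predict_surface",
]

TARGET_COL = "target"


@dataclass
class ForestParams:
    """Tuning parameters of the ensemble.

    mtry is the number of candidate covariates per split (None resolves to
    max(1, p//3) for regression and floor(sqrt(p)) for probability at fit
    time); min_node_size the minimal terminal node size; sample_fraction
    the bootstrap fraction (drawn with replacement); case_weights optional
    per-observation sampling probabilities (weight-0 observations never
    enter any bootstrap draw).  When one or two covariates dominate — e.g.
    temporal axes in spatiotemporal models — keep mtry high (> p/2) so they
    are not systematically missed at split selection.
    """

    num_trees: int = 500
    mtry: int | None = None
    min_node_size: int | None = None
    sample_fraction: float = 1.0
    case_weights: np.ndarray | None = None
    seed: int = 0
    task: str = "regression"  # regression | probability

    def validate(self, n: int, p: int) -> None:
        if self.num_trees < 1:
            raise InputError("num_trees must be >= 1")
        if self.mtry is not None and not (1 <= self.mtry <= p):
            raise InputError(f"mtry must be in [1, {p}]")
        if not (0 < self.sample_fraction <= 1):
            raise InputError("sample_fraction must be in (0, 1]")
        if self.task not in ("regression", "probability"):
            raise InputError(f"unknown task {self.task!r}")
        if self.case_weights is not None:
            w = np.asarray(self.case_weights, dtype=float)
            if w.shape != (n,):
                raise InputError("case_weights length must match observations")
            if np.any(w < 0) or not np.any(w > 0):
                raise InputError("case_weights must be >= 0 with at least one > 0")

    def resolved_mtry(self, p: int) -> int:
        if self.mtry is not None:
            return self.mtry
        return max(1, p // 3) if self.task == "regression" else max(1, int(np.sqrt(p)))

    def resolved_min_node(self) -> int:
        if self.min_node_size is not None:
            return self.min_node_size
        return 5 if self.task == "regression" else 10


@dataclass
class RFspModel:
    """Fitted ensemble with the bookkeeping QRF and OOB statistics need.

    inbag_idx[b] holds the training indices drawn (with multiplicity) for
    tree b; inbag_leaves[b] the terminal node of each such draw.  The
    ensemble prediction is the average of per-tree predictions.
    """

    trees: list
    params: ForestParams
    covariate_names: list[str]
    y_train: np.ndarray
    inbag_idx: list[np.ndarray]
    inbag_leaves: list[np.ndarray]
    classes: np.ndarray | None = None
    oob_mse: float | None = None
    oob_r2: float | None = None
    importance: pd.Series | None = None
    y_range: tuple[float, float] | None = None

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "params": {
                "num_trees": self.params.num_trees,
                "mtry": self.params.mtry,
                "min_node_size": self.params.min_node_size,
                "sample_fraction": self.params.sample_fraction,
                "seed": self.params.seed,
                "task": self.params.task,
            },
            "covariate_names": self.covariate_names,
            "oob_mse": self.oob_mse,
            "oob_r2": self.oob_r2,
            "classes": None if self.classes is None else self.classes.tolist(),
        }
        (path / "params.json").write_text(json.dumps(meta, indent=1))
        # all draws share one size, so the bookkeeping stacks to int tables
        np.savez(
            path / "train.npz",
            y_train=self.y_train,
            inbag_idx=np.stack(self.inbag_idx).astype(np.int64),
            inbag_leaves=np.stack(self.inbag_leaves).astype(np.int64),
        )
        joblib.dump(self.trees, path / "trees.joblib")

    @classmethod
    def load(cls, path) -> "RFspModel":
        path = Path(path)
        meta = json.loads((path / "params.json").read_text())
        arrs = np.load(path / "train.npz", allow_pickle=True)
        params = ForestParams(**meta["params"])
        return cls(
            trees=joblib.load(path / "trees.joblib"),
            params=params,
            covariate_names=meta["covariate_names"],
            y_train=arrs["y_train"],
            inbag_idx=list(arrs["inbag_idx"]),
            inbag_leaves=list(arrs["inbag_leaves"]),
            classes=None if meta["classes"] is None else np.asarray(meta["classes"]),
            oob_mse=meta["oob_mse"],
            oob_r2=meta["oob_r2"],
        )


@dataclass
class QuantilePrediction:
    """Per-location quantiles, mean, sigma and (optionally) QRF weights."""

    quantiles: dict[float, np.ndarray]
    mean: np.ndarray
    sigma: np.ndarray | None = None
    weights: np.ndarray | None = None  # (n_pred, n_train)


# ---------------------------------------------------------------------------
# design construction

def build_design(
    ps: PointSet | list[PointSet],
    stacks: CovariateStack | list[CovariateStack],
    temporal: TemporalCovariates | None = None,
    multivariate: bool = False,
    method_labels: list | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Overlay points on covariate stacks into one regression table.

    Returns (design, weights): design has one row per observation with a
    ``target`` column, weights is 1/meas_sd^2 when measurement-error SDs
    are present (else None).  Rows with any missing covariate are dropped
    with a count in ``design.attrs['n_dropped']``.

    In multivariate mode, ps is a list of PointSets each carrying a
    type_label; rows are stacked into a single matrix and the type (and
    optional per-set method label) become 0/1 indicator columns, so one
    model serves several target variables.
    """
    if isinstance(stacks, CovariateStack):
        stacks = [stacks]
    ps_list = ps if isinstance(ps, list) else [ps]
    if multivariate:
        for k, p_ in enumerate(ps_list):
            if p_.type_label is None:
                raise InputError(f"multivariate mode: PointSet {k} lacks type_label")
    elif len(ps_list) != 1:
        raise InputError("pass multivariate=True to stack several PointSets")

    frames = []
    for k, p_ in enumerate(ps_list):
        cols = [overlay(p_, s) for s in stacks]
        df = pd.concat(cols, axis=1)
        if temporal is not None and not multivariate:
            df = pd.concat([df, temporal.as_frame()], axis=1)
        elif p_.time is not None:
            from .geocov import temporal_covariates
            df = pd.concat(
                [df, temporal_covariates(p_.time).as_frame()], axis=1
            )
        df[TARGET_COL] = p_.target
        if multivariate:
            df["_type"] = p_.type_label
            df["_method"] = (
                method_labels[k] if method_labels is not None else "default"
            )
        if p_.meas_sd is not None:
            df["_w"] = 1.0 / p_.meas_sd**2
        frames.append(df)
    design = pd.concat(frames, ignore_index=True)

    if multivariate:
        design = pd.get_dummies(design, columns=["_type"], prefix="TYPE", dtype=float)
        design = pd.get_dummies(design, columns=["_method"], prefix="METHOD", dtype=float)

    weights = None
    if "_w" in design.columns:
        weights = design.pop("_w").to_numpy()

    feat = [c for c in design.columns if c != TARGET_COL]
    good = ~design[feat].isna().any(axis=1).to_numpy()
    n_dropped = int((~good).sum())
    if n_dropped == len(design):
        raise InputError("no complete rows after overlay")
    design = design[good].reset_index(drop=True)
    if weights is not None:
        weights = weights[good]
    design.attrs["n_dropped"] = n_dropped
    return design, weights


# ---------------------------------------------------------------------------
# fitting

def fit_forest(design: pd.DataFrame, params: ForestParams) -> RFspModel:
    """Grow the ensemble on (case-weighted) bootstrap draws.

    Deterministic for a fixed seed.  p >= n is permitted — with buffer
    distances there is one covariate per training point, and more
    covariates than observations is routine.  OOB statistics come from
    predictions of trees whose bootstrap excluded the observation.
    """
    feat = [c for c in design.columns if c != TARGET_COL]
    X = design[feat].to_numpy(dtype=float)
    y = design[TARGET_COL].to_numpy()
    n, p = X.shape
    params.validate(n, p)

    if params.task == "regression":
        y = y.astype(float)
        if np.unique(y).size < 2:
            raise InputError("regression needs >= 2 distinct target values")
        Tree, is_reg = DecisionTreeRegressor, True
    else:
        y = y.astype(str)
        classes = np.unique(y)
        if classes.size < 2:
            raise InputError("probability task needs >= 2 classes")
        Tree, is_reg = DecisionTreeClassifier, False

    w = None
    if params.case_weights is not None:
        w = np.asarray(params.case_weights, dtype=float)
        w = w / w.sum()

    mtry = params.resolved_mtry(p)
    min_node = params.resolved_min_node()
    n_draw = max(1, round(params.sample_fraction * n))
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    tree_seeds = rng.integers(0, 2**31 - 1, size=params.num_trees)

    trees, inbag_idx, inbag_leaves = [], [], []
    oob_sum = np.zeros((n, len(np.unique(y)) if not is_reg else 1))
    oob_cnt = np.zeros(n)
    classes_all = None if is_reg else np.unique(y)

    for b in range(params.num_trees):
        idx = rng.choice(n, size=n_draw, replace=True, p=w)
        tree = Tree(
            max_features=mtry,
            min_samples_leaf=min_node,
            random_state=int(tree_seeds[b]),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag_idx.append(idx)
        inbag_leaves.append(tree.apply(X[idx]).astype(np.int32))

        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if oob.any():
            if is_reg:
                oob_sum[oob, 0] += tree.predict(X[oob])
            else:
                proba = tree.predict_proba(X[oob])
                cols = np.searchsorted(classes_all, tree.classes_)
                oob_sum[np.ix_(oob, cols)] += proba
            oob_cnt[oob] += 1

    seen = oob_cnt > 0
    oob_mse = oob_r2 = None
    if is_reg and seen.any():
        oob_pred = oob_sum[seen, 0] / oob_cnt[seen]
        oob_mse = float(np.mean((oob_pred - y[seen]) ** 2))
        sst = float(np.mean((y[seen] - y[seen].mean()) ** 2))
        oob_r2 = 1.0 - oob_mse / sst if sst > 0 else None
    elif not is_reg and seen.any():
        pred_cls = classes_all[np.argmax(oob_sum[seen], axis=1)]
        oob_mse = float(np.mean(pred_cls != y[seen]))  # misclassification rate

    imp = pd.Series(
        np.mean([t.feature_importances_ for t in trees], axis=0), index=feat
    ).sort_values(ascending=False)

    return RFspModel(
        trees=trees,
        params=params,
        covariate_names=feat,
        y_train=y,
        inbag_idx=inbag_idx,
        inbag_leaves=inbag_leaves,
        classes=classes_all,
        oob_mse=oob_mse,
        oob_r2=oob_r2,
        importance=imp,
        y_range=(float(y.min()), float(y.max())) if is_reg else None,
    )


# ---------------------------------------------------------------------------
# prediction

def _check_X0(model: RFspModel, X0) -> np.ndarray:
    if isinstance(X0, pd.DataFrame):
        missing = [c for c in model.covariate_names if c not in X0.columns]
        if missing:
            raise InputError(f"prediction rows lack covariates {missing}")
        X0 = X0[model.covariate_names]
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if X0.shape[1] != len(model.covariate_names):
        raise InputError(
            f"expected {len(model.covariate_names)} covariates, got {X0.shape[1]}"
        )
    return X0


def predict_mean(model: RFspModel, X0) -> np.ndarray:
    """Ensemble mean: average of per-tree predictions."""
    X0 = _check_X0(model, X0)
    if model.params.task != "regression":
        raise InputError("predict_mean needs a regression model")
    return np.mean([t.predict(X0) for t in model.trees], axis=0)


def qrf_weights(model: RFspModel, X0) -> np.ndarray:
    """QRF observation weights alpha_i(s0), one row per prediction point.

    Per tree, each in-bag draw in the prediction point's leaf gets weight
    1/(leaf size); weights are accumulated per original observation
    (multiplicity counts) and averaged over trees.  Rows sum to 1.
    """
    X0 = _check_X0(model, X0)
    n0, n = X0.shape[0], model.n_train
    alpha = np.zeros((n0, n))
    for tree, idx, leaves in zip(model.trees, model.inbag_idx, model.inbag_leaves):
        leaf0 = tree.apply(X0)
        order = np.argsort(leaves, kind="stable")
        sorted_leaves = leaves[order]
        uniq, starts = np.unique(sorted_leaves, return_index=True)
        ends = np.append(starts[1:], len(sorted_leaves))
        # per-leaf scatter of 1/leafsize onto original observation indices
        leafw = np.zeros((len(uniq), n))
        for u, (s, e) in enumerate(zip(starts, ends)):
            np.add.at(leafw[u], idx[order[s:e]], 1.0 / (e - s))
        pos = np.searchsorted(uniq, leaf0)
        alpha += leafw[pos]
    alpha /= len(model.trees)
    return alpha


def predict_quantiles(
    model: RFspModel,
    X0,
    qs=(0.05, 0.5, 0.95),
    sigma: bool = True,
    sigma_method: str = "interval",
    keep_weights: bool = False,
) -> QuantilePrediction:
    """Quantiles by inverting the QRF conditional CDF.

    F_hat(t) = sum_i alpha_i(s0) 1{y_i <= t}; the q-quantile is the
    smallest observed y with F_hat >= q (lower-step rule, no
    interpolation).  sigma_method 'interval' uses half the width of the
    68.27% interval, sigma = (q_.841 - q_.159)/2, assuming locally
    symmetric errors; 'sd' computes the full weighted-distribution SD,
    for when that symmetry is suspect.
    """
    qs = tuple(float(q) for q in qs)
    if len(qs) == 0:
        raise InputError("qs must be non-empty")
    if any(not (0 < q < 1) for q in qs):
        raise InputError("quantile levels must lie in (0, 1)")
    if model.params.task != "regression":
        raise InputError("quantiles need a regression model")

    alpha = qrf_weights(model, X0)
    y = model.y_train.astype(float)
    order = np.argsort(y)
    y_sorted = y[order]
    cum = np.cumsum(alpha[:, order], axis=1)
    cum[:, -1] = 1.0  # exact tail despite round-off

    need = set(qs)
    if sigma and sigma_method == "interval":
        need |= {0.159, 0.841}
    qvals: dict[float, np.ndarray] = {}
    for q in sorted(need):
        # first index where cumulative weight reaches q (rows are monotone)
        pos = np.minimum((cum < q - 1e-12).sum(axis=1), len(y_sorted) - 1)
        qvals[q] = y_sorted[pos]

    mean = alpha @ y
    sig = None
    if sigma:
        if sigma_method == "interval":
            sig = sigma_from_interval(qvals[0.841], qvals[0.159])
        elif sigma_method == "sd":
            sig = np.sqrt(np.maximum(alpha @ y**2 - mean**2, 0.0))
        else:
            raise InputError(f"unknown sigma_method {sigma_method!r}")
    return QuantilePrediction(
        quantiles={q: qvals[q] for q in qs},
        mean=mean,
        sigma=sig,
        weights=alpha if keep_weights else None,
    )


def sigma_from_interval(q841, q159):
    """Prediction-error SD from a 68.27% interval: (q_.841 - q_.159)/2."""
    q841 = np.asarray(q841, dtype=float)
    q159 = np.asarray(q159, dtype=float)
    if np.any(q841 < q159):
        raise InputError("upper quantile below lower quantile")
    return (q841 - q159) / 2.0


def predict_probabilities(model: RFspModel, X0) -> pd.DataFrame:
    """Per-class occurrence probabilities (ensemble-averaged leaf frequencies).

    For a binary 0/1 target this is numerically equivalent to running a
    regression forest on the indicator.
    """
    if model.params.task != "probability":
        raise InputError("predict_probabilities needs a probability-task model")
    X0 = _check_X0(model, X0)
    out = np.zeros((X0.shape[0], len(model.classes)))
    for tree in model.trees:
        proba = tree.predict_proba(X0)
        cols = np.searchsorted(model.classes, tree.classes_)
        out[:, cols] += proba
    out /= len(model.trees)
    return pd.DataFrame(out, columns=list(model.classes))


def predict_multivariate(
    model: RFspModel,
    stack: CovariateStack,
    active_type: str,
    active_method: str = "default",
    temporal_row: dict | None = None,
) -> np.ndarray:
    """Prediction surface for one variable type from a stacked model.

    Sets exactly one TYPE_* and one METHOD_* indicator to 1 and predicts
    over the stack's valid cells.  Switching active_type re-targets the
    same fitted ensemble to a different variable.
    """
    type_col = f"TYPE_{active_type}"
    method_col = f"METHOD_{active_method}"
    known_t = [c[5:] for c in model.covariate_names if c.startswith("TYPE_")]
    known_m = [c[7:] for c in model.covariate_names if c.startswith("METHOD_")]
    if type_col not in model.covariate_names:
        raise InputError(f"unknown type {active_type!r}; known: {known_t}")
    if method_col not in model.covariate_names:
        raise InputError(f"unknown method {active_method!r}; known: {known_m}")

    X0 = stack.table(valid_only=True).copy()
    for c in model.covariate_names:
        if c.startswith("TYPE_"):
            X0[c] = 1.0 if c == type_col else 0.0
        elif c.startswith("METHOD_"):
            X0[c] = 1.0 if c == method_col else 0.0
        elif temporal_row is not None and c in temporal_row:
            X0[c] = temporal_row[c]
    pred = predict_mean(model, X0)
    surf = np.full(stack.grid.shape, np.nan)
    surf[stack.mask] = pred
    return surf


def predict_surface(
    model: RFspModel,
    stack: CovariateStack,
    qs=(),
    extra: dict | None = None,
) -> dict[str, np.ndarray]:
    """Mean (and optional quantile/sigma) maps over a stack's valid cells.

    extra supplies constant covariate columns not present in the stack,
    e.g. {'cdate': 16375, 'doy': 305} to map a single day from a
    spatiotemporal model.
    """
    X0 = stack.table(valid_only=True).copy()
    if extra:
        for k, v in extra.items():
            X0[k] = v

    def to_grid(vals):
        g = np.full(model_grid_shape, np.nan)
        g[stack.mask] = vals
        return g

    model_grid_shape = stack.grid.shape
    out: dict[str, np.ndarray] = {}
    if qs:
        qp = predict_quantiles(model, X0, qs=qs, sigma=True)
        out["mean"] = to_grid(qp.mean)
        out["sigma"] = to_grid(qp.sigma)
        for q, v in qp.quantiles.items():
            out[f"q{q:g}"] = to_grid(v)
    else:
        out["mean"] = to_grid(predict_mean(model, X0))
    return out
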