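"""MLR fitting and the QSAR validation battery.

Implements ordinary least squares on raw (unscaled) descriptors plus the
internal, external and robustness statistics conventionally reported for
regression QSAR models:

- internal: R^2, adjusted R^2, Q^2_LOO (closed-form PRESS), Q^2_LMO,
  training MAE, Roy's r_m^2(LOO) and its delta;
- external: Q^2_F1 (a.k.a. R^2_Pred), Q^2_F2, RMSEP, test MAE,
  r_m^2(test) and its delta;
- diagnostics: cross-correlation matrix, VIF, standardized coefficients;
- robustness: Y-randomization with the cR_p^2 statistic;
- applicability domain: Williams-plot leverages and standardized
  residuals with structural (h > h* = 3(p+1)/n) and response
  (|standardized residual| > 3) outlier flags.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MLRModel",
    "ValidationReport",
    "ADReport",
    "fit_ols",
    "loo_predictions",
    "q2_loo",
    "q2_lmo",
    "external_metrics",
    "rm2_metrics",
    "collinearity",
    "y_randomization",
    "williams_ad",
    "standardized_coefficients",
    "validate_model",
]


@dataclass
class MLRModel:
    """A fitted (or frozen) multiple linear regression model."""

    names: list[str]
    coefficients: list[float]
    intercept: float
    coefficient_se: list[float] | None = None
    intercept_se: float | None = None
    training_ids: list[str] | None = None

    def __post_init__(self):
        if len(self.coefficients) != len(self.names):
            raise ValueError("one coefficient per descriptor name required")
        values = list(self.coefficients) + [self.intercept]
        if not np.all(np.isfinite(values)):
            raise ValueError("model coefficients must be finite")

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.names if n not in X.columns]
            if missing:
                raise KeyError(f"missing descriptors: {', '.join(missing)}")
            X = X[self.names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ np.asarray(self.coefficients)


def _design(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    return np.column_stack([np.ones(len(X)), X])


def fit_ols(X: pd.DataFrame, y: pd.Series | np.ndarray) -> MLRModel:
    """OLS with intercept on raw descriptors; SEs from unbiased residual variance."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    A = _design(X)
    yv = np.asarray(y, dtype=float)
    n, pp1 = A.shape
    if np.linalg.matrix_rank(A) < pp1:
        corr = np.corrcoef(A[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        worst = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient design; most collinear columns: "
            f"{names[worst[0]]}, {names[worst[1]]}"
        )
    res = sm.OLS(yv, A).fit()
    if n <= pp1:
        warnings.warn("zero residual degrees of freedom; standard errors undefined")
        ses = [float("nan")] * pp1
    else:
        ses = list(res.bse)
    ids = list(X.index.astype(str)) if isinstance(X, pd.DataFrame) else None
    return MLRModel(
        names=names,
        coefficients=[float(c) for c in res.params[1:]],
        intercept=float(res.params[0]),
        coefficient_se=[float(s) for s in ses[1:]],
        intercept_se=float(ses[0]),
        training_ids=ids,
    )


# ---------------------------------------------------------------------- #
# cross-validation
# ---------------------------------------------------------------------- #
def loo_predictions(X, y) -> np.ndarray:
    """Leave-one-out predictions via the closed-form PRESS residual.

    For OLS, the LOO residual is e_i / (1 - h_ii); points with h_ii = 1
    fall back to an explicit refit without that point.
    """
    A = _design(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    H = A @ np.linalg.solve(A.T @ A, A.T)
    h = np.diag(H)
    resid = yv - H @ yv
    press_resid = np.empty(n)
    for i in range(n):
        if 1.0 - h[i] < 1e-12:
            mask = np.arange(n) != i
            beta = np.linalg.lstsq(A[mask], yv[mask], rcond=None)[0]
            press_resid[i] = yv[i] - A[i] @ beta
        else:
            press_resid[i] = resid[i] / (1.0 - h[i])
    return yv - press_resid


def q2_loo(X, y) -> float:
    """Leave-one-out cross-validated R^2 (1 - PRESS/SStot about the mean)."""
    yv = np.asarray(y, dtype=float)
    press = np.sum((yv - loo_predictions(X, y)) ** 2)
    sstot = np.sum((yv - yv.mean()) ** 2)
    if sstot == 0:
        raise ValueError("constant response: Q2 undefined")
    return 1.0 - press / sstot


def q2_lmo(X, y, groups: int = 5, runs: int = 20, seed: int = 0) -> float:
    """Leave-many-out Q^2: random partition into groups, averaged over runs."""
    A = _design(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    sstot = np.sum((yv - yv.mean()) ** 2)
    rng = np.random.default_rng(seed)
    q2s = []
    for _ in range(runs):
        perm = rng.permutation(n)
        folds = np.array_split(perm, groups)
        pred = np.empty(n)
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            beta = np.linalg.lstsq(A[mask], yv[mask], rcond=None)[0]
            pred[fold] = A[fold] @ beta
        q2s.append(1.0 - np.sum((yv - pred) ** 2) / sstot)
    return float(np.mean(q2s))


# ---------------------------------------------------------------------- #
# external validation
# ---------------------------------------------------------------------- #
def external_metrics(model: MLRModel, Xtest, ytest, ytrain_mean: float) -> dict[str, float]:
    """Q^2_F1, Q^2_F2, RMSEP and MAE on an external test set."""
    yv = np.asarray(ytest, dtype=float)
    if len(yv) == 0:
        raise ValueError("empty test set")
    pred = model.predict(Xtest)
    sse = np.sum((yv - pred) ** 2)
    denom_f1 = np.sum((yv - ytrain_mean) ** 2)
    denom_f2 = np.sum((yv - yv.mean()) ** 2)
    return {
        "Q2_F1": 1.0 - sse / denom_f1 if denom_f1 > 0 else float("nan"),
        "Q2_F2": 1.0 - sse / denom_f2 if denom_f2 > 0 else float("nan"),
        "RMSEP": float(np.sqrt(sse / len(yv))),
        "MAE_test": float(np.mean(np.abs(yv - pred))),
    }


def rm2_metrics(yobs, ypred) -> dict[str, float]:
    """Roy's r_m^2 metrics from observed and predicted activities.

    r_m^2 = r^2 (1 - sqrt(r^2 - r0^2)) with r0^2 the determination
    coefficient of the through-origin regression of predicted on observed;
    the reverse variant swaps the roles.  A slightly negative radicand
    (numerical noise) is clamped to zero with a notice.
    """
    yo = np.asarray(yobs, dtype=float)
    yp = np.asarray(ypred, dtype=float)
    if len(yo) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(yo, yo[0]) or np.allclose(yp, yp[0]):
        raise ValueError("constant vector: r_m^2 undefined")
    r2 = float(np.corrcoef(yo, yp)[0, 1] ** 2)

    def _r02(x, z):
        # through-origin regression of z on x
        k = float(np.sum(x * z) / np.sum(x * x))
        return 1.0 - np.sum((z - k * x) ** 2) / np.sum((z - z.mean()) ** 2)

    def _rm2(r02):
        radicand = r2 - r02
        if radicand < 0:
            if radicand < -1e-8:
                warnings.warn(f"negative radicand {radicand:.3g} in r_m^2 clamped to 0")
            radicand = 0.0
        return r2 * (1.0 - np.sqrt(radicand))

    rm2 = _rm2(_r02(yo, yp))
    rm2_rev = _rm2(_r02(yp, yo))
    return {
        "rm2": rm2,
        "rm2_reverse": rm2_rev,
        "rm2_mean": 0.5 * (rm2 + rm2_rev),
        "delta_rm2": abs(rm2 - rm2_rev),
    }


# ---------------------------------------------------------------------- #
# diagnostics
# ---------------------------------------------------------------------- #
def collinearity(X: pd.DataFrame) -> dict:
    """Cross-correlation matrix, its maximum |r|, and per-column VIF."""
    Xv = X.to_numpy(dtype=float)
    names = list(X.columns)
    corr = np.atleast_2d(np.corrcoef(Xv, rowvar=False))
    off = corr.copy()
    np.fill_diagonal(off, 0.0)
    vifs = {}
    for j, name in enumerate(names):
        others = np.delete(Xv, j, axis=1)
        A = np.column_stack([np.ones(len(Xv)), others])
        beta, *_ = np.linalg.lstsq(A, Xv[:, j], rcond=None)
        resid = Xv[:, j] - A @ beta
        sst = np.sum((Xv[:, j] - Xv[:, j].mean()) ** 2)
        r2j = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
        vifs[name] = float("inf") if 1.0 - r2j < 1e-12 else 1.0 / (1.0 - r2j)
    return {
        "correlation": pd.DataFrame(corr, index=names, columns=names),
        "max_abs_r": float(np.max(np.abs(off))) if len(names) > 1 else 0.0,
        "vif": vifs,
    }


def standardized_coefficients(model: MLRModel, X: pd.DataFrame, y) -> pd.Series:
    """b_j * sd(x_j) / sd(y), ranked by absolute magnitude."""
    yv = np.asarray(y, dtype=float)
    sy = yv.std(ddof=1)
    out = {}
    for name, b in zip(model.names, model.coefficients):
        sx = X[name].to_numpy(dtype=float).std(ddof=1)
        out[name] = b * sx / sy if sx > 0 else float("nan")
    s = pd.Series(out, name="standardized_coefficient")
    return s.reindex(s.abs().sort_values(ascending=False).index)


def y_randomization(X, y, iterations: int = 100, seed: int = 0) -> dict[str, float]:
    """Response-permutation robustness test with the cR_p^2 statistic.

    cR_p^2 = R * sqrt(R^2 - mean(R_r^2)) where R^2 belongs to the true
    model and R_r^2 to models refit on permuted responses.
    """
    if iterations < 10:
        raise ValueError("need at least 10 iterations")
    A = _design(X)
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def _r2(ys):
        beta = np.linalg.lstsq(A, ys, rcond=None)[0]
        resid = ys - A @ beta
        return 1.0 - np.sum(resid**2) / np.sum((ys - ys.mean()) ** 2)

    r2_true = _r2(yv)
    r2_rand = np.array([_r2(rng.permutation(yv)) for _ in range(iterations)])
    radicand = r2_true - r2_rand.mean()
    if radicand < 0:
        warnings.warn("mean randomized R^2 exceeds true R^2; cR_p^2 clamped to 0")
        radicand = 0.0
    return {
        "R2": float(r2_true),
        "mean_R2_rand": float(r2_rand.mean()),
        "cRp2": float(np.sqrt(r2_true) * np.sqrt(radicand)),
    }


# ---------------------------------------------------------------------- #
# applicability domain
# ---------------------------------------------------------------------- #
@dataclass
class ADReport:
    """Williams-plot data: leverages, standardized residuals, outlier flags."""

    table: pd.DataFrame  # id, set, leverage, std_residual, structural_outlier, response_outlier
    h_star: float
    n_structural_outliers: int
    n_response_outliers: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def williams_ad(
    model: MLRModel,
    Xtrain: pd.DataFrame,
    ytrain,
    Xtest: pd.DataFrame | None = None,
    ytest=None,
    residual_limit: float = 3.0,
) -> ADReport:
    """Applicability-domain analysis on the intercept-augmented design.

    Leverage h_i = x_i (X'X)^-1 x_i' with X the training design; test
    points are projected onto it.  Warning leverage h* = 3(p+1)/n.
    Standardized residuals divide by the training RMSE (training points)
    or the RMSEP (test points).
    """
    A = _design(Xtrain[model.names])
    yv = np.asarray(ytrain, dtype=float)
    XtX = A.T @ A
    if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        raise np.linalg.LinAlgError("singular X'X in leverage computation")
    XtX_inv = np.linalg.inv(XtX)
    p = len(model.names)
    n = len(yv)
    h_star = 3.0 * (p + 1) / n

    def _leverages(M):
        return np.einsum("ij,jk,ik->i", M, XtX_inv, M)

    pred_train = model.predict(Xtrain)
    resid_train = yv - pred_train
    rmse_train = float(np.sqrt(np.mean(resid_train**2)))
    rows = []
    for i, cid in enumerate(Xtrain.index.astype(str)):
        rows.append(("train", cid, _leverages(A[i : i + 1])[0], resid_train[i] / rmse_train))
    if Xtest is not None and len(Xtest):
        At = _design(Xtest[model.names])
        ytv = np.asarray(ytest, dtype=float)
        resid_test = ytv - model.predict(Xtest)
        rmsep = float(np.sqrt(np.mean(resid_test**2)))
        hs = _leverages(At)
        for i, cid in enumerate(Xtest.index.astype(str)):
            rows.append(("test", cid, hs[i], resid_test[i] / rmsep))
    table = pd.DataFrame(rows, columns=["set", "id", "leverage", "std_residual"])
    table["structural_outlier"] = table["leverage"] > h_star
    table["response_outlier"] = table["std_residual"].abs() > residual_limit
    return ADReport(
        table=table[["id", "set", "leverage", "std_residual", "structural_outlier", "response_outlier"]],
        h_star=h_star,
        n_structural_outliers=int(table["structural_outlier"].sum()),
        n_response_outliers=int(table["response_outlier"].sum()),
    )


# ---------------------------------------------------------------------- #
# the full report
# ---------------------------------------------------------------------- #
@dataclass
class ValidationReport:
    """Every statistic of the validation battery, training and test side."""

    n_train: int
    n_test: int
    R2: float
    R2_adj: float
    Q2_LOO: float
    Q2_LMO: float
    MAE: float
    rm2_LOO: float
    delta_rm2_LOO: float
    Q2_F1: float | None
    Q2_F2: float | None
    RMSEP: float | None
    MAE_test: float | None
    rm2_test: float | None
    delta_rm2_test: float | None
    max_abs_r: float
    vif: dict[str, float]
    cRp2: float
    mean_R2_rand: float
    standardized_coefficients: dict[str, float]
    lmo_groups: int = 5
    lmo_runs: int = 20
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_markdown(self) -> str:
        lines = [
            "| statistic | value |",
            "|---|---|",
            f"| N_train | {self.n_train} |",
            f"| R2 | {self.R2:.3f} |",
            f"| R2_adj | {self.R2_adj:.3f} |",
            f"| Q2_LOO | {self.Q2_LOO:.3f} |",
            f"| Q2_LMO ({self.lmo_groups} groups, {self.lmo_runs} runs) | {self.Q2_LMO:.3f} |",
            f"| MAE (train) | {self.MAE:.3f} |",
            f"| rm2_LOO | {self.rm2_LOO:.3f} |",
            f"| delta_rm2_LOO | {self.delta_rm2_LOO:.3f} |",
            f"| max pairwise abs r | {self.max_abs_r:.3f} |",
            f"| cRp2 | {self.cRp2:.3f} |",
        ]
        if self.n_test:
            lines += [
                f"| N_test | {self.n_test} |",
                f"| Q2_F1 (R2_Pred) | {self.Q2_F1:.3f} |",
                f"| Q2_F2 | {self.Q2_F2:.3f} |",
                f"| RMSEP | {self.RMSEP:.3f} |",
                f"| MAE (test) | {self.MAE_test:.3f} |",
                f"| rm2_test | {self.rm2_test:.3f} |",
                f"| delta_rm2_test | {self.delta_rm2_test:.3f} |",
            ]
        return "\n".join(lines)


def validate_model(
    Xtrain: pd.DataFrame,
    ytrain,
    Xtest: pd.DataFrame | None = None,
    ytest=None,
    model: MLRModel | None = None,
    y_rand_iterations: int = 100,
    lmo_groups: int = 5,
    lmo_runs: int = 20,
    seed: int = 0,
) -> tuple[MLRModel, ValidationReport]:
    """Fit (or take) an MLR model and compute the full validation battery."""
    if model is None:
        model = fit_ols(Xtrain, ytrain)
    Xt = Xtrain[model.names]
    yv = np.asarray(ytrain, dtype=float)
    n, p = len(yv), len(model.names)
    pred = model.predict(Xt)
    sse = np.sum((yv - pred) ** 2)
    sst = np.sum((yv - yv.mean()) ** 2)
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    loo_pred = loo_predictions(Xt, yv)
    q2 = 1.0 - np.sum((yv - loo_pred) ** 2) / sst
    rm_loo = rm2_metrics(yv, loo_pred)
    coll = collinearity(Xt)
    yr = y_randomization(Xt, yv, iterations=y_rand_iterations, seed=seed)
    std_coefs = standardized_coefficients(model, Xt, yv)
    ext = {"Q2_F1": None, "Q2_F2": None, "RMSEP": None, "MAE_test": None}
    rm_test = {"rm2": None, "delta_rm2": None}
    n_test = 0
    if Xtest is not None and len(Xtest):
        n_test = len(Xtest)
        ext = external_metrics(model, Xtest[model.names], ytest, float(yv.mean()))
        rm_test = rm2_metrics(np.asarray(ytest, float), model.predict(Xtest[model.names]))
    report = ValidationReport(
        n_train=n,
        n_test=n_test,
        R2=float(r2),
        R2_adj=float(r2_adj),
        Q2_LOO=float(q2),
        Q2_LMO=float(q2_lmo(Xt, yv, groups=lmo_groups, runs=lmo_runs, seed=seed)),
        MAE=float(np.mean(np.abs(yv - pred))),
        rm2_LOO=float(rm_loo["rm2"]),
        delta_rm2_LOO=float(rm_loo["delta_rm2"]),
        Q2_F1=ext["Q2_F1"],
        Q2_F2=ext["Q2_F2"],
        RMSEP=ext["RMSEP"],
        MAE_test=ext["MAE_test"],
        rm2_test=rm_test["rm2"],
        delta_rm2_test=rm_test["delta_rm2"],
        max_abs_r=coll["max_abs_r"],
        vif={k: float(v) for k, v in coll["vif"].items()},
        cRp2=yr["cRp2"],
        mean_R2_rand=yr["mean_R2_rand"],
        standardized_coefficients={k: float(v) for k, v in std_coefs.items()},
        lmo_groups=lmo_groups,
        lmo_runs=lmo_runs,
        seed=seed,
    )
    return model, report
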