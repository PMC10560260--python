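"""Regularized linear BMI models on the lipidome.

The estimator minimizes the elastic-net objective in the 1/(2n) convention

    (1/2n) * sum_i (y_i - x_i'b)^2 + lam * [ l1 * |b_P|_1 + (1-l1)/2 * |b_P|^2 ]

where the penalty P runs over the *penalized* features only: the intercept
and declared covariates (age, sex by default) are never shrunk unless
``shrink_covariates`` is set.  Unpenalized covariates are profiled out
exactly (Frisch–Waugh residualization), so the penalized sub-problem can be
handed to an SVD ridge path or to coordinate descent unchanged.

The response is standardized internally to unit SD, which puts lambda on the
scale used by glmnet-style tooling (grids of 10^-4 .. 10^0.2 reach both the
practically-optimal ridge region and the all-null LASSO model); coefficients
and predictions are returned in kg/m^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from ._version import __version__ as _pkg_version
from .qc import LipidStandardizer

#: 120-point lambda grid spanning log10 lambda in [-4, 0.2].
DEFAULT_LAMBDA_GRID = np.logspace(-4.0, 0.2, 120)

PENALTIES = ("ridge", "lasso", "elastic_net")


@dataclass
class ModelSpec:
    """Declarative description of one BMI model fit."""

    penalty: str = "ridge"
    lam: float | str = "optimize"
    l1_ratio: float = 0.5
    unpenalized: tuple = ("age", "sex")
    folds: int = 10
    inner_folds: int = 5
    shrink_covariates: bool = False
    seed: int = 0
    lambda_grid: np.ndarray | None = None

    def validate(self) -> None:
        if self.penalty not in PENALTIES:
            raise ValueError(f"penalty must be one of {PENALTIES}")
        if self.lam != "optimize" and float(self.lam) < 0:
            raise ValueError("lambda must be non-negative or 'optimize'")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @property
    def grid(self) -> np.ndarray:
        return DEFAULT_LAMBDA_GRID if self.lambda_grid is None else np.asarray(self.lambda_grid)


# ----------------------------------------------------------------------
def _residualize(Xu: np.ndarray, *arrays):
    """Project out the column space of Xu from each array (exact profiling)."""
    Q, _ = np.linalg.qr(Xu)
    return [a - Q @ (Q.T @ a) for a in arrays]


def _effective_l1_ratio(penalty: str, l1_ratio: float) -> float:
    return {"ridge": 0.0, "lasso": 1.0}.get(penalty, l1_ratio)


def _ridge_path(Xp_t: np.ndarray, y_t: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Ridge solutions (p x L) for all lambdas via one SVD.

    Solves (Xp'Xp + n*lam*I) b = Xp'y for each lam in the 1/(2n) objective
    convention; with duplicate columns the + n*lam*I term makes the solution
    unique and symmetric in the duplicates.
    """
    n = Xp_t.shape[0]
    U, s, Vt = np.linalg.svd(Xp_t, full_matrices=False)
    c = U.T @ y_t
    d = s[:, None] / (s[:, None] ** 2 + n * np.atleast_1d(lams)[None, :])
    return Vt.T @ (d * c[:, None])


def _enet_coef_path(Xp_t, y_t, lams, l1_ratio) -> np.ndarray:
    """Coordinate-descent elastic-net path, returned in the order of `lams`."""
    order = np.argsort(lams)[::-1]          # enet_path wants decreasing alphas
    alphas = np.asarray(lams, dtype=float)[order]
    _, coefs, _ = enet_path(
        np.ascontiguousarray(Xp_t), np.ascontiguousarray(y_t),
        l1_ratio=max(l1_ratio, 1e-6), alphas=alphas, max_iter=5000,
    )
    out = np.empty_like(coefs)
    out[:, order] = coefs
    return out


def _coef_path(Xp_t, y_t, lams, penalty, l1_ratio):
    l1 = _effective_l1_ratio(penalty, l1_ratio)
    if penalty == "ridge":
        return _ridge_path(Xp_t, y_t, np.asarray(lams, dtype=float))
    return _enet_coef_path(Xp_t, y_t, np.asarray(lams, dtype=float), l1)


def _gamma_for(Xu, y, Xp, coef_path):
    """Unpenalized coefficients per lambda: gamma = (Xu'Xu)^-1 Xu'(y - Xp b)."""
    resid = y[:, None] - Xp @ coef_path
    gamma, *_ = np.linalg.lstsq(Xu, resid, rcond=None)
    return gamma


# ----------------------------------------------------------------------
class RegularizedBmiRegressor(RegressorMixin, BaseEstimator):
    """Ridge/LASSO/elastic-net regression with unpenalized covariates.

    Parameters
    ----------
    penalty:
        ``"ridge"``, ``"lasso"`` or ``"elastic_net"``.
    lam:
        Regularization strength in the 1/(2n) objective convention, or
        ``"optimize"`` to pick the inner-CV MSE minimizer over ``lambda_grid``.
    l1_ratio:
        Elastic-net mixing fraction (ignored for ridge/lasso).
    unpenalized:
        Feature names excluded from the penalty (the intercept always is).
    shrink_covariates:
        If True the covariates join the penalized set (internally z-scored),
        so at extreme lambda the model collapses to the intercept alone.
    cv:
        Inner folds used when ``lam="optimize"``.
    random_state:
        Seed for the inner-CV fold shuffle.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : coefficients in response units (kg/m^2 per unit
        feature); ``lambda_`` the lambda actually used; ``cv_mse_path_`` the
        inner-CV MSE per grid lambda when optimized.
    """

    def __init__(self, penalty="ridge", lam="optimize", l1_ratio=0.5,
                 unpenalized=("age", "sex"), shrink_covariates=False,
                 cv=5, lambda_grid=None, random_state=0):
        self.penalty = penalty
        self.lam = lam
        self.l1_ratio = l1_ratio
        self.unpenalized = unpenalized
        self.shrink_covariates = shrink_covariates
        self.cv = cv
        self.lambda_grid = lambda_grid
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _design(self, X: pd.DataFrame):
        names = list(X.columns)
        unpen = [] if self.shrink_covariates else [
            c for c in self.unpenalized if c in names
        ]
        pen = [c for c in names if c not in unpen]
        Xu = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in unpen])
        Xp = X[pen].to_numpy(float)
        if self.shrink_covariates:
            cov_cols = [c for c in self.unpenalized if c in pen]
            idx = [pen.index(c) for c in cov_cols]
            self._cov_scale_ = {}
            for c, j in zip(cov_cols, idx):
                mu, sd = Xp[:, j].mean(), Xp[:, j].std(ddof=1)
                sd = sd if sd > 0 else 1.0
                self._cov_scale_[c] = (mu, sd)
        return Xu, Xp, unpen, pen

    def _apply_cov_scale(self, Xp, pen):
        if getattr(self, "_cov_scale_", None):
            Xp = Xp.copy()
            for c, (mu, sd) in self._cov_scale_.items():
                j = pen.index(c)
                Xp[:, j] = (Xp[:, j] - mu) / sd
        return Xp

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if X.isna().to_numpy().any() or np.isnan(y).any():
            raise ValueError("missing values are not supported")
        n = len(y)
        if n < 2:
            raise ValueError("need at least 2 samples")

        self._cov_scale_ = {}
        Xu, Xp, unpen, pen = self._design(X)
        Xp = self._apply_cov_scale(Xp, pen)

        y_mean = y.mean()
        y_sd = y.std(ddof=1)
        y_sd = y_sd if y_sd > 0 else 1.0
        ys = (y - y_mean) / y_sd

        lam = self.lam
        grid = DEFAULT_LAMBDA_GRID if self.lambda_grid is None else np.asarray(self.lambda_grid)
        if lam == "optimize":
            lam, self.cv_mse_path_ = self._optimize_lambda(Xu, Xp, ys, grid)
        else:
            lam = float(lam)
            self.cv_mse_path_ = None

        if lam == 0.0:
            full = np.column_stack([Xu, Xp])
            if full.shape[1] > n or np.linalg.matrix_rank(full) < full.shape[1]:
                raise ValueError(
                    "lambda=0 requires a full-rank design with p < n; "
                    "use a positive lambda for this problem size"
                )
            sol, *_ = np.linalg.lstsq(full, ys, rcond=None)
            gamma, beta_p = sol[: Xu.shape[1]], sol[Xu.shape[1]:]
        else:
            Xp_t, ys_t = _residualize(Xu, Xp, ys)
            beta_p = _coef_path(Xp_t, ys_t, [lam], self.penalty, self.l1_ratio)[:, 0]
            gamma = _gamma_for(Xu, ys, Xp, beta_p[:, None])[:, 0]

        # back to response units; covariate z-scoring folded into coef/intercept
        coef = pd.Series(0.0, index=pd.Index(list(X.columns), name="feature"))
        for j, c in enumerate(unpen):
            coef[c] = gamma[1 + j] * y_sd
        intercept = y_mean + gamma[0] * y_sd
        for j, c in enumerate(pen):
            b = beta_p[j] * y_sd
            if c in self._cov_scale_:
                mu, sd = self._cov_scale_[c]
                b = b / sd
                intercept -= b * mu
            coef[c] = b
        # the z-scored-covariate mean shift for penalized covariates is folded
        # into the intercept above; pure lipid features are already standardized
        self.coef_series_ = coef
        self.coef_ = coef.to_numpy()
        self.intercept_ = float(intercept)
        self.lambda_ = float(lam)
        self.feature_names_in_ = np.asarray(X.columns)
        self.penalized_features_ = pen
        self.unpenalized_features_ = unpen
        self.n_features_selected_ = int(np.sum(coef[pen].to_numpy() != 0.0))
        self.y_mean_, self.y_sd_ = float(y_mean), float(y_sd)
        return self

    def _optimize_lambda(self, Xu, Xp, ys, grid):
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        mse = np.zeros(len(grid))
        for tr, va in kf.split(Xp):
            Xp_t, ys_t = _residualize(Xu[tr], Xp[tr], ys[tr])
            coefs = _coef_path(Xp_t, ys_t, grid, self.penalty, self.l1_ratio)
            gam = _gamma_for(Xu[tr], ys[tr], Xp[tr], coefs)
            pred = Xu[va] @ gam + Xp[va] @ coefs
            mse += np.mean((ys[va][:, None] - pred) ** 2, axis=0)
        mse /= self.cv
        return float(grid[int(np.argmin(mse))]), mse

    # ------------------------------------------------------------------
    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        Xa = X[list(self.feature_names_in_)].to_numpy(float)
        return self.intercept_ + Xa @ self.coef_


# ----------------------------------------------------------------------
def variance_explained(pred, y, method: str = "pearson") -> float:
    """Variance of y explained by pred.

    ``method="pearson"`` (primary): squared Pearson correlation — symmetric
    and sign-invariant.  ``method="sse"``: 1 - SSE/SST.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape or pred.size < 2:
        raise ValueError("pred and y must have equal length >= 2")
    if np.std(y) == 0 or np.std(pred) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r = np.corrcoef(pred, y)[0, 1]
        return float(r * r)
    if method == "sse":
        return float(1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))
    raise ValueError("method must be 'pearson' or 'sse'")


# ----------------------------------------------------------------------
@dataclass
class CvPrediction:
    """Stitched out-of-fold predictions plus per-fold fit metadata."""

    pbmi: pd.Series
    fold: pd.Series
    fold_lambdas: list
    models: list = field(default_factory=list)
    scalers: list = field(default_factory=list)

    @property
    def lambda_mean(self) -> float:
        return float(np.mean(self.fold_lambdas))

    @property
    def lambda_range(self) -> tuple:
        return float(np.min(self.fold_lambdas)), float(np.max(self.fold_lambdas))


def _split_columns(features: pd.DataFrame, spec: ModelSpec):
    covars = [c for c in spec.unpenalized if c in features.columns]
    lipid_cols = [c for c in features.columns if c not in covars]
    return lipid_cols, covars


def crossval_predict(features: pd.DataFrame, y, spec: ModelSpec) -> CvPrediction:
    """Out-of-fold BMI predictions with per-fold standardization and lambda.

    ``features`` holds raw (positive) lipid concentration columns plus the
    covariate columns named in ``spec.unpenalized``.  Within each training
    fold the lipid columns are log10-standardized and, when requested, lambda
    is optimized by inner CV — the held-out tenth never influences either.
    """
    spec.validate()
    y = np.asarray(y, dtype=float)
    n = len(features)
    if spec.folds > n:
        raise ValueError("more folds than samples")
    lipid_cols, covars = _split_columns(features, spec)

    kf = KFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    pbmi = pd.Series(np.nan, index=features.index, name="pbmi")
    fold_id = pd.Series(-1, index=features.index, name="fold")
    fold_lambdas, models, scalers = [], [], []
    for k, (tr, va) in enumerate(kf.split(features)):
        scaler = LipidStandardizer().fit(features.iloc[tr][lipid_cols])
        X_tr = pd.concat(
            [scaler.transform(features.iloc[tr][lipid_cols]),
             features.iloc[tr][covars]], axis=1)
        X_va = pd.concat(
            [scaler.transform(features.iloc[va][lipid_cols]),
             features.iloc[va][covars]], axis=1)
        reg = RegularizedBmiRegressor(
            penalty=spec.penalty, lam=spec.lam, l1_ratio=spec.l1_ratio,
            unpenalized=tuple(covars), shrink_covariates=spec.shrink_covariates,
            cv=spec.inner_folds, lambda_grid=spec.lambda_grid,
            random_state=spec.seed + k,
        ).fit(X_tr, y[tr])
        pbmi.iloc[va] = reg.predict(X_va)
        fold_id.iloc[va] = k
        fold_lambdas.append(reg.lambda_)
        models.append(reg)
        scalers.append(scaler)
    return CvPrediction(pbmi, fold_id, fold_lambdas, models, scalers)


# ----------------------------------------------------------------------
@dataclass
class FittedBmiModel:
    """Serializable full-data model: coefficients + feature scaling + line."""

    penalty: str
    lam: float
    l1_ratio: float
    intercept: float
    coefficients: dict
    scaler_params: dict
    covariates: list
    reference_line: dict | None = None
    seed: int | None = None
    version: str = _pkg_version

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedBmiModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_bmi_model(features: pd.DataFrame, y, spec: ModelSpec,
                  lam: float | None = None) -> FittedBmiModel:
    """Fit the full-data model used for external cohorts.

    ``lam`` overrides ``spec.lam`` (typically with the mean of the per-fold
    optimal lambdas from :func:`crossval_predict`); otherwise ``spec.lam``
    (or its inner-CV optimum) is used.
    """
    spec.validate()
    lipid_cols, covars = _split_columns(features, spec)
    scaler = LipidStandardizer().fit(features[lipid_cols])
    X = pd.concat([scaler.transform(features[lipid_cols]), features[covars]], axis=1)
    reg = RegularizedBmiRegressor(
        penalty=spec.penalty, lam=spec.lam if lam is None else float(lam),
        l1_ratio=spec.l1_ratio, unpenalized=tuple(covars),
        shrink_covariates=spec.shrink_covariates, cv=spec.inner_folds,
        lambda_grid=spec.lambda_grid, random_state=spec.seed,
    ).fit(X, y)
    return FittedBmiModel(
        penalty=spec.penalty, lam=reg.lambda_, l1_ratio=spec.l1_ratio,
        intercept=reg.intercept_,
        coefficients=reg.coef_series_.to_dict(),
        scaler_params=scaler.to_params(),
        covariates=covars, seed=spec.seed,
    )


def external_apply(model: FittedBmiModel, X_new: pd.DataFrame) -> pd.Series:
    """Predict BMI on a new cohort with a frozen model (never refits).

    ``X_new`` holds raw concentration columns for the model's lipid features
    plus its covariate columns; alignment is by name, so column order is
    irrelevant.  The model's stored log10-standardization parameters are
    applied — the new cohort's own means and SDs are never used.
    """
    scaler = LipidStandardizer.from_params(model.scaler_params)
    lipid_cols = list(scaler.feature_names_in_)
    missing = [c for c in lipid_cols + model.covariates if c not in X_new.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing[:10]}")
    Z = pd.concat([scaler.transform(X_new[lipid_cols]), X_new[model.covariates]], axis=1)
    coef = pd.Series(model.coefficients)
    pred = model.intercept + Z[coef.index].to_numpy(float) @ coef.to_numpy()
    return pd.Series(pred, index=X_new.index, name="pbmi")


# ----------------------------------------------------------------------
def lambda_sweep(features: pd.DataFrame, y, penalty: str = "lasso",
                 n_points: int = 120, log10_range=(-4.0, 0.2),
                 l1_ratio: float = 0.5, unpenalized=("age", "sex"),
                 shrink_covariates: bool = False) -> pd.DataFrame:
    """Characterize the regularization path on one cohort.

    For each lambda on the grid: the number of penalized features retained,
    in-sample R^2(pBMI, BMI), R^2(mBMI, BMI) after re-deriving the reference
    line at that lambda, and the in-sample MSE.  With ``shrink_covariates``
    the LASSO end of the grid collapses to the intercept-only model, where
    mBMI equals BMI identically and R^2(mBMI, BMI) is exactly 1.
    """
    from .scoring import fit_reference_line, compute_mbmi

    y = np.asarray(y, dtype=float)
    grid = np.logspace(log10_range[0], log10_range[1], n_points)
    lipid_cols, covars = _split_columns(
        features, ModelSpec(unpenalized=tuple(unpenalized)))
    scaler = LipidStandardizer().fit(features[lipid_cols])
    X = pd.concat([scaler.transform(features[lipid_cols]), features[covars]], axis=1)

    reg = RegularizedBmiRegressor(
        penalty=penalty, lam=1.0, l1_ratio=l1_ratio,
        unpenalized=tuple(covars), shrink_covariates=shrink_covariates)
    Xu, Xp, unpen, pen = reg._design(X)
    Xp = reg._apply_cov_scale(Xp, pen)
    y_mean, y_sd = y.mean(), y.std(ddof=1)
    ys = (y - y_mean) / y_sd
    Xp_t, ys_t = _residualize(Xu, Xp, ys)
    coefs = _coef_path(Xp_t, ys_t, grid, penalty, l1_ratio)
    gammas = _gamma_for(Xu, ys, Xp, coefs)
    preds = y_mean + y_sd * (Xu @ gammas + Xp @ coefs)

    rows = []
    for j, lam in enumerate(grid):
        pbmi = preds[:, j]
        if penalty == "ridge":
            n_feat = Xp.shape[1]
        else:
            n_feat = int(np.sum(coefs[:, j] != 0.0))
        if np.ptp(pbmi) == 0:
            # constant pBMI: flat reference line, mBMIdelta identically 0,
            # mBMI = BMI — the sample-correlation formula is undefined here,
            # so the closed-form limit is reported
            r2_p, r2_m = 0.0, 1.0
        else:
            r2_p = variance_explained(pbmi, y)
            line = fit_reference_line(pbmi, y)
            scores = compute_mbmi(y, pbmi, line)
            r2_m = variance_explained(scores["mbmi"].to_numpy(), y)
        rows.append({
            "lambda": float(lam), "log10_lambda": float(np.log10(lam)),
            "n_features_selected": n_feat, "r2_pbmi": r2_p, "r2_mbmi": r2_m,
            "mse": float(np.mean((y - pbmi) ** 2)),
        })
    return pd.DataFrame(rows)


def fit_regularized(X: pd.DataFrame, y, spec: ModelSpec) -> RegularizedBmiRegressor:
    """Fit one regularized model on an already-standardized design."""
    spec.validate()
    return RegularizedBmiRegressor(
        penalty=spec.penalty, lam=spec.lam, l1_ratio=spec.l1_ratio,
        unpenalized=tuple(spec.unpenalized),
        shrink_covariates=spec.shrink_covariates, cv=spec.inner_folds,
        lambda_grid=spec.lambda_grid, random_state=spec.seed,
    ).fit(X, y)
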