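"""Downstream epidemiological statistics for the mBMI scores.

Per-species association scans (log10 lipid ~ predictor + covariates, with
percent-difference back-transform and Benjamini–Hochberg control), the
coefficient-mirroring diagnostic between BMI and mBMIdelta effect profiles,
quintile trait trends and discordant-group contrasts, logistic and Cox
(age-as-time-scale, delayed entry) outcome models, nested-model AIC/LRT
comparison, and diet/lifestyle regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from lifelines import CoxPHFitter
from statsmodels.stats.multitest import multipletests

from .tables import LipidTable


# ----------------------------------------------------------------------
def _design_matrix(predictor: pd.Series, covariates: pd.DataFrame | None):
    cols = [np.ones(len(predictor)), np.asarray(predictor, dtype=float)]
    names = ["const", predictor.name or "predictor"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(float))
            names.append(c)
    return np.column_stack(cols), names


def lipid_association(
    lipids: LipidTable | pd.DataFrame,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Per-species OLS of log10 concentration on a predictor plus covariates.

    Effects are reported both as ``beta`` (per-unit change on the log10
    concentration scale) and as ``percent_diff = (10**beta - 1) * 100``, the
    % change in concentration per unit of the predictor.  Wald CIs, two-sided
    p-values, and BH q-values across the species family.  Zero-variance
    species are skipped and flagged.
    """
    data = lipids.data if isinstance(lipids, LipidTable) else lipids
    data = data.loc[predictor.index]
    X, _ = _design_matrix(predictor, None if covariates is None
                          else covariates.loc[predictor.index])
    Y = np.log10(data.to_numpy(float))
    n, k = X.shape

    keep = Y.std(axis=0) > 0
    skipped = list(data.columns[~keep])
    Yk = Y[:, keep]

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Yk)                      # k x p, all species at once
    resid = Yk - X @ B
    sigma2 = (resid**2).sum(axis=0) / (n - k)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))

    beta, beta_se = B[1], se[1]
    tstat = beta / beta_se
    p = 2.0 * st.t.sf(np.abs(tstat), df=n - k)
    tcrit = st.t.ppf(0.5 + conf_level / 2.0, df=n - k)
    lo, hi = beta - tcrit * beta_se, beta + tcrit * beta_se
    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({
        "beta": beta,
        "se": beta_se,
        "percent_diff": (np.power(10.0, beta) - 1.0) * 100.0,
        "ci_low": (np.power(10.0, lo) - 1.0) * 100.0,
        "ci_high": (np.power(10.0, hi) - 1.0) * 100.0,
        "p": p,
        "q": q,
    }, index=pd.Index(data.columns[keep], name="species_id"))
    out.attrs["skipped_zero_variance"] = skipped
    out.attrs["predictor"] = predictor.name
    return out


@dataclass
class MirrorStats:
    """Agreement between BMI and mBMIdelta per-species effect profiles."""

    r_squared: float      # squared Pearson correlation of the beta vectors
    amplification: float  # OLS slope of beta_mbmi_delta on beta_bmi


def coefficient_mirror(records_bmi: pd.DataFrame,
                       records_delta: pd.DataFrame) -> MirrorStats:
    if not records_bmi.index.equals(records_delta.index):
        raise ValueError("association records cover different species sets")
    x = records_bmi["beta"].to_numpy(float)
    y = records_delta["beta"].to_numpy(float)
    r = np.corrcoef(x, y)[0, 1]
    xc = x - x.mean()
    slope = float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))
    return MirrorStats(r_squared=float(r * r), amplification=slope)


# ----------------------------------------------------------------------
def zscore(values) -> np.ndarray:
    """(x - mean) / sample SD; errors on constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant trait; z-score undefined")
    out = (x - x.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def _quintile_index(quintiles: pd.Series) -> np.ndarray:
    idx = quintiles.astype(str).str.removeprefix("Q").astype(int)
    if not set(idx.unique()) <= {1, 2, 3, 4, 5}:
        raise ValueError("quintile labels must be Q1..Q5")
    return idx.to_numpy()


def trait_quintile_trend(trait: pd.Series, quintiles: pd.Series):
    """OLS slope of the z-scored trait on the numeric quintile index (1-5)."""
    q = _quintile_index(quintiles.loc[trait.index])
    if len(np.unique(q)) < 2:
        raise ValueError("need at least two distinct quintiles")
    X = sm.add_constant(q.astype(float))
    fit = sm.OLS(np.asarray(zscore(trait)), X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def discordant_contrast(
    trait: pd.Series,
    quintiles: pd.Series,
    covariates: pd.DataFrame | None = None,
    conf_level: float = 0.95,
):
    """Q5-vs-Q1 fold difference of a positive trait, covariate-adjusted.

    Restricts to the discordant groups, regresses ln(trait) on a Q5 indicator
    (Q1 reference) plus covariates, and back-transforms the indicator
    coefficient to a fold difference with Wald CI.
    """
    q = quintiles.loc[trait.index]
    mask = q.isin(["Q1", "Q5"])
    t = trait.loc[mask]
    if (t <= 0).any():
        raise ValueError("trait must be strictly positive for fold differences")
    ind = (q.loc[mask] == "Q5").astype(float)
    parts = [np.ones(mask.sum()), ind.to_numpy()]
    names = ["const", "Q5"]
    if covariates is not None:
        cov = covariates.loc[t.index]
        parts += [cov[c].to_numpy(float) for c in cov.columns]
        names += list(cov.columns)
    fit = sm.OLS(np.log(t.to_numpy(float)), np.column_stack(parts)).fit()
    ci = fit.conf_int(alpha=1 - conf_level)[1]
    return {
        "fold_difference": float(np.exp(fit.params[1])),
        "ci_low": float(np.exp(ci[0])),
        "ci_high": float(np.exp(ci[1])),
        "p": float(fit.pvalues[1]),
        "n": int(mask.sum()),
    }


# ----------------------------------------------------------------------
@dataclass
class OutcomeEffect:
    """One contrast from an outcome model (odds or hazard ratio)."""

    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_cases: int
    n_controls: int
    covariates: tuple = ()
    kind: str = "OR"
    flags: tuple = ()


def _effects_frame(effects: list[OutcomeEffect]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in effects]).set_index("contrast")


def outcome_logistic(
    outcome: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Logistic regression of a binary outcome on mBMIdelta (or quintiles).

    A numeric predictor yields one per-unit odds ratio; a quintile-labelled
    predictor yields Q2..Q5 contrasts against the Q1 reference.  Wald CIs;
    quasi-separation is detected (divergent coefficients) and flagged.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if predictor.dtype == object or str(predictor.dtype) == "category":
        dummies = pd.get_dummies(
            pd.Categorical(predictor, categories=[f"Q{i}" for i in range(1, 6)]),
            drop_first=True, dtype=float)
        dummies.index = predictor.index
        Xdf = dummies
        contrasts = [f"{c} vs Q1" for c in dummies.columns]
    else:
        Xdf = predictor.to_frame()
        contrasts = [f"per unit {predictor.name or 'predictor'}"]
    if covariates is not None:
        Xdf = pd.concat([Xdf, covariates.loc[Xdf.index]], axis=1)
    X = sm.add_constant(Xdf.to_numpy(float))

    flags: list[str] = []
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:  # perfect separation raises in statsmodels
        raise ValueError(f"logistic fit failed (separation?): {err}") from err
    if not fit.mle_retvals.get("converged", True) or np.max(np.abs(fit.params)) > 15:
        flags.append("possible quasi-separation")

    ci = fit.conf_int(alpha=1 - conf_level)
    cov_names = tuple(covariates.columns) if covariates is not None else ()
    effects = []
    for j, name in enumerate(contrasts, start=1):
        effects.append(OutcomeEffect(
            contrast=name,
            estimate=float(np.exp(fit.params[j])),
            ci_low=float(np.exp(ci[j][0])),
            ci_high=float(np.exp(ci[j][1])),
            p=float(fit.pvalues[j]),
            n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
            covariates=cov_names, kind="OR", flags=tuple(flags),
        ))
    out = _effects_frame(effects)
    out.attrs["loglik"] = float(fit.llf)
    out.attrs["aic"] = float(fit.aic)
    return out


def outcome_cox(
    event: pd.Series,
    entry_age: pd.Series,
    exit_age: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Cox proportional hazards with age as the time scale (delayed entry).

    Participants enter the risk set at their baseline age and exit at the age
    of event or censoring; ties use the Efron approximation (lifelines
    default).  Returns per-unit hazard ratios with Wald CIs.
    """
    if (np.asarray(exit_age) <= np.asarray(entry_age)).any():
        raise ValueError("exit age must exceed entry age for every sample")
    if np.asarray(event).sum() < 1:
        raise ValueError("no events")
    df = pd.DataFrame({
        "entry": np.asarray(entry_age, float),
        "exit": np.asarray(exit_age, float),
        "event": np.asarray(event, float),
        "x": np.asarray(predictor, float),
    })
    cov_names: tuple = ()
    if covariates is not None:
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy(float)
        cov_names = tuple(covariates.columns)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="exit", event_col="event", entry_col="entry")
    z = st.norm.ppf(0.5 + conf_level / 2.0)
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    effect = OutcomeEffect(
        contrast=f"per unit {predictor.name or 'predictor'}",
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p=float(cph.summary.loc["x", "p"]),
        n_cases=int(df["event"].sum()),
        n_controls=int((df["event"] == 0).sum()),
        covariates=cov_names, kind="HR",
    )
    out = _effects_frame([effect])
    out.attrs["loglik"] = float(cph.log_likelihood_)
    return out


# ----------------------------------------------------------------------
@dataclass
class NestedComparison:
    """AIC and likelihood-ratio comparison of nested outcome models."""

    aic_with: float
    aic_without: float
    lrt_stat: float
    lrt_p: float
    df_diff: int


def nested_model_comparison(
    outcome: pd.Series,
    base_covariates: pd.DataFrame,
    added: pd.Series,
) -> NestedComparison:
    """Compare logistic models with and without an added term (e.g. mBMIdelta).

    Both models are maximum-likelihood logistic fits on the identical sample;
    AIC = 2k - 2 loglik, LRT statistic 2*(ll_with - ll_without) against
    chi-square with the added degrees of freedom.
    """
    if not outcome.index.equals(base_covariates.index):
        raise ValueError("outcome and covariates must cover identical samples")
    y = np.asarray(outcome, dtype=float)
    X0 = sm.add_constant(base_covariates.to_numpy(float))
    X1 = sm.add_constant(
        pd.concat([base_covariates, added.loc[outcome.index]], axis=1).to_numpy(float))
    # IRLS with pinv tolerates exactly collinear added terms (delta-ll = 0)
    family = sm.families.Binomial()
    fit0 = sm.GLM(y, X0, family=family).fit()
    fit1 = sm.GLM(y, X1, family=family).fit()
    stat = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    df_diff = X1.shape[1] - X0.shape[1]
    # AIC with k = parameters as specified (not design rank)
    return NestedComparison(
        aic_with=float(2.0 * X1.shape[1] - 2.0 * fit1.llf),
        aic_without=float(2.0 * X0.shape[1] - 2.0 * fit0.llf),
        lrt_stat=float(stat),
        lrt_p=float(st.chi2.sf(stat, df=df_diff)),
        df_diff=int(df_diff),
    )


# ----------------------------------------------------------------------
def lifestyle_association(
    mbmi_delta: pd.Series,
    exposure_quintiles: pd.Series,
    covariates: pd.DataFrame,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """OLS of mBMIdelta on exposure-quintile indicators plus covariates.

    One row per Q2..Q5 contrast against the Q1 reference, with beta in kg/m^2
    of mBMIdelta, Wald CI and two-sided p.  The covariate set distinguishes
    the minimally-adjusted model (age, sex, BMI) from the fully-adjusted one;
    collinear covariates surface as a reported error.
    """
    dummies = pd.get_dummies(
        pd.Categorical(exposure_quintiles, categories=[f"Q{i}" for i in range(1, 6)]),
        drop_first=True, dtype=float)
    dummies.index = exposure_quintiles.index
    Xdf = pd.concat([dummies, covariates.loc[dummies.index]], axis=1)
    X = sm.add_constant(Xdf.to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in the lifestyle model")
    fit = sm.OLS(np.asarray(mbmi_delta.loc[dummies.index], float), X).fit()
    ci = fit.conf_int(alpha=1 - conf_level)
    rows = []
    for j, name in enumerate(dummies.columns, start=1):
        rows.append({
            "contrast": f"{name} vs Q1",
            "beta": float(fit.params[j]),
            "ci_low": float(ci[j][0]),
            "ci_high": float(ci[j][1]),
            "p": float(fit.pvalues[j]),
        })
    return pd.DataFrame(rows).set_index("contrast")
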