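"""Lipidomic pre-processing: batch median-centring, %CV, log-standardization.

Batch correction is multiplicative on the concentration scale: within each
batch, every species is rescaled so the batch's pooled-QC (PQC) median matches
the across-batch global PQC median.  After the downstream log10 transform this
is an additive per-batch offset, which is why the multiplicative form is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .tables import LipidTable


# ----------------------------------------------------------------------
class BatchMedianCenterer(BaseEstimator, TransformerMixin):
    """Align per-batch PQC medians to the global PQC median.

    ``fit`` learns one multiplicative factor per (batch, species) from the PQC
    rows of a :class:`LipidTable`; ``transform`` applies those factors to every
    sample in the batch (cohort and QC alike), preserving positivity.
    """

    def __init__(self, qc_type: str = "PQC"):
        self.qc_type = qc_type

    def fit(self, table: LipidTable, y=None):
        table.validate_positive()
        qc = table.subset(sample_type=self.qc_type)
        batches = list(dict.fromkeys(table.samples["batch"]))
        missing = [b for b in batches
                   if (qc.samples["batch"] == b).sum() == 0]
        if missing:
            raise ValueError(
                f"batches without any {self.qc_type} sample: {missing}"
            )
        global_median = qc.data.median(axis=0)
        factors = {}
        for b in batches:
            batch_median = qc.subset(batch=b).data.median(axis=0)
            if (batch_median <= 0).any():
                bad = batch_median.index[batch_median <= 0]
                raise ValueError(
                    f"non-positive {self.qc_type} median in batch {b} for "
                    f"species {list(bad[:5])}"
                )
            factors[b] = global_median / batch_median
        self.global_median_ = global_median
        self.factors_ = pd.DataFrame(factors).T  # batches x species
        return self

    def transform(self, table: LipidTable) -> LipidTable:
        check_is_fitted(self, "factors_")
        out = table.copy()
        for b, factors in self.factors_.iterrows():
            mask = out.samples["batch"] == b
            if mask.any():
                out.data.loc[mask] = out.data.loc[mask] * factors[out.data.columns]
        return out


def batch_median_center(table: LipidTable, qc_type: str = "PQC") -> LipidTable:
    """Fit-and-apply batch median-centring on one table."""
    return BatchMedianCenterer(qc_type=qc_type).fit(table).transform(table)


# ----------------------------------------------------------------------
def compute_cv(replicates: LipidTable, group: str | None = None):
    """Per-species %CV (100 * sample SD / mean, concentration scale).

    Parameters
    ----------
    replicates:
        Table of replicate measurements.
    group:
        Optional ``sample_type`` to restrict to (e.g. ``"PQC"``/``"NIST"``).

    Returns
    -------
    (cv, summary):
        ``cv`` — per-species %CV Series; ``summary`` — dict with the median
        %CV and the fraction of species under 20%.
    """
    table = replicates if group is None else replicates.subset(sample_type=group)
    if table.n_samples < 2:
        raise ValueError("need at least 2 replicates to compute %CV")
    values = table.data
    mean = values.mean(axis=0)
    if (mean == 0).any():
        raise ValueError(
            f"zero-mean species: {list(mean.index[mean == 0][:5])}"
        )
    cv = 100.0 * values.std(axis=0, ddof=1) / mean
    summary = {
        "median_cv": float(cv.median()),
        "fraction_below_20": float((cv < 20.0).mean()),
        "n_replicates": int(table.n_samples),
    }
    return cv, summary


# ----------------------------------------------------------------------
@dataclass
class StandardizedMatrix:
    """Log10-transformed, mean-centred, unit-SD matrix plus its parameters."""

    values: pd.DataFrame
    mean: pd.Series     # per-species mean of log10 values on the fitting set
    sd: pd.Series       # per-species sample SD (ddof=1) of log10 values
    zero_sd_species: list


class LipidStandardizer(BaseEstimator, TransformerMixin):
    """log10 -> centre -> scale transformer with reusable parameters.

    Fitted on one cohort (or one training fold) and applied to new data with
    the *stored* means and SDs, never the new data's own.  Species with zero
    SD on the fitting set are retained with standardized value 0 and flagged
    in ``zero_sd_species_`` so feature indices stay aligned across cohorts.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = self._as_frame(X)
        if (X.to_numpy() <= 0).any():
            bad = X.columns[(X <= 0).any(axis=0)]
            raise ValueError(f"non-positive concentrations in: {list(bad[:5])}")
        logged = np.log10(X)
        self.mean_ = logged.mean(axis=0)
        self.sd_ = logged.std(axis=0, ddof=1)
        self.zero_sd_species_ = list(self.sd_.index[self.sd_ == 0])
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = self._as_frame(X)[list(self.feature_names_in_)]
        if (X.to_numpy() <= 0).any():
            bad = X.columns[(X <= 0).any(axis=0)]
            raise ValueError(f"non-positive concentrations in: {list(bad[:5])}")
        sd = self.sd_.replace(0.0, 1.0)  # zero-SD species map to 0, not NaN
        return (np.log10(X) - self.mean_) / sd

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        sd = self.sd_.replace(0.0, 1.0)
        return np.power(10.0, Z * sd + self.mean_)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, LipidTable):
            return X.data
        return pd.DataFrame(X)

    def to_params(self) -> dict:
        check_is_fitted(self, "mean_")
        return {
            "mean": self.mean_.to_dict(),
            "sd": self.sd_.to_dict(),
            "zero_sd_species": list(self.zero_sd_species_),
        }

    @classmethod
    def from_params(cls, params: dict) -> "LipidStandardizer":
        obj = cls()
        obj.mean_ = pd.Series(params["mean"])
        obj.sd_ = pd.Series(params["sd"])
        obj.zero_sd_species_ = list(params["zero_sd_species"])
        obj.feature_names_in_ = np.asarray(obj.mean_.index)
        return obj


def log_scale_standardize(
    table: LipidTable | pd.DataFrame, fit_on: pd.Series | np.ndarray | None = None
) -> tuple[StandardizedMatrix, LipidStandardizer]:
    """Standardize a lipid table, optionally fitting on a sample subset.

    ``fit_on`` is a boolean mask selecting the rows whose means/SDs define the
    transform (default: all rows); all rows are transformed with the stored
    parameters.
    """
    X = LipidStandardizer._as_frame(table)
    fit_X = X if fit_on is None else X.loc[np.asarray(fit_on)]
    scaler = LipidStandardizer().fit(fit_X)
    values = scaler.transform(X)
    matrix = StandardizedMatrix(
        values=values,
        mean=scaler.mean_,
        sd=scaler.sd_,
        zero_sd_species=scaler.zero_sd_species_,
    )
    return matrix, scaler
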