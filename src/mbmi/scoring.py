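"""Metabolic BMI (mBMI) score construction.

Given out-of-fold predicted BMI (pBMI), the score is built around the
ordinary-least-squares *reference line* of pBMI on measured BMI:

    mBMI      = BMI + (pBMI - (a + b * BMI))
    mBMIdelta = mBMI - BMI

Regressing pBMI (response) on BMI (regressor) makes mBMIdelta an OLS
residual, hence exactly mean-zero and uncorrelated with BMI on the cohort the
line was fitted on — the "independent of measured BMI" property the score is
built for.  On external cohorts scored with a frozen line neither identity
need hold; that is a contract, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

#: Priority order for distributing the remainder when n is not divisible by
#: 5: outermost groups first, the deficit lands on the middle group(s).
_QUINTILE_PRIORITY = (0, 4, 1, 3, 2)


@dataclass
class ReferenceLine:
    """OLS line of best fit of pBMI on BMI: pBMI ~ a + b * BMI."""

    intercept: float  # a, kg/m^2
    slope: float      # b, dimensionless

    def predict(self, bmi) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(bmi, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceLine":
        return cls(intercept=float(d["intercept"]), slope=float(d["slope"]))


def fit_reference_line(pbmi, bmi) -> ReferenceLine:
    """Fit the reference line on the score-defining cohort."""
    pbmi = np.asarray(pbmi, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if pbmi.size < 3:
        raise ValueError("need at least 3 samples to fit the reference line")
    bmi_c = bmi - bmi.mean()
    denom = np.sum(bmi_c**2)
    if denom == 0:
        raise ValueError("BMI is constant; reference line undefined")
    slope = float(np.sum(bmi_c * (pbmi - pbmi.mean())) / denom)
    intercept = float(pbmi.mean() - slope * bmi.mean())
    return ReferenceLine(intercept=intercept, slope=slope)


def compute_mbmi(bmi, pbmi, line: ReferenceLine) -> pd.DataFrame:
    """mBMI and mBMIdelta for each sample (no quintiles yet)."""
    if line is None:
        raise ValueError("reference line is required; fit or load one first")
    bmi = np.asarray(bmi, dtype=float)
    pbmi = np.asarray(pbmi, dtype=float)
    delta = pbmi - line.predict(bmi)
    return pd.DataFrame({
        "pbmi": pbmi,
        "mbmi": bmi + delta,
        "mbmi_delta": delta,
    })


def assign_quintiles(mbmi_delta) -> tuple[pd.Series, dict]:
    """Rank-based partition into Q1..Q5 (Q1 lowest mBMIdelta, Q5 highest).

    Groups are contiguous in the sorted order, as equal as possible; when n is
    not a multiple of 5 the extra members go to the outermost groups first, so
    the deficit sits in the middle (n=10,339 gives 2068/2068/2067/2068/2068).
    Ties are broken by stable input order.
    """
    values = np.asarray(mbmi_delta, dtype=float)
    n = values.size
    if n < 5:
        raise ValueError("need at least 5 samples for quintiles")
    base, rem = divmod(n, 5)
    sizes = [base] * 5
    for j in _QUINTILE_PRIORITY[:rem]:
        sizes[j] += 1
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=object)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = f"Q{q}"
        start += size
    index = mbmi_delta.index if isinstance(mbmi_delta, pd.Series) else None
    out = pd.Series(labels, index=index, name="quintile")
    return out, {f"Q{q}": s for q, s in enumerate(sizes, start=1)}


def score_precision(qc_mbmi, assumed_bmi: float = 26.0) -> float:
    """%CV of replicate mBMI scores (each scored at a fixed assumed BMI)."""
    scores = np.asarray(qc_mbmi, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 replicate scores")
    return float(100.0 * scores.std(ddof=1) / scores.mean())


# ----------------------------------------------------------------------
class MbmiScorer(BaseEstimator, TransformerMixin):
    """Transformer view of the score construction.

    ``fit(pbmi, bmi)`` learns the reference line on the score-defining
    cohort; ``transform`` turns (bmi, pbmi) pairs — from the same cohort or an
    external one scored with the frozen line — into a ScoreSet table with
    pBMI, mBMI, mBMIdelta and quintile labels.
    """

    def __init__(self, assign_quintiles: bool = True):
        self.assign_quintiles = assign_quintiles

    def fit(self, pbmi, bmi=None):
        if bmi is None:
            raise ValueError("fit requires both pbmi and bmi")
        self.line_ = fit_reference_line(pbmi, bmi)
        return self

    def transform(self, bmi, pbmi=None) -> pd.DataFrame:
        check_is_fitted(self, "line_")
        if pbmi is None:
            raise ValueError("transform requires both bmi and pbmi")
        scores = compute_mbmi(np.asarray(bmi, float), np.asarray(pbmi, float), self.line_)
        if isinstance(bmi, pd.Series):
            scores.index = bmi.index
        if self.assign_quintiles:
            labels, self.quintile_sizes_ = assign_quintiles(scores["mbmi_delta"])
            scores["quintile"] = labels.to_numpy()
        return scores
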