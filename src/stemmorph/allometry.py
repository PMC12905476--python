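"""Eye-size/head-length allometry on log-log axes.

The scaling of the largest-lens diameter d with head length L is modeled as
a power law d = 10^b * L^s, i.e. a straight line in log10-log10 space:

    log10(d) = b + s * log10(L)

fitted by ordinary least squares with head length as predictor (matching
the axes of the scatterplot it summarizes). Specimens lying above the trend
line — positive vertical residual in log10 units — have disproportionately
large eyes for their head size; an optional residual cutoff separates
"above the line" from noise. Major-axis regression (principal axis of the
log-log covariance) is available for the symmetric-errors view; the
qualitative outlier calls are robust to either choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DataError, ParameterError
from .io import MeasurementRecord


@dataclass
class AllometryFit:
    slope: float
    intercept: float                   # log10 lens-diameter units
    residuals: pd.Series               # signed vertical distance, log10 units
    r_squared: float
    method: str = "ols"
    fit_group: str = "all"

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.residuals.index)


class LogLogAllometry(RegressorMixin, BaseEstimator):
    """Power-law regression of lens diameter on head length.

    Parameters
    ----------
    method : {"ols", "major_axis"}, default="ols"
        "ols" minimizes vertical log10 residuals; "major_axis" takes the
        principal axis of the log-log covariance (both variables treated
        as measured with error).

    Attributes
    ----------
    slope_, intercept_ : float
        Log10-log10 line parameters.
    residuals_ : (n,) ndarray
        Signed vertical residuals in log10 units.
    r_squared_ : float
    """

    def __init__(self, method: str = "ols"):
        self.method = method

    def fit(self, X, y):
        if self.method not in ("ols", "major_axis"):
            raise ParameterError(f"unknown method {self.method!r}")
        head = np.asarray(X, dtype=float).reshape(-1)
        lens = np.asarray(y, dtype=float).reshape(-1)
        if len(head) != len(lens):
            raise ParameterError("X and y length mismatch")
        if len(head) < 3:
            raise ParameterError(f"need at least 3 records, got {len(head)}")
        if np.any(head <= 0) or np.any(lens <= 0):
            raise DataError("measurements must be strictly positive")
        lx, ly = np.log10(head), np.log10(lens)
        mx, my = lx.mean(), ly.mean()
        sxx = np.sum((lx - mx) ** 2)
        syy = np.sum((ly - my) ** 2)
        sxy = np.sum((lx - mx) * (ly - my))
        if sxx == 0:
            raise DataError("head lengths are all identical; slope undefined")
        if self.method == "ols":
            self.slope_ = sxy / sxx
        else:
            # principal axis of the 2x2 log-log covariance
            diff = syy - sxx
            self.slope_ = (diff + np.hypot(diff, 2 * sxy)) / (2 * sxy) if sxy != 0 \
                else (0.0 if sxx >= syy else np.inf)
        self.intercept_ = my - self.slope_ * mx
        self.residuals_ = ly - (self.intercept_ + self.slope_ * lx)
        self.r_squared_ = float(sxy**2 / (sxx * syy)) if syy > 0 else 1.0
        return self

    def predict(self, X):
        head = np.asarray(X, dtype=float).reshape(-1)
        return 10.0 ** (self.intercept_ + self.slope_ * np.log10(head))


def fit_loglog(records: Sequence[MeasurementRecord], method: str = "ols",
               fit_group: str = "all") -> AllometryFit:
    """Fit the log-log trend line over a set of measurement records.

    ``fit_group="extant"`` fits the line to extant specimens only while
    residuals are still reported for every specimen; default fits all.
    """
    records = list(records)
    if len(records) < 3:
        raise ParameterError(f"need at least 3 records, got {len(records)}")
    for r in records:
        if r.head_length <= 0 or r.lens_diameter <= 0:
            raise DataError(f"specimen {r.specimen_id!r}: nonpositive measurement")
    if fit_group == "all":
        fit_records = records
    elif fit_group in ("extant", "fossil", "new"):
        fit_records = [r for r in records if r.group == fit_group]
        if len(fit_records) < 3:
            raise ParameterError(
                f"fewer than 3 records in fit group {fit_group!r}"
            )
    else:
        raise ParameterError(f"unknown fit_group {fit_group!r}")
    est = LogLogAllometry(method=method).fit(
        [r.head_length for r in fit_records],
        [r.lens_diameter for r in fit_records],
    )
    all_head = np.array([r.head_length for r in records])
    all_lens = np.array([r.lens_diameter for r in records])
    resid = np.log10(all_lens) - (est.intercept_ + est.slope_ * np.log10(all_head))
    return AllometryFit(
        slope=float(est.slope_),
        intercept=float(est.intercept_),
        residuals=pd.Series(resid, index=[r.specimen_id for r in records]),
        r_squared=float(est.r_squared_),
        method=method,
        fit_group=fit_group,
    )


def flag_above_line(fit: AllometryFit, threshold: float = 0.0,
                    tol: float = 1e-12) -> list[str]:
    """Specimen ids with residual > threshold, sorted by residual descending.

    ``tol`` absorbs floating-point noise so exactly-on-the-line specimens
    are never flagged at threshold 0.
    """
    above = fit.residuals[fit.residuals > threshold + tol]
    return list(above.sort_values(ascending=False).index)
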