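"""Inter-rater reliability for multi-rater audit assessments.

During field training, every rater independently assesses the same set of
parcels, giving an n-targets x k-raters matrix per variable.  Two summaries
are computed:

* **percent agreement** — the mean over targets of the fraction of rater
  pairs giving identical ratings;
* **intraclass correlation (ICC)** under the one-way random-effects model
  (targets random; raters treated as interchangeable draws rather than a
  fixed panel).  With MSB and MSW the between- and within-target mean
  squares from the one-way ANOVA and k raters:

      ICC(1)   = (MSB - MSW) / (MSB + (k - 1) * MSW)        single rater
      ICC(1,k) = (MSB - MSW) / MSB                          mean of k raters

  linked by the Spearman-Brown relation ICC(1,k) = k*r / (1 + (k-1)*r).
  Confidence intervals come from the F distribution on (n-1, n(k-1))
  degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "percent_agreement",
    "icc_oneway",
    "stacked_matrix",
    "reliability_report",
]


def _as_matrix(m) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2:
        raise ValueError("rating matrix must be 2-D (targets x raters)")
    if np.isnan(arr).any():
        raise ValueError("rating matrix has missing cells; apply listwise deletion first")
    n, k = arr.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 2:
        raise ValueError("need at least 2 targets")
    return arr


@dataclass(frozen=True)
class ReliabilityResult:
    """ICC estimates (both one-way forms), the CI for the requested form,
    and percent agreement."""

    icc_single: float
    icc_average: float
    ci_low: float
    ci_high: float
    confidence: float
    form: str
    n_targets: int
    n_raters: int
    percent_agreement: Optional[float] = None


def percent_agreement(m) -> float:
    """Mean over targets of the fraction of rater pairs in exact agreement."""
    arr = _as_matrix(m)
    n, k = arr.shape
    pairs = list(combinations(range(k), 2))
    agree = np.mean([arr[:, i] == arr[:, j] for i, j in pairs], axis=0)
    return float(agree.mean())


def icc_oneway(m, form: str = "single", confidence: float = 0.95) -> ReliabilityResult:
    """One-way random-effects intraclass correlation with an F-based CI.

    ``form`` selects which estimate the confidence interval covers:
    ``"single"`` for ICC(1) or ``"average"`` for ICC(1,k); both point
    estimates are always returned.  Rating matrices with zero total variance
    leave the ANOVA with no information and are rejected.
    """
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    arr = _as_matrix(m)
    n, k = arr.shape

    grand = arr.mean()
    if np.allclose(arr, grand):
        raise ValueError("degenerate ratings: zero total variance, ICC undefined")

    row_means = arr.mean(axis=1)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((arr - row_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))

    if msw == 0.0:
        icc_single, icc_average = 1.0, 1.0
    else:
        icc_single = (msb - msw) / (msb + (k - 1) * msw)
        icc_average = (msb - msw) / msb if msb > 0 else -np.inf

    # F-based interval (one-way model): F0 = MSB/MSW on (n-1, n(k-1)) df.
    df1, df2 = n - 1, n * (k - 1)
    alpha = 1.0 - confidence
    if msw == 0.0:
        fl = fu = np.inf
    else:
        f0 = msb / msw
        fl = f0 / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f0 * stats.f.ppf(1 - alpha / 2, df2, df1)
    if form == "single":
        ci_low = (fl - 1) / (fl + k - 1) if np.isfinite(fl) else 1.0
        ci_high = (fu - 1) / (fu + k - 1) if np.isfinite(fu) else 1.0
        estimate = icc_single
    else:
        ci_low = 1 - 1 / fl if fl > 0 else -np.inf
        ci_high = 1 - 1 / fu if fu > 0 else -np.inf
        estimate = icc_average
    ci_low = float(min(ci_low, estimate))
    ci_high = float(max(ci_high, estimate))

    return ReliabilityResult(
        icc_single=float(icc_single),
        icc_average=float(icc_average),
        ci_low=ci_low,
        ci_high=ci_high,
        confidence=confidence,
        form=form,
        n_targets=n,
        n_raters=k,
        percent_agreement=percent_agreement(arr),
    )


def stacked_matrix(ratings: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack a long ratings table into one matrix across all variables.

    ``ratings`` has columns parcel_id, variable, rater, rating.  Each
    (variable, parcel) pair becomes one target row; targets with any missing
    rater are dropped listwise.  Returns ``(matrix, dropped)`` where
    ``dropped`` reports the excluded targets.
    """
    required = {"parcel_id", "variable", "rater", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    pivot = ratings.pivot_table(
        index=["variable", "parcel_id"], columns="rater", values="rating",
        aggfunc="first",
    )
    complete = pivot.dropna()
    dropped = pivot[pivot.isna().any(axis=1)].reset_index()[["variable", "parcel_id"]]
    return complete.to_numpy(dtype=float), dropped


def reliability_report(
    ratings: pd.DataFrame, form: str = "single", confidence: float = 0.95
) -> pd.DataFrame:
    """Per-variable reliability plus a pooled ALL row (targets stacked
    across variables, as when agreement is reported over the whole
    instrument).  Variables whose ratings are degenerate (zero variance)
    are reported with NaN ICCs rather than dropped."""
    frames = []
    groups = [("ALL", ratings)] + [
        (var, sub) for var, sub in ratings.groupby("variable", sort=True)
    ]
    for name, sub in groups:
        matrix, _ = stacked_matrix(sub)
        row = {"variable": name, "n_targets": matrix.shape[0],
               "n_raters": matrix.shape[1]}
        try:
            res = icc_oneway(matrix, form=form, confidence=confidence)
            row.update(
                icc_single=res.icc_single, icc_average=res.icc_average,
                ci_low=res.ci_low, ci_high=res.ci_high,
                percent_agreement=res.percent_agreement,
            )
        except ValueError:
            row.update(
                icc_single=np.nan, icc_average=np.nan, ci_low=np.nan,
                ci_high=np.nan, percent_agreement=percent_agreement(matrix),
            )
        frames.append(row)
    return pd.DataFrame(frames)
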