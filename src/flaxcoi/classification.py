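"""Hypertension classification and survey-weighted summary statistics.

A respondent is classified hypertensive when systolic BP is at or above the
systolic cut-point, diastolic BP is at or above the diastolic cut-point, or
they self-report use of anti-hypertensive medication.  Prevalence and mean
blood pressure are estimated as survey-weighted averages; confidence
intervals use a normal approximation on the Kish effective sample size
(design-based variance estimation with replicate weights is out of scope,
so these intervals describe the weighted sample, not the survey design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.weightstats import DescrStatsW

from .records import DEFAULT_AGE_BANDS, IndividualRecord, assign_age_band, to_frame

__all__ = [
    "Thresholds",
    "WeightedEstimate",
    "classify_hypertension",
    "hypertension_flags",
    "weighted_prevalence",
    "weighted_bp_summary",
    "kish_effective_n",
]


@dataclass(frozen=True)
class Thresholds:
    """Hypertension cut-points in mm Hg (inclusive: BP >= cut qualifies)."""

    sbp_cut: float = 140.0
    dbp_cut: float = 90.0

    def __post_init__(self) -> None:
        if not (self.sbp_cut > self.dbp_cut > 0):
            raise ValueError(
                f"require sbp_cut > dbp_cut > 0, got ({self.sbp_cut}, {self.dbp_cut})"
            )


@dataclass(frozen=True)
class WeightedEstimate:
    """A survey-weighted point estimate with a normal-approximation CI."""

    point: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    method: str = "normal_effective_n"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket {self.point}"
            )


def classify_hypertension(
    record: IndividualRecord, thresholds: Thresholds = Thresholds()
) -> int:
    """Return 1 iff the record meets any hypertension criterion, else 0."""
    return int(
        record.sbp >= thresholds.sbp_cut
        or record.dbp >= thresholds.dbp_cut
        or record.on_medication
    )


def hypertension_flags(
    records: "pd.DataFrame | Iterable[IndividualRecord]",
    thresholds: Thresholds = Thresholds(),
) -> np.ndarray:
    """Vectorised hypertension indicator (0/1 int array) over a collection."""
    df = to_frame(records)
    flags = (
        (df["sbp"].to_numpy(float) >= thresholds.sbp_cut)
        | (df["dbp"].to_numpy(float) >= thresholds.dbp_cut)
        | df["on_medication"].to_numpy(bool)
    )
    return flags.astype(int)


def kish_effective_n(weights: np.ndarray) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.sum(w**2))


def _z(confidence: float) -> float:
    if not (0 < confidence < 1):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    return float(stats.norm.ppf(0.5 + confidence / 2))


def weighted_prevalence(
    records: "pd.DataFrame | Iterable[IndividualRecord]",
    thresholds: Thresholds = Thresholds(),
    confidence: float = 0.95,
) -> WeightedEstimate:
    """Survey-weighted hypertension prevalence with a clipped normal CI.

    The point estimate is ``sum(H_i w_i) / sum(w_i)`` and is invariant to
    rescaling all weights by a positive constant.  The CI uses the binomial
    variance at the Kish effective sample size and is clipped to [0, 1].
    """
    df = to_frame(records)
    if len(df) == 0:
        raise ValueError("cannot estimate prevalence from an empty record set")
    z = _z(confidence)
    flags = hypertension_flags(df, thresholds).astype(float)
    w = df["weight"].to_numpy(float)
    point = float(np.sum(flags * w) / np.sum(w))
    n_eff = kish_effective_n(w)
    se = np.sqrt(max(point * (1 - point), 0.0) / n_eff)
    return WeightedEstimate(
        point=point,
        ci_low=float(np.clip(point - z * se, 0.0, 1.0)),
        ci_high=float(np.clip(point + z * se, 0.0, 1.0)),
        n_unweighted=len(df),
    )


def _weighted_mean_estimate(
    values: np.ndarray, weights: np.ndarray, z: float
) -> WeightedEstimate:
    d = DescrStatsW(values, weights=weights)
    n_eff = kish_effective_n(weights)
    se = float(d.std) / np.sqrt(n_eff)
    return WeightedEstimate(
        point=float(d.mean),
        ci_low=float(d.mean - z * se),
        ci_high=float(d.mean + z * se),
        n_unweighted=len(values),
    )


def weighted_bp_summary(
    records: "pd.DataFrame | Iterable[IndividualRecord]",
    group_by: Sequence[str] = (),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Weighted mean SBP/DBP (with CIs) overall or by age band and/or sex.

    Parameters
    ----------
    group_by : sequence of {"age_band", "sex"}
        Empty for a single overall row.

    Returns
    -------
    DataFrame with one row per non-empty group and columns
    ``group, n, mean_sbp, sbp_ci_low, sbp_ci_high, mean_dbp, dbp_ci_low,
    dbp_ci_high``.
    """
    df = to_frame(records).copy()
    if len(df) == 0:
        raise ValueError("cannot summarise an empty record set")
    allowed = {"age_band", "sex"}
    unknown = set(group_by) - allowed
    if unknown:
        raise ValueError(f"unknown group keys {sorted(unknown)}; allowed: {sorted(allowed)}")
    z = _z(confidence)
    if "age_band" in group_by:
        df["age_band"] = assign_age_band(df["age_years"].to_numpy())
    keys = list(group_by)
    groups = [("overall", df)] if not keys else [
        (" / ".join(map(str, k if isinstance(k, tuple) else (k,))), g)
        for k, g in df.groupby(keys, sort=True, observed=True)
    ]
    rows = []
    for label, g in groups:
        if len(g) == 0:
            continue
        w = g["weight"].to_numpy(float)
        s = _weighted_mean_estimate(g["sbp"].to_numpy(float), w, z)
        d = _weighted_mean_estimate(g["dbp"].to_numpy(float), w, z)
        rows.append(
            {
                "group": label,
                "n": len(g),
                "mean_sbp": s.point,
                "sbp_ci_low": s.ci_low,
                "sbp_ci_high": s.ci_high,
                "mean_dbp": d.point,
                "dbp_ci_low": d.ci_low,
                "dbp_ci_high": d.ci_high,
            }
        )
    return pd.DataFrame(rows)
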