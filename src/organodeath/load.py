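"""Image-based organoid-load statistics.

Three sampled load metrics per well — nuclei count, mean organoid
cross-section area and organoid count — are normalized to the day-0
control mean ("tumor growth") and each treated dose is compared with the
day-10 untreated fold changes by an unpaired t-test with Bonferroni
correction across doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import WellLoad

__all__ = [
    "LOAD_METRICS",
    "GrowthComparison",
    "wells_to_frame",
    "normalize_growth",
    "compare_to_untreated",
    "dose_response_comparisons",
]

LOAD_METRICS = ("n_nuclei", "mean_area", "n_organoids")


def wells_to_frame(wells: list[WellLoad]) -> pd.DataFrame:
    """Tidy table from a list of per-well loads."""
    return pd.DataFrame([w.as_dict() for w in wells])


def _metric_values(wells, metric: str) -> np.ndarray:
    if isinstance(wells, pd.DataFrame):
        return wells[metric].to_numpy(dtype=float)
    if isinstance(wells, (list, tuple)) and wells and isinstance(wells[0], WellLoad):
        return np.asarray([getattr(w, metric) for w in wells], dtype=float)
    return np.asarray(wells, dtype=float)


def normalize_growth(day10_wells, day0_wells, metric: str = "n_nuclei") -> np.ndarray:
    """Per-well day-10 fold changes over the pooled day-0 control mean.

    ``day10_wells``/``day0_wells`` may be WellLoad lists, DataFrames with
    a ``metric`` column, or plain value arrays.
    """
    day10 = _metric_values(day10_wells, metric)
    day0 = _metric_values(day0_wells, metric)
    if day0.size == 0:
        raise ValueError("no day-0 control wells")
    baseline = float(np.mean(day0))
    if baseline <= 0 or not np.isfinite(baseline):
        raise ValueError(f"day-0 mean of {metric!r} must be positive, got {baseline}")
    return day10 / baseline


@dataclass(frozen=True)
class GrowthComparison:
    """Treated-vs-untreated growth comparison for one metric and dose."""

    metric: str
    dose: float
    fold_change_treated: float  # mean over treated wells
    fold_change_untreated: float
    t_statistic: float
    p_value: float
    adjusted_p: float  # Bonferroni: min(1, p * n_comparisons)
    significant: bool  # adjusted_p < 0.05

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "dose": self.dose,
            "fold_change_treated": self.fold_change_treated,
            "fold_change_untreated": self.fold_change_untreated,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "significant": self.significant,
        }


def compare_to_untreated(
    treated_folds,
    untreated_folds,
    n_comparisons: int = 1,
    equal_var: bool = False,
    metric: str = "",
    dose: float = float("nan"),
    alpha: float = 0.05,
) -> GrowthComparison:
    """Two-sided unpaired t-test of treated vs untreated fold changes.

    Welch's unequal-variance form by default (``equal_var=True`` gives
    the pooled-variance Student test).  The Bonferroni-adjusted p is
    ``min(1, p * n_comparisons)``.
    """
    treated = np.asarray(treated_folds, dtype=float)
    untreated = np.asarray(untreated_folds, dtype=float)
    if treated.size < 2 or untreated.size < 2:
        raise ValueError("each group needs at least 2 wells for a t-test")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    t, p = stats.ttest_ind(treated, untreated, equal_var=equal_var)
    adj = min(1.0, float(p) * n_comparisons)
    return GrowthComparison(
        metric=metric,
        dose=float(dose),
        fold_change_treated=float(treated.mean()),
        fold_change_untreated=float(untreated.mean()),
        t_statistic=float(t),
        p_value=float(p),
        adjusted_p=adj,
        significant=adj < alpha,
    )


def dose_response_comparisons(
    loads: pd.DataFrame,
    metric: str = "n_nuclei",
    equal_var: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-dose growth comparisons for one metric.

    ``loads`` needs columns ``day``, ``dose``, ``control_role`` and the
    metric.  Day-10 wells of every nonzero dose are normalized to the
    pooled day-0 untreated mean and tested against day-10 untreated fold
    changes; Bonferroni ``n_comparisons`` = number of doses tested.
    """
    required = {"day", "dose", "control_role", metric}
    missing = required - set(loads.columns)
    if missing:
        raise ValueError(f"loads table missing columns: {sorted(missing)}")
    day0 = loads[(loads["day"] == 0) & (loads["control_role"] == "untreated")]
    day10 = loads[loads["day"] == 10]
    untreated10 = day10[day10["control_role"] == "untreated"]
    if day0.empty or untreated10.empty:
        raise ValueError("need day-0 and day-10 untreated control wells")
    untreated_folds = normalize_growth(untreated10, day0, metric)
    doses = sorted(
        d for d in day10.loc[day10["control_role"] == "none", "dose"].unique() if d > 0
    )
    rows = []
    for dose in doses:
        treated = day10[(day10["control_role"] == "none") & (day10["dose"] == dose)]
        folds = normalize_growth(treated, day0, metric)
        cmp = compare_to_untreated(
            folds,
            untreated_folds,
            n_comparisons=len(doses),
            equal_var=equal_var,
            metric=metric,
            dose=dose,
            alpha=alpha,
        )
        rows.append(cmp.as_dict())
    return pd.DataFrame(rows)
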