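"""Whole-well viability arm: normalization, 4PL fits and plate QC.

Viability readings (ATP-lysis luminescence style, one scalar per well)
are normalized to vehicle controls, fitted with the four-parameter
logistic ("log(inhibitor) vs response, variable slope")

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

and each treatment plate is screened with the standard acceptance rules
for organoid drug tests: day-0 -> day-10 untreated growth >= 1.5x,
negative-control CV < 0.22, Z-factor > 0.4, and (when a DMSO vehicle is
used) a DMSO effect within [0.8, 1.2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "four_param_logistic",
    "normalize_viability",
    "FourParamLogistic",
    "DoseResponseFit",
    "fit_dose_response",
    "PlateQC",
    "compute_qc",
    "z_factor",
    "coefficient_of_variation",
    "QC_THRESHOLDS",
]

#: Default plate-acceptance thresholds: untreated growth ratio (>=),
#: negative-control CV (<), Z-factor (>), DMSO-effect bounds (inclusive).
QC_THRESHOLDS = {
    "growth_ratio": 1.5,
    "cv": 0.22,
    "z_factor": 0.4,
    "dmso_effect": (0.8, 1.2),
}

NEGATIVE_ROLES = ("untreated", "vehicle_dmso", "vehicle_ethanol")


def four_param_logistic(dose, top: float, bottom: float, ic50: float, hill: float):
    """4PL response at ``dose``; dose 0 returns ``top`` exactly (hill > 0)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0 if hill > 0 else np.inf)
    out = bottom + (top - bottom) / (1.0 + ratio)
    return out if out.ndim else float(out)


def normalize_viability(readings, vehicle_readings) -> np.ndarray:
    """Readings divided by the vehicle-control mean (vehicle averages to 1)."""
    readings = np.asarray(readings, dtype=float)
    vehicle = np.asarray(vehicle_readings, dtype=float)
    if vehicle.size == 0:
        raise ValueError("no vehicle wells to normalize against")
    m = float(vehicle.mean())
    if m <= 0 or not np.isfinite(m):
        raise ValueError(f"vehicle mean must be positive, got {m}")
    return readings / m


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters with convergence diagnostics."""

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    n_points: int = 0

    def predict(self, dose):
        return four_param_logistic(dose, self.top, self.bottom, self.ic50, self.hill)

    def as_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "ic50": self.ic50,
            "hill": self.hill,
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
        }


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Least-squares 4PL dose-response fit, sklearn style.

    The IC50 is fitted on a log10 scale for conditioning.  Initial
    values come from the data: top/bottom from the response means at the
    extreme doses, IC50 from the dose whose mean response is nearest the
    half-way point, hill = 1.  Non-convergence and unidentifiable (flat)
    responses are *flagged* (``converged_ = False``), never raised.

    Attributes (after ``fit``): ``top_``, ``bottom_``, ``ic50_``,
    ``hill_``, ``rss_``, ``converged_``.
    """

    def __init__(self, hill_bounds: tuple[float, float] = (0.05, 20.0), maxfev: int = 10000) -> None:
        self.hill_bounds = hill_bounds
        self.maxfev = maxfev

    def fit(self, doses, response) -> "FourParamLogistic":
        doses = np.asarray(doses, dtype=float).ravel()
        y = np.asarray(response, dtype=float).ravel()
        if doses.shape != y.shape:
            raise ValueError("doses and response must have the same length")
        if (doses <= 0).any():
            raise ValueError(
                "doses must be strictly positive (vehicle/dose-0 wells are "
                "used for normalization, not fitting)"
            )
        distinct = np.unique(doses)
        if distinct.size < 4:
            raise ValueError("need >= 4 distinct doses to fit 4 parameters")
        self.n_points_ = y.size

        # dose-averaged responses, in dose order, for initialization
        means = np.array([y[doses == d].mean() for d in distinct])
        top0, bottom0 = means[0], means[-1]
        if abs(top0 - bottom0) < 1e-12 * max(1.0, abs(top0)):
            # flat response: parameters unidentifiable
            self.top_ = self.bottom_ = float(y.mean())
            self.ic50_ = float(np.sqrt(distinct[0] * distinct[-1]))
            self.hill_ = 1.0
            self.rss_ = float(((y - y.mean()) ** 2).sum())
            self.converged_ = False
            return self
        half = 0.5 * (top0 + bottom0)
        ic50_0 = distinct[int(np.argmin(np.abs(means - half)))]

        def model(d, top, bottom, log_ic50, hill):
            return four_param_logistic(d, top, bottom, 10.0**log_ic50, hill)

        lo_d, hi_d = np.log10(distinct[0]) - 3, np.log10(distinct[-1]) + 3
        span = abs(top0 - bottom0) + max(abs(top0), abs(bottom0), 1.0)
        p0 = [top0, bottom0, np.log10(ic50_0), 1.0]
        bounds = (
            [top0 - 5 * span, bottom0 - 5 * span, lo_d, self.hill_bounds[0]],
            [top0 + 5 * span, bottom0 + 5 * span, hi_d, self.hill_bounds[1]],
        )
        try:
            popt, _ = curve_fit(model, doses, y, p0=p0, bounds=bounds, maxfev=self.maxfev)
            self.top_, self.bottom_ = float(popt[0]), float(popt[1])
            self.ic50_ = float(10.0 ** popt[2])
            self.hill_ = float(popt[3])
            resid = y - model(doses, *popt)
            self.rss_ = float((resid**2).sum())
            self.converged_ = True
        except RuntimeError:
            self.top_, self.bottom_ = float(top0), float(bottom0)
            self.ic50_ = float(ic50_0)
            self.hill_ = 1.0
            resid = y - four_param_logistic(doses, top0, bottom0, ic50_0, 1.0)
            self.rss_ = float((resid**2).sum())
            self.converged_ = False
        return self

    def predict(self, doses):
        check_is_fitted(self, "ic50_")
        return four_param_logistic(np.asarray(doses, dtype=float), self.top_, self.bottom_, self.ic50_, self.hill_)

    @property
    def result_(self) -> DoseResponseFit:
        check_is_fitted(self, "ic50_")
        return DoseResponseFit(
            top=self.top_,
            bottom=self.bottom_,
            ic50=self.ic50_,
            hill=self.hill_,
            rss=self.rss_,
            converged=self.converged_,
            n_points=self.n_points_,
        )


def fit_dose_response(doses, normalized_viability, **kwargs) -> DoseResponseFit:
    """Functional wrapper over :class:`FourParamLogistic`."""
    return FourParamLogistic(**kwargs).fit(doses, normalized_viability).result_


@dataclass(frozen=True)
class PlateQC:
    """Plate-acceptance metrics and verdicts.

    ``verdicts`` maps rule name to True/False, or None when the rule is
    not applicable (no positive controls -> no Z-factor; no DMSO wells
    -> no DMSO effect).  ``passed`` is the conjunction of the applicable
    rules.
    """

    growth_ratio: float
    cv: float
    z_factor: float | None
    dmso_effect: float | None
    verdicts: dict[str, bool | None]
    thresholds: dict = field(default_factory=lambda: dict(QC_THRESHOLDS))

    @property
    def passed(self) -> bool:
        return all(v for v in self.verdicts.values() if v is not None)

    def as_dict(self) -> dict:
        return {
            "growth_ratio": self.growth_ratio,
            "cv": self.cv,
            "z_factor": self.z_factor,
            "dmso_effect": self.dmso_effect,
            "passed": self.passed,
            **{f"pass_{k}": v for k, v in self.verdicts.items()},
        }

    def summary(self) -> str:
        """Human-readable rule-by-rule report."""
        t = self.thresholds
        lines = ["Plate QC report", "---------------"]
        def fmt(name, value, rule, verdict):
            v = "n/a" if value is None else f"{value:.4g}"
            s = "n/a" if verdict is None else ("PASS" if verdict else "FAIL")
            lines.append(f"{name:<14} {v:>8}  (require {rule})  {s}")
        fmt("growth ratio", self.growth_ratio, f">= {t['growth_ratio']}", self.verdicts["growth_ratio"])
        fmt("CV", self.cv, f"< {t['cv']}", self.verdicts["cv"])
        fmt("Z-factor", self.z_factor, f"> {t['z_factor']}", self.verdicts["z_factor"])
        lo, hi = t["dmso_effect"]
        fmt("DMSO effect", self.dmso_effect, f"in [{lo}, {hi}]", self.verdicts["dmso_effect"])
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def z_factor(positive: np.ndarray, negative: np.ndarray) -> float:
    """Screening-window statistic Z' = 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|.

    Sample SDs (ddof=1), computed on raw readings; invariant under
    affine rescaling of all readings.
    """
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    if positive.size < 2 or negative.size < 2:
        raise ValueError("Z-factor needs >= 2 wells per control group")
    mu_p, mu_n = positive.mean(), negative.mean()
    if mu_p == mu_n:
        return float("-inf")
    return float(1.0 - 3.0 * (positive.std(ddof=1) + negative.std(ddof=1)) / abs(mu_p - mu_n))


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample SD / mean; 0 for constant wells."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs >= 2 wells")
    m = values.mean()
    if m == 0:
        raise ValueError("CV undefined for zero-mean readings")
    return float(values.std(ddof=1) / m)


def compute_qc(
    readings: pd.DataFrame,
    thresholds: dict | None = None,
    endpoint_day: int = 10,
    baseline_day: int = 0,
) -> PlateQC:
    """Apply the plate-acceptance rules to one plate's readings.

    ``readings`` needs columns ``well``, ``day``, ``control_role``,
    ``reading`` (raw, unnormalized).  Metrics:

    - growth ratio: mean(day-10 untreated) / mean(day-0 untreated);
    - CV: sample SD / mean over day-10 negative controls (untreated and
      vehicle wells);
    - Z-factor: Z' between day-10 staurosporine positives and negative
      controls (None when positives are missing -> rule not applicable);
    - DMSO effect: mean(day-10 DMSO vehicle) / mean(day-10 untreated),
      None when no DMSO wells exist.

    Verdict boundaries: growth >= threshold (inclusive), CV and Z-factor
    strict, DMSO bounds inclusive.
    """
    thresholds = {**QC_THRESHOLDS, **(thresholds or {})}
    required = {"well", "day", "control_role", "reading"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings missing columns: {sorted(missing)}")

    day10 = readings[readings["day"] == endpoint_day]
    day0 = readings[readings["day"] == baseline_day]
    untreated10 = day10.loc[day10["control_role"] == "untreated", "reading"].to_numpy(float)
    untreated0 = day0.loc[day0["control_role"] == "untreated", "reading"].to_numpy(float)
    negatives10 = day10.loc[
        day10["control_role"].isin(NEGATIVE_ROLES), "reading"
    ].to_numpy(float)
    positives10 = day10.loc[
        day10["control_role"] == "staurosporine", "reading"
    ].to_numpy(float)
    dmso10 = day10.loc[day10["control_role"] == "vehicle_dmso", "reading"].to_numpy(float)

    if untreated0.size == 0 or untreated10.size == 0:
        raise ValueError("growth ratio needs untreated wells on both days")
    if untreated0.mean() <= 0:
        raise ValueError("day-0 untreated mean must be positive")
    growth = float(untreated10.mean() / untreated0.mean())
    cv = coefficient_of_variation(negatives10)
    z = z_factor(positives10, negatives10) if positives10.size >= 2 else None
    dmso = (
        float(dmso10.mean() / untreated10.mean()) if dmso10.size > 0 else None
    )

    lo, hi = thresholds["dmso_effect"]
    verdicts: dict[str, bool | None] = {
        "growth_ratio": growth >= thresholds["growth_ratio"],
        "cv": cv < thresholds["cv"],
        "z_factor": (z > thresholds["z_factor"]) if z is not None else None,
        "dmso_effect": (lo <= dmso <= hi) if dmso is not None else None,
    }
    return PlateQC(
        growth_ratio=growth,
        cv=cv,
        z_factor=z,
        dmso_effect=dmso,
        verdicts=verdicts,
        thresholds=thresholds,
    )
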