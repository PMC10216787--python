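"""Control-calibrated four-population cell-death gating.

Each nucleus carries a mean Caspase 3/7 Green intensity (apoptosis
reporter) and a mean propidium-iodide intensity (membrane-integrity
reporter).  Gating proceeds in two stages:

1. *Viable thresholds* — per channel, mean + 2 x sample SD of the day-0
   untreated-control nuclei (pooled over the experiment).  A nucleus at
   or below both thresholds is viable; above either, dead.
2. *Death-mode wedges* — dead nuclei are split by the angle of
   ``(caspase - t_caspase, pi - t_pi)`` (negative components clipped to
   zero) about the threshold intersection, measured from the Caspase
   axis.  Two rays through that anchor bound a late-apoptotic wedge:
   below both rays (Caspase-dominant) is apoptotic, above both
   (PI-dominant) is necrotic, between them is late apoptosis /
   secondary necrosis.  Ray angles default to 30 deg and 60 deg and can
   be calibrated from the angular distribution of day-10
   untreated-control dead cells.

The four classes partition the intensity quadrant: every point gets
exactly one label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .synth import DEATH_MODES

__all__ = [
    "DeathGater",
    "DeathCounts",
    "fit_viable_thresholds",
    "fit_gate_lines",
    "classify_nuclei",
    "summarize_death",
    "validate_positive_control",
]

INTENSITY_COLUMNS = ("mean_caspase", "mean_pi")


def _as_xy(records) -> np.ndarray:
    """Coerce records (DataFrame with intensity columns, or (n, 2) array)
    into an (n, 2) float array of (caspase, pi)."""
    if isinstance(records, pd.DataFrame):
        arr = records.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(records, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (n, 2) intensities or a DataFrame with "
                         f"columns {INTENSITY_COLUMNS}")
    return arr


class DeathGater(BaseEstimator, ClassifierMixin):
    """Classifier of nuclei into viable / apoptotic / necrotic / late-apoptotic.

    Parameters
    ----------
    scale : {"linear", "log10"}, default "linear"
        Scale on which thresholds are computed and the angular test runs.
        On ``"log10"`` intensities must be positive (values are clipped
        at 1e-9 before the transform).
    theta_apoptotic : float, default 60.0
        Angle (degrees from the Caspase axis) of the upper gate ray; dead
        nuclei above it are necrotic.
    theta_necrotic : float, default 30.0
        Angle of the lower gate ray; dead nuclei below it are apoptotic.
        Must satisfy ``0 < theta_necrotic < theta_apoptotic < 90``.
    calibrate_angles : bool, default False
        When True, ``fit`` re-derives the two angles from day-10 control
        dead cells as the quantiles of their angular distribution that
        bound the central ``central_quantile`` mass (the wedge treated as
        late-apoptotic).
    central_quantile : float, default 1/3
        Central angular mass assigned to the late-apoptotic wedge during
        calibration.

    Attributes
    ----------
    t_caspase_, t_pi_ : float
        Viable thresholds (mean + 2 SD of day-0 controls, on ``scale``).
    theta_apoptotic_, theta_necrotic_ : float
        Gate-ray angles actually used, degrees from the Caspase axis.
    classes_ : ndarray of str
        ``["viable", "apoptotic", "necrotic", "late_apoptotic"]``.
    """

    def __init__(
        self,
        scale: str = "linear",
        theta_apoptotic: float = 60.0,
        theta_necrotic: float = 30.0,
        calibrate_angles: bool = False,
        central_quantile: float = 1.0 / 3.0,
    ) -> None:
        self.scale = scale
        self.theta_apoptotic = theta_apoptotic
        self.theta_necrotic = theta_necrotic
        self.calibrate_angles = calibrate_angles
        self.central_quantile = central_quantile

    # -- helpers ----------------------------------------------------------
    def _transform(self, xy: np.ndarray) -> np.ndarray:
        if self.scale == "linear":
            return xy
        if self.scale == "log10":
            return np.log10(np.clip(xy, 1e-9, None))
        raise ValueError(f"unknown intensity scale {self.scale!r}")

    def _check_angles(self, theta_necrotic: float, theta_apoptotic: float) -> None:
        if not 0.0 < theta_necrotic < theta_apoptotic < 90.0:
            raise ValueError(
                "gate angles must satisfy 0 < theta_necrotic < "
                f"theta_apoptotic < 90; got {theta_necrotic}, {theta_apoptotic}"
            )

    def _angles_of(self, xy_t: np.ndarray) -> np.ndarray:
        """Angle (deg from the Caspase axis) about the threshold anchor,
        with negative excess clipped to zero."""
        dc = np.clip(xy_t[:, 0] - self.t_caspase_, 0.0, None)
        dp = np.clip(xy_t[:, 1] - self.t_pi_, 0.0, None)
        return np.degrees(np.arctan2(dp, dc))

    # -- estimator API ----------------------------------------------------
    def fit(self, X_day0, X_day10=None) -> "DeathGater":
        """Calibrate thresholds (and optionally gate angles) from controls.

        Parameters
        ----------
        X_day0 : DataFrame or (n, 2) array
            Day-0 untreated-control nuclei (caspase, pi); needs >= 2 rows.
        X_day10 : DataFrame or (n, 2) array, optional
            Day-10 untreated-control nuclei, used only when
            ``calibrate_angles=True``.
        """
        self._check_angles(self.theta_necrotic, self.theta_apoptotic)
        xy = self._transform(_as_xy(X_day0))
        if len(xy) < 2:
            raise ValueError("need at least 2 day-0 control nuclei "
                             "(sample SD undefined below that)")
        mean = xy.mean(axis=0)
        sd = xy.std(axis=0, ddof=1)
        self.t_caspase_ = float(mean[0] + 2.0 * sd[0])
        self.t_pi_ = float(mean[1] + 2.0 * sd[1])
        self.theta_apoptotic_ = float(self.theta_apoptotic)
        self.theta_necrotic_ = float(self.theta_necrotic)
        self.classes_ = np.asarray(DEATH_MODES)
        if self.calibrate_angles:
            if X_day10 is None:
                raise ValueError("calibrate_angles=True needs day-10 controls")
            self.calibrate(X_day10)
        self.n_features_in_ = 2
        return self

    def calibrate(self, X_day10) -> "DeathGater":
        """Set gate angles from day-10 control dead-cell angular quantiles.

        With zero dead cells among the controls the default angles are
        kept and a warning is emitted.
        """
        check_is_fitted(self, "t_caspase_")
        xy = self._transform(_as_xy(X_day10))
        dead = (xy[:, 0] > self.t_caspase_) | (xy[:, 1] > self.t_pi_)
        if not dead.any():
            warnings.warn(
                "no dead cells in day-10 controls; keeping default gate angles"
            )
            return self
        q = self.central_quantile
        if not 0.0 < q < 1.0:
            raise ValueError("central_quantile must be in (0, 1)")
        alpha = self._angles_of(xy[dead])
        lo, hi = np.quantile(alpha, [(1.0 - q) / 2.0, (1.0 + q) / 2.0])
        # keep rays strictly inside the quadrant
        eps = 1e-6
        self.theta_necrotic_ = float(np.clip(lo, eps, 90.0 - 2 * eps))
        self.theta_apoptotic_ = float(np.clip(hi, self.theta_necrotic_ + eps, 90.0 - eps))
        return self

    def predict(self, X) -> np.ndarray:
        """Class label for every nucleus.

        Viable iff caspase <= t_caspase AND pi <= t_pi; dead nuclei are
        split by the gate rays (apoptotic below both, necrotic above
        both, late-apoptotic between; boundary angles go to the wedge).
        """
        check_is_fitted(self, "t_caspase_")
        xy = self._transform(_as_xy(X))
        out = np.empty(len(xy), dtype=object)
        viable = (xy[:, 0] <= self.t_caspase_) & (xy[:, 1] <= self.t_pi_)
        out[viable] = "viable"
        if (~viable).any():
            alpha = self._angles_of(xy[~viable])
            sub = np.where(
                alpha < self.theta_necrotic_,
                "apoptotic",
                np.where(alpha > self.theta_apoptotic_, "necrotic", "late_apoptotic"),
            )
            out[~viable] = sub
        return out

    def thresholds(self) -> tuple[float, float]:
        check_is_fitted(self, "t_caspase_")
        return self.t_caspase_, self.t_pi_

    def to_dict(self) -> dict:
        """JSON-ready description of the fitted model."""
        check_is_fitted(self, "t_caspase_")
        return {
            "scale": self.scale,
            "t_caspase": self.t_caspase_,
            "t_pi": self.t_pi_,
            "theta_apoptotic": self.theta_apoptotic_,
            "theta_necrotic": self.theta_necrotic_,
            "calibrated": bool(self.calibrate_angles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeathGater":
        model = cls(
            scale=d.get("scale", "linear"),
            theta_apoptotic=d["theta_apoptotic"],
            theta_necrotic=d["theta_necrotic"],
        )
        model.t_caspase_ = float(d["t_caspase"])
        model.t_pi_ = float(d["t_pi"])
        model.theta_apoptotic_ = float(d["theta_apoptotic"])
        model.theta_necrotic_ = float(d["theta_necrotic"])
        model.classes_ = np.asarray(DEATH_MODES)
        model.n_features_in_ = 2
        return model


@dataclass(frozen=True)
class DeathCounts:
    """Per-well death-population counts and fractions."""

    well_id: str
    n_viable: int
    n_apoptotic: int
    n_necrotic: int
    n_late: int

    @property
    def total(self) -> int:
        return self.n_viable + self.n_apoptotic + self.n_necrotic + self.n_late

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {m: 0.0 for m in DEATH_MODES}
        return {
            "viable": self.n_viable / t,
            "apoptotic": self.n_apoptotic / t,
            "necrotic": self.n_necrotic / t,
            "late_apoptotic": self.n_late / t,
        }

    @property
    def dead_fraction(self) -> float:
        return 1.0 - self.fractions["viable"] if self.total else 0.0

    def as_dict(self) -> dict:
        d = {
            "well_id": self.well_id,
            "n_viable": self.n_viable,
            "n_apoptotic": self.n_apoptotic,
            "n_necrotic": self.n_necrotic,
            "n_late": self.n_late,
            "total": self.total,
        }
        d.update({f"frac_{k}": v for k, v in self.fractions.items()})
        return d


# -- thin functional wrappers ----------------------------------------------

def fit_viable_thresholds(day0_controls, scale: str = "linear") -> tuple[float, float]:
    """Mean + 2 x sample SD per channel on day-0 control nuclei."""
    model = DeathGater(scale=scale).fit(day0_controls)
    return model.thresholds()


def fit_gate_lines(
    day10_controls,
    thresholds: tuple[float, float],
    scale: str = "linear",
    central_quantile: float = 1.0 / 3.0,
) -> DeathGater:
    """Calibrate gate-ray angles on day-10 controls, given viable thresholds."""
    model = DeathGater(scale=scale, central_quantile=central_quantile)
    model.t_caspase_, model.t_pi_ = float(thresholds[0]), float(thresholds[1])
    model.theta_apoptotic_ = model.theta_apoptotic
    model.theta_necrotic_ = model.theta_necrotic
    model.classes_ = np.asarray(DEATH_MODES)
    model.n_features_in_ = 2
    return model.calibrate(day10_controls)


def classify_nuclei(records, model: DeathGater) -> np.ndarray:
    """Vector of death-mode labels for a record table or (n, 2) array."""
    return model.predict(records)


def summarize_death(records, model: DeathGater, well_id: str = "") -> DeathCounts:
    """Count the four populations in one well (order-invariant)."""
    if isinstance(records, pd.DataFrame) and records.empty:
        return DeathCounts(well_id, 0, 0, 0, 0)
    arr = _as_xy(records)
    if len(arr) == 0:
        return DeathCounts(well_id, 0, 0, 0, 0)
    labels = model.predict(arr)
    n = {m: int((labels == m).sum()) for m in DEATH_MODES}
    return DeathCounts(
        well_id, n["viable"], n["apoptotic"], n["necrotic"], n["late_apoptotic"]
    )


def validate_positive_control(
    staurosporine_wells: dict[str, pd.DataFrame],
    untreated_wells: dict[str, pd.DataFrame],
    model: DeathGater,
    margin: float = 0.2,
) -> tuple[bool, dict[str, float]]:
    """Check staurosporine wells show excess death over untreated wells.

    Passes when the mean dead fraction of the positive-control wells
    exceeds that of the untreated wells by at least ``margin``
    (absolute).  Returns (pass flag, per-group mean dead fractions).
    """
    if not staurosporine_wells or not untreated_wells:
        raise ValueError("both well sets must be non-empty")
    def mean_dead(wells: dict[str, pd.DataFrame]) -> float:
        fracs = [
            summarize_death(records, model, well_id=w).dead_fraction
            for w, records in wells.items()
        ]
        return float(np.mean(fracs))

    dead_pos = mean_dead(staurosporine_wells)
    dead_neg = mean_dead(untreated_wells)
    passed = dead_pos - dead_neg >= margin
    return passed, {"staurosporine": dead_pos, "untreated": dead_neg}
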