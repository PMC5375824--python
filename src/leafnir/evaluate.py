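"""Accuracy metrics, calibration grading and ancillary analyses.

R^2 is the squared Pearson correlation between predicted and measured N
(for a least-squares fit with intercept this equals 1 - SS_res/SS_tot on the
training data; on validation data the two can differ and both are recorded).
RMSEC/RMSEV are root-mean-square errors on the calibration and validation
subsets, in g/kg on the modelled scale.  Grades follow the Saeys rule of
thumb for calibration quality: R^2 > 0.91 excellent, 0.82-0.91 good
(boundaries closed into "good"), else below good.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .spectra import SpectraSet

logger = logging.getLogger(__name__)


def _aligned(measured, predicted):
    m = np.asarray(measured, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if m.shape != p.shape:
        raise ValueError("measured and predicted differ in length")
    return m, p


def r_squared(measured, predicted) -> float:
    """Squared Pearson correlation between predicted and measured values."""
    m, p = _aligned(measured, predicted)
    if m.size < 3:
        raise ValueError("need at least 3 points")
    mc, pc = m - m.mean(), p - p.mean()
    ss_m, ss_p = mc @ mc, pc @ pc
    if ss_m == 0:
        raise ValueError("measured values are constant")
    if ss_p == 0:
        return 0.0  # constant predictions carry no information
    return float((mc @ pc) ** 2 / (ss_m * ss_p))


def rmse(measured, predicted) -> float:
    m, p = _aligned(measured, predicted)
    return float(np.sqrt(np.mean((p - m) ** 2)))


def mean_relative_error(measured, predicted) -> float:
    """100 * mean(|predicted - measured| / measured), in percent."""
    m, p = _aligned(measured, predicted)
    if np.any(m == 0):
        raise ValueError("zero measured value makes relative error undefined")
    return float(100.0 * np.mean(np.abs(p - m) / np.abs(m)))


class SaeysGrade(str, Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    BELOW_GOOD = "below_good"


def saeys_grade(r2: float) -> SaeysGrade:
    """Calibration-quality band: > 0.91 excellent; [0.82, 0.91] good; else below."""
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("R^2 must be in [0, 1]")
    if r2 > 0.91:
        return SaeysGrade.EXCELLENT
    if r2 >= 0.82:
        return SaeysGrade.GOOD
    return SaeysGrade.BELOW_GOOD


@dataclass
class EvaluationReport:
    """Calibration/validation accuracy summary for one fitted model."""

    method: str
    r2_calibration: float
    rmsec_gkg: float
    r2_validation: float
    rmsev_gkg: float
    mean_relative_error_pct: float   # on the validation subset
    saeys_grade: str                 # grade of the validation R^2
    n_cal: int
    n_val: int

    def as_dict(self) -> dict:
        return asdict(self)


def evaluation_report(method: str, y_cal, yhat_cal, y_val, yhat_val) -> EvaluationReport:
    r2c = r_squared(y_cal, yhat_cal)
    r2v = r_squared(y_val, yhat_val)
    return EvaluationReport(
        method=method,
        r2_calibration=r2c,
        rmsec_gkg=rmse(y_cal, yhat_cal),
        r2_validation=r2v,
        rmsev_gkg=rmse(y_val, yhat_val),
        mean_relative_error_pct=mean_relative_error(y_val, yhat_val),
        saeys_grade=saeys_grade(r2v).value,
        n_cal=len(np.asarray(y_cal).ravel()),
        n_val=len(np.asarray(y_val).ravel()),
    )


def correlogram(spectra_set: SpectraSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-band Pearson r between reflectance and N over unmasked bands.

    Returns (wavelengths_nm, r).  Constant bands get r = 0 with a log entry.
    """
    X, wl = spectra_set.matrix(drop_masked=True)
    y = spectra_set.n_gkg
    if len(spectra_set) < 3:
        raise ValueError("need at least 3 samples")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    const = ss_x <= 1e-24
    if const.any():
        logger.info("correlogram: %d constant bands set to r=0", int(const.sum()))
    denom = np.sqrt(np.where(const, 1.0, ss_x) * (yc @ yc))
    r = np.where(const, 0.0, (yc @ Xc) / denom)
    return wl, r


def polyfit_n_yield(mean_n_gkg, yield_kg_tree, degree: int = 2
                    ) -> tuple[np.ndarray, float]:
    """Least-squares polynomial of yield on per-treatment mean leaf N, with its R^2."""
    x = np.asarray(mean_n_gkg, dtype=float)
    y = np.asarray(yield_kg_tree, dtype=float)
    if x.size < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for degree {degree}")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    return coeffs, r_squared(y, fitted)


OVERFIT_GAP = 0.1


def compare_methods(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Ranking table: sorted by validation R^2 then RMSEV; flags overfitting.

    A report is flagged when calibration R^2 exceeds validation R^2 by more
    than 0.1 — the classic symptom of an over-parameterized calibration.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    rows = []
    for rep in reports:
        d = rep.as_dict()
        d["overfit_flag"] = (rep.r2_calibration - rep.r2_validation) > OVERFIT_GAP
        rows.append(d)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["r2_validation", "rmsev_gkg", "method"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)
    return df
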