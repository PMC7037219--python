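"""Calibration-curve fitting, back-calculation, and intra-assay QC metrics.

Two curve families, matching common bioanalytical practice:

* :class:`FourParamLogistic` — 4PL response curve with 1/y weighted
  regression, used for electrochemiluminescence ligand binding assays.
* :class:`LinearCalibration` — least-squares line with 1/x^2 weighting on
  (nominal concentration -> analyte/internal-standard area ratio), used for
  LC/MS signature-peptide assays.

QC acceptance: |%RE| <= 20 (25 at the LLOQ) and %CV <= 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .nca import round_sig

__all__ = [
    "FourParamLogistic",
    "LinearCalibration",
    "fit_4pl",
    "fit_linear",
    "back_calculate",
    "QCReport",
    "qc_metrics",
    "qualification_table",
    "CALIBRATION_RANGES",
    "QC_LEVELS",
]

#: Assay calibration ranges (μg/mL plasma, μg/g tumor).
CALIBRATION_RANGES = {
    ("LBA", "plasma"): (0.586, 300.0),
    ("LBA", "tumor"): (0.039, 10.0),
    ("ICMS_IFNA", "plasma"): (0.10, 100.0),
    ("ICMS_IFNA", "tumor"): (0.25, 50.0),
    ("ICMS_IGG4", "plasma"): (0.10, 100.0),
    ("ICMS_IGG4", "tumor"): (0.25, 50.0),
}

#: Nominal QC concentrations per platform and matrix (low/mid/high).
QC_LEVELS = {
    ("LBA", "plasma"): {"LQC": 3.0, "MQC": 30.0, "HQC": 240.0},
    ("LBA", "tumor"): {"LQC": 0.3, "MQC": 2.0, "HQC": 8.0},
    ("ICMS", "plasma"): {"LQC": 0.3, "MQC": 2.0, "HQC": 80.0},
    ("ICMS", "tumor"): {"LQC": 0.3, "MQC": 2.0},
}


class CalibrationError(ValueError):
    """Raised on invalid standards or fit failure."""


class ResponseOutOfRange(ValueError):
    """Back-calculation requested outside the invertible response range."""


class FourParamLogistic(BaseEstimator):
    """Four-parameter logistic calibration curve with 1/y weighting.

    Parameterization::

        response(x) = bottom + (top - bottom) / (1 + (x / ec50) ** (-hill))

    so response rises from ``bottom`` (x -> 0) to ``top`` (x -> inf) for
    ``hill > 0`` and the response at ``ec50`` is the midpoint
    ``(bottom + top) / 2``.

    Parameters
    ----------
    weighting : {"1/y", "none"}
        Residual weighting in the regression; "1/y" divides squared
        residuals by the observed response, the convention for
        heteroscedastic immunoassay signals.

    Attributes
    ----------
    bottom_, top_, ec50_, hill_ : float
        Fitted curve parameters.
    """

    def __init__(self, weighting: str = "1/y"):
        self.weighting = weighting

    # -- sklearn-style API -------------------------------------------------
    def fit(self, conc, response):
        conc = np.asarray(conc, dtype=float).ravel()
        response = np.asarray(response, dtype=float).ravel()
        if conc.size != response.size:
            raise CalibrationError("conc and response must have equal length")
        if conc.size < 5:
            raise CalibrationError("need >= 5 standard levels for a 4PL fit")
        if np.any(conc <= 0):
            raise CalibrationError("standard concentrations must be > 0")
        if self.weighting not in ("1/y", "none"):
            raise CalibrationError(f"unknown weighting {self.weighting!r}")

        order = np.argsort(conc)
        mono = response[order]
        # direction of the curve from the span of sorted responses
        increasing = mono[-1] >= mono[0]
        rho = stats_spearman(conc, response)
        if abs(rho) < 0.5:
            raise CalibrationError(
                "standards are not monotone in concentration (Spearman "
                f"rho={rho:.2f}); cannot fit a logistic curve"
            )

        lo, hi = float(response.min()), float(response.max())
        span = hi - lo if hi > lo else 1.0
        x0 = np.array([
            lo - 0.01 * span if increasing else hi + 0.01 * span,  # bottom
            hi + 0.01 * span if increasing else lo - 0.01 * span,  # top
            math.log(float(np.exp(np.mean(np.log(conc))))),        # log ec50
            1.0 if increasing else -1.0,                            # hill
        ])
        if self.weighting == "1/y":
            w = 1.0 / np.sqrt(np.clip(np.abs(response), 1e-12, None))
        else:
            w = np.ones_like(response)

        def residuals(theta):
            bottom, top, log_ec50, hill = theta
            pred = _fpl(conc, bottom, top, math.exp(log_ec50), hill)
            return w * (pred - response)

        sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15)
        if not sol.success:
            raise CalibrationError(f"4PL fit failed: {sol.message}")
        self.bottom_, self.top_ = float(sol.x[0]), float(sol.x[1])
        self.ec50_, self.hill_ = float(math.exp(sol.x[2])), float(sol.x[3])
        self.n_standards_ = conc.size
        return self

    def predict(self, conc):
        """Predicted response at the given concentrations."""
        self._check_fitted()
        return _fpl(np.asarray(conc, dtype=float), self.bottom_, self.top_,
                    self.ec50_, self.hill_)

    def __call__(self, conc):
        return self.predict(conc)

    def inverse(self, response):
        """Exact analytic inverse of the fitted curve.

        Valid strictly between the ``bottom_`` and ``top_`` asymptotes;
        responses at or beyond an asymptote raise :class:`ResponseOutOfRange`
        rather than extrapolating.
        """
        self._check_fitted()
        response = np.asarray(response, dtype=float)
        lo, hi = sorted((self.bottom_, self.top_))
        if np.any(response <= lo) or np.any(response >= hi):
            raise ResponseOutOfRange(
                f"response outside the open interval ({lo:.6g}, {hi:.6g})"
            )
        frac = (self.top_ - self.bottom_) / (response - self.bottom_) - 1.0
        return self.ec50_ * frac ** (-1.0 / self.hill_)

    def _check_fitted(self):
        if not hasattr(self, "ec50_"):
            raise CalibrationError("curve is not fitted")


def _fpl(x, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** (-hill))


def stats_spearman(x, y) -> float:
    from scipy.stats import spearmanr

    return float(spearmanr(x, y).statistic)


class LinearCalibration(BaseEstimator):
    """Weighted least-squares calibration line, default weighting 1/x^2.

    Regresses the analyte / internal-standard area ratio on nominal
    concentration. The 1/x^2 weighting makes relative (not absolute)
    deviations homoscedastic, the standard choice for LC/MS calibration
    spanning orders of magnitude.

    Attributes
    ----------
    slope_, intercept_ : float
    """

    def __init__(self, weighting: str = "1/x^2"):
        self.weighting = weighting

    def fit(self, conc, response):
        conc = np.asarray(conc, dtype=float).ravel()
        response = np.asarray(response, dtype=float).ravel()
        if conc.size < 2:
            raise CalibrationError("need >= 2 standards for a line")
        if self.weighting == "1/x^2":
            if np.any(conc <= 0):
                raise CalibrationError("1/x^2 weighting requires conc > 0")
            w = 1.0 / conc**2
        elif self.weighting in ("none", None):
            w = np.ones_like(conc)
        else:
            raise CalibrationError(f"unknown weighting {self.weighting!r}")
        # closed-form WLS for a straight line
        sw = w.sum()
        xb = float((w * conc).sum() / sw)
        yb = float((w * response).sum() / sw)
        sxx = float((w * (conc - xb) ** 2).sum())
        sxy = float((w * (conc - xb) * (response - yb)).sum())
        self.slope_ = sxy / sxx
        self.intercept_ = yb - self.slope_ * xb
        if self.slope_ <= 0:
            raise CalibrationError("calibration slope must be > 0")
        return self

    def predict(self, conc):
        self._check_fitted()
        return self.slope_ * np.asarray(conc, dtype=float) + self.intercept_

    def __call__(self, conc):
        return self.predict(conc)

    def inverse(self, response):
        """Back-calculated concentration: (response - intercept) / slope."""
        self._check_fitted()
        return (np.asarray(response, dtype=float) - self.intercept_) / self.slope_

    def _check_fitted(self):
        if not hasattr(self, "slope_"):
            raise CalibrationError("curve is not fitted")


def fit_4pl(conc, response, weighting: str = "1/y") -> FourParamLogistic:
    """Fit a 1/y-weighted four-parameter logistic to calibration standards."""
    return FourParamLogistic(weighting=weighting).fit(conc, response)


def fit_linear(conc, response, weighting: str = "1/x^2") -> LinearCalibration:
    """Fit a 1/x^2-weighted calibration line to LC/MS standards."""
    return LinearCalibration(weighting=weighting).fit(conc, response)


def back_calculate(curve, response, dilution_factor: float = 1.0,
                   sig_figs: int | None = None):
    """Concentration read back from a fitted curve via its analytic inverse.

    ``dilution_factor`` multiplies the result (e.g. the minimum required
    dilution of plasma before the assay). ``sig_figs`` optionally rounds for
    reporting (bioanalytical convention: 3 significant figures); the default
    returns the exact inverse.
    """
    conc = curve.inverse(response) * dilution_factor
    if sig_figs is not None:
        conc = np.vectorize(round_sig)(conc, sig_figs)
        if np.ndim(conc) == 0:
            conc = float(conc)
    return conc


# ---------------------------------------------------------------------------
# QC metrics

LEVELS = ("LQC", "MQC", "HQC", "LLOQ")


@dataclass
class QCReport:
    """Intra-assay precision (%CV) and accuracy (%RE) at one QC level.

    ``%CV = 100 * sd / mean`` over replicates and
    ``%RE = 100 * (mean - nominal) / nominal``; the run passes when
    ``|%RE| <= 20`` (25 at LLOQ) and ``%CV <= 20``. Runs with fewer than 3
    replicates are computed but flagged non-qualifying.
    """

    level: str
    nominal: float
    mean_conc: float
    cv_percent: float
    re_percent: float
    passed: bool
    n_replicates: int
    qualifying: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def re_percent(mean_conc: float, nominal: float) -> float:
    """Relative error of a measured mean vs its nominal concentration, %."""
    if nominal <= 0:
        raise ValueError("nominal must be > 0")
    return 100.0 * (mean_conc - nominal) / nominal


def qc_metrics(replicate_concs, nominal: float, level: str = "MQC") -> QCReport:
    """Mean, %CV, %RE and pass/fail for one set of QC replicates."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    values = np.asarray(replicate_concs, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need >= 2 replicates to compute a %CV")
    mean = float(values.mean())
    cv = 100.0 * float(values.std(ddof=1)) / mean
    re = re_percent(mean, nominal)
    re_limit = 25.0 if level == "LLOQ" else 20.0
    return QCReport(
        level=level,
        nominal=float(nominal),
        mean_conc=mean,
        cv_percent=cv,
        re_percent=re,
        passed=(abs(re) <= re_limit) and (cv <= 20.0),
        n_replicates=int(values.size),
        qualifying=values.size >= 3,
    )


def qualification_table(reports) -> pd.DataFrame:
    """Assemble QC reports into a qualification table.

    ``reports`` is an iterable of ``(platform, peptide, matrix, QCReport)``
    tuples; the result has one row per (platform, peptide, matrix, level).
    """
    rows = []
    for platform, peptide, matrix, report in reports:
        rows.append({
            "platform": platform,
            "peptide": peptide,
            "matrix": matrix,
            "level": report.level,
            "nominal": report.nominal,
            "mean_conc": report.mean_conc,
            "cv_percent": round(report.cv_percent, 1),
            "re_percent": round(report.re_percent, 1),
            "pass": report.passed,
            "n": report.n_replicates,
        })
    columns = ["platform", "peptide", "matrix", "level", "nominal",
               "mean_conc", "cv_percent", "re_percent", "pass", "n"]
    return pd.DataFrame(rows, columns=columns)
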