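"""Simultaneous estimation of PBPK parameters from plasma and tumor data.

The five conventionally estimated parameters are the plasma volume ``Vp``,
plasma clearance ``CLp``, the tumor exchange rate constants ``kpt`` and
``ktp``, and the leaky-tissue vascular reflection coefficient ``S2``; the
remaining parameters are fixed at literature or experimental values. Both
dose groups are fitted jointly with shared parameters (the model is linear
in dose), against per-timepoint mean concentrations — with destructive
sampling each animal contributes one timepoint, so mean profiles are the
natural fitting unit.

Default residual weighting is 1/prediction^2 (proportional error), because
concentrations span roughly three orders of magnitude over the 336 h study.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .data import PKDataset, summarize_by_timepoint
from .model import (
    FITTED_PARAMETER_NAMES,
    ModelParameters,
    SimulationError,
    mouse_reference_parameters,
    simulate,
)

__all__ = ["FitSpec", "FitResult", "PBPKFitter", "objective", "fit", "fit_report"]

WEIGHTINGS = ("uniform", "one_over_pred", "one_over_pred_sq")

#: Default box constraints per fittable parameter.
DEFAULT_BOUNDS = {
    "Vp": (0.1, 20.0),       # mL
    "CLp": (1e-4, 1.0),      # mL/h
    "kpt": (1e-6, 1.0),      # 1/h
    "ktp": (1e-6, 10.0),     # 1/h
    "S2": (0.0, 1.0),        # reflection coefficient
    "S1": (0.0, 1.0),
    "SL": (0.0, 1.0),
    "L": (1e-3, 10.0),
    "ISF": (0.1, 50.0),
    "Kp": (1e-3, 10.0),
    "Vlymph": (0.1, 20.0),
    "Vt": (0.01, 5.0),
}

PARAMETER_UNITS = {
    "L": "mL/h", "ISF": "mL", "Kp": "-", "Vp": "mL", "Vlymph": "mL",
    "Vt": "mL", "CLp": "mL/h", "kpt": "1/h", "ktp": "1/h",
    "S1": "-", "S2": "-", "SL": "-",
}

PARAMETER_DESCRIPTIONS = {
    "L": "Total lymph flow",
    "ISF": "Total interstitial fluid volume",
    "Kp": "Tissue-to-plasma concentration ratio",
    "Vp": "Plasma volume",
    "Vlymph": "Lymphatic volume",
    "Vt": "Tumor volume",
    "CLp": "Clearance",
    "kpt": "Plasma-to-tumor rate constant",
    "ktp": "Tumor-to-plasma rate constant",
    "S1": "Vascular reflection coefficient, tight tissue",
    "S2": "Vascular reflection coefficient, leaky tissue",
    "SL": "Lymphatic capillary reflection coefficient",
}

REPORT_ORDER = ("L", "ISF", "Kp", "Vp", "Vlymph", "Vt",
                "CLp", "kpt", "ktp", "S1", "S2", "SL")


@dataclass
class FitSpec:
    """What to fit, from where, under which constraints.

    Attributes
    ----------
    fitted_names : sequence of str
        Parameters to estimate (default: Vp, CLp, kpt, ktp, S2).
    fixed : ModelParameters
        Full parameter set supplying the non-fitted values and, unless
        ``initial_values`` overrides them, the starting point.
    bounds : dict
        (lower, upper) per fitted parameter.
    residual_weighting : {"uniform", "one_over_pred", "one_over_pred_sq"}
    initial_values : dict
        Starting values per fitted parameter.
    assay : str or None
        Restrict the fit to one assay's records (None = all records).
    """

    fitted_names: Sequence[str] = FITTED_PARAMETER_NAMES
    fixed: ModelParameters = field(default_factory=mouse_reference_parameters)
    bounds: dict = field(default_factory=dict)
    residual_weighting: str = "one_over_pred_sq"
    initial_values: dict = field(default_factory=dict)
    assay: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.fitted_names:
            raise ValueError("at least one parameter must be fitted")
        unknown = set(self.fitted_names) - set(DEFAULT_BOUNDS)
        if unknown:
            raise ValueError(f"cannot fit unknown parameter(s) {sorted(unknown)}")
        if self.residual_weighting not in WEIGHTINGS:
            raise ValueError(
                f"weighting must be one of {WEIGHTINGS}, "
                f"got {self.residual_weighting!r}"
            )
        self.fitted_names = tuple(self.fitted_names)
        bounds = {name: self.bounds.get(name, DEFAULT_BOUNDS[name])
                  for name in self.fitted_names}
        self.bounds = bounds
        x0 = dict(self.initial_values)
        for name in self.fitted_names:
            x0.setdefault(name, getattr(self.fixed, name))
            lo, hi = bounds[name]
            if not lo <= x0[name] <= hi:
                raise ValueError(
                    f"initial value {x0[name]!r} for {name} outside bounds {bounds[name]}"
                )
        self.initial_values = x0


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one fit."""

    estimates: dict
    se: dict
    cv_percent: dict
    objective: float
    residuals: pd.DataFrame
    converged: bool
    message: str
    n_obs: int
    spec: FitSpec
    trace: list = field(default_factory=list)

    @property
    def parameters(self) -> ModelParameters:
        """Full parameter set with the estimates substituted in."""
        return self.spec.fixed.with_values(**self.estimates)


def _mean_observations(data: PKDataset, assay: Optional[str]) -> pd.DataFrame:
    ds = data.filter(assay=assay) if assay is not None else data
    summary = summarize_by_timepoint(ds)
    # pool assays (if several remain) into one mean per (dose, matrix, time)
    summary = summary[summary["n"] > 0]
    obs = (summary.groupby(["dose_group", "matrix", "time_h"], sort=True)["mean"]
           .mean().reset_index().rename(columns={"mean": "observed"}))
    if obs.empty:
        raise ValueError("no quantifiable observations to fit")
    return obs


def _predict(params: ModelParameters, obs: pd.DataFrame, design) -> np.ndarray:
    pred = np.empty(len(obs))
    for dose, group in obs.groupby("dose_group", sort=True):
        times = np.unique(group["time_h"].to_numpy())
        sim = simulate(params, design.dose_ug(dose), times)
        lookup = {
            ("plasma", t): c for t, c in zip(sim.times, sim.Cp)
        }
        lookup.update({("tumor", t): c for t, c in zip(sim.times, sim.Ct)})
        pred[group.index] = [
            lookup[(m, t)] for m, t in zip(group["matrix"], group["time_h"])
        ]
    return pred


def _weighted_residuals(observed, predicted, weighting: str) -> np.ndarray:
    predicted = np.clip(predicted, 1e-12, None)
    raw = observed - predicted
    if weighting == "uniform":
        return raw
    if weighting == "one_over_pred":
        return raw / np.sqrt(predicted)
    return raw / predicted  # one_over_pred_sq


def objective(params: ModelParameters, data: PKDataset,
              weighting: str = "one_over_pred_sq",
              assay: Optional[str] = None) -> float:
    """Weighted sum of squared residuals of model vs per-timepoint means."""
    obs = _mean_observations(data, assay)
    pred = _predict(params, obs, data.design)
    r = _weighted_residuals(obs["observed"].to_numpy(), pred, weighting)
    return float(np.sum(r**2))


class PBPKFitter(BaseEstimator):
    """Least-squares estimator of minimal-PBPK parameters.

    An sklearn-style estimator: hyperparameters (which parameters to fit,
    weighting, bounds...) go to ``__init__``; :meth:`fit` consumes a
    :class:`~fusionpk.data.PKDataset` and exposes ``estimates_``, ``se_``,
    ``cv_percent_`` and the full :class:`FitResult` as ``result_``.

    Parameters
    ----------
    fitted_names : sequence of str
    fixed : ModelParameters or None
        Non-fitted values (reference set when None).
    bounds, initial_values : dict
    residual_weighting : str
    assay : str or None
        Fit only this assay's records.
    n_starts : int
        Extra multi-start points with seeded jitter around the initial
        values (1 = single deterministic start).
    seed : int
        Seed for the multi-start jitter.
    """

    def __init__(self, fitted_names=FITTED_PARAMETER_NAMES, fixed=None,
                 bounds=None, initial_values=None,
                 residual_weighting="one_over_pred_sq", assay=None,
                 n_starts=1, seed=0):
        self.fitted_names = fitted_names
        self.fixed = fixed
        self.bounds = bounds
        self.initial_values = initial_values
        self.residual_weighting = residual_weighting
        self.assay = assay
        self.n_starts = n_starts
        self.seed = seed

    def _make_spec(self) -> FitSpec:
        return FitSpec(
            fitted_names=tuple(self.fitted_names),
            fixed=self.fixed if self.fixed is not None else mouse_reference_parameters(),
            bounds=dict(self.bounds or {}),
            residual_weighting=self.residual_weighting,
            initial_values=dict(self.initial_values or {}),
            assay=self.assay,
        )

    def fit(self, data: PKDataset, y=None):
        spec = self._make_spec()
        obs = _mean_observations(data, spec.assay)
        names = list(spec.fitted_names)
        lo = np.array([spec.bounds[n][0] for n in names])
        hi = np.array([spec.bounds[n][1] for n in names])
        design = data.design
        observed = obs["observed"].to_numpy()
        trace: list = []

        def residual_vector(x):
            params = spec.fixed.with_values(**dict(zip(names, x)))
            try:
                pred = _predict(params, obs, design)
            except SimulationError as exc:
                warnings.warn(f"simulation failed during fit: {exc}")
                return np.full(len(obs), 1e6)
            r = _weighted_residuals(observed, pred, spec.residual_weighting)
            trace.append((tuple(x), float(np.sum(r**2))))
            return r

        starts = [np.array([spec.initial_values[n] for n in names])]
        if self.n_starts > 1:
            rng = np.random.default_rng(self.seed)
            for _ in range(self.n_starts - 1):
                jitter = np.exp(rng.normal(0.0, 0.3, len(names)))
                starts.append(np.clip(starts[0] * jitter, lo, hi))

        best = None
        for x0 in starts:
            sol = least_squares(residual_vector, x0, bounds=(lo, hi),
                                method="trf", x_scale="jac",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol

        estimates = dict(zip(names, map(float, best.x)))
        n_obs = len(obs)
        dof = max(n_obs - len(names), 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.pinv(jtj)
            se = {n: float(math.sqrt(max(cov[i, i], 0.0)))
                  for i, n in enumerate(names)}
        except np.linalg.LinAlgError:
            se = {n: float("nan") for n in names}
        cv = {n: (100.0 * se[n] / abs(estimates[n]) if estimates[n] != 0
                  else float("inf")) for n in names}

        final_params = spec.fixed.with_values(**estimates)
        pred = _predict(final_params, obs, design)
        residual_table = obs.copy()
        residual_table["predicted"] = pred
        residual_table["weighted_residual"] = _weighted_residuals(
            observed, pred, spec.residual_weighting)

        self.result_ = FitResult(
            estimates=estimates,
            se=se,
            cv_percent=cv,
            objective=float(2.0 * best.cost),
            residuals=residual_table,
            converged=bool(best.success),
            message=str(best.message),
            n_obs=n_obs,
            spec=spec,
            trace=trace,
        )
        self.estimates_ = estimates
        self.se_ = se
        self.cv_percent_ = cv
        self.parameters_ = final_params
        self.n_obs_ = n_obs
        return self

    def predict(self, data: PKDataset) -> np.ndarray:
        """Model concentrations at the dataset's mean-profile observations."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fitter is not fitted")
        obs = _mean_observations(data, self.result_.spec.assay)
        return _predict(self.parameters_, obs, data.design)


def fit(data: PKDataset, spec: FitSpec, n_starts: int = 1, seed: int = 0) -> FitResult:
    """Bound-constrained least-squares fit of ``spec`` to ``data``."""
    fitter = PBPKFitter(
        fitted_names=spec.fitted_names, fixed=spec.fixed, bounds=spec.bounds,
        initial_values=spec.initial_values,
        residual_weighting=spec.residual_weighting, assay=spec.assay,
        n_starts=n_starts, seed=seed,
    )
    fitter.fit(data)
    return fitter.result_


def fit_report(result: FitResult) -> pd.DataFrame:
    """One row per model parameter: value, %CV (fitted only), unit, provenance."""
    params = result.parameters
    rows = []
    for name in REPORT_ORDER:
        fitted = name in result.estimates
        rows.append({
            "parameter": name,
            "value": getattr(params, name),
            "cv_percent": result.cv_percent[name] if fitted else float("nan"),
            "unit": PARAMETER_UNITS[name],
            "description": PARAMETER_DESCRIPTIONS[name],
            "source": "fitted" if fitted else "fixed",
        })
    return pd.DataFrame(rows)


def parse_fit_report(frame: pd.DataFrame) -> ModelParameters:
    """Rebuild a full parameter set from a fit report table."""
    values = dict(zip(frame["parameter"], frame["value"]))
    return ModelParameters(
        L=values["L"], ISF=values["ISF"], Kp=values["Kp"], Vp=values["Vp"],
        Vlymph=values["Vlymph"], Vt=values["Vt"], CLp=values["CLp"],
        kpt=values["kpt"], ktp=values["ktp"], S1=values["S1"],
        S2=values["S2"], SL=values["SL"],
    )
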