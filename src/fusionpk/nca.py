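"""Non-compartmental analysis and cross-assay exposure comparison.

AUC by the linear trapezoidal rule, terminal half-life by unweighted least
squares of ln(concentration) vs time, clearance as Dose/AUC, and a
many-to-one (Dunnett) comparison of assay platforms against a reference
with critical values from a seeded Monte-Carlo simulation of the max-|t|
null distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auc_trapezoid",
    "terminal_halflife",
    "TerminalFit",
    "NCAResult",
    "nca_profile",
    "tumor_plasma_ratio",
    "round_sig",
    "dunnett_max_t_samples",
    "dunnett_critical_value",
    "dunnett_mc",
    "ExposureComparison",
    "compare_assays",
    "nca_report",
]


def auc_trapezoid(times, concs) -> float:
    """Linear trapezoidal AUC: sum of (t[i+1]-t[i]) * (C[i]+C[i+1]) / 2."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 points for a trapezoidal AUC")
    if times.shape != concs.shape:
        raise ValueError("times and concs must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(concs < 0):
        raise ValueError("concentrations must be nonnegative")
    return float(np.trapezoid(concs, times))


class TerminalFit(NamedTuple):
    """Terminal log-linear regression: rate constant, half-life, fit R^2.

    ``lambda_z`` and ``t_half`` are NaN when the terminal slope is
    nonnegative (no measurable elimination phase).
    """

    lambda_z: float
    t_half: float
    r2: float


def terminal_halflife(times, concs, n_points: int = 3) -> TerminalFit:
    """Estimate the terminal elimination rate from the last ``n_points``.

    Unweighted least squares of ln(conc) on time over the selected terminal
    points; ``lambda_z = -slope`` and ``t_half = ln(2)/lambda_z``.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if n_points < 3:
        raise ValueError("terminal regression needs n_points >= 3")
    if times.size < n_points:
        raise ValueError(f"profile has {times.size} points, need {n_points}")
    t = times[-n_points:]
    c = concs[-n_points:]
    if np.any(c <= 0):
        raise ValueError("terminal concentrations must be positive")
    slope, intercept = np.polyfit(t, np.log(c), 1)
    resid = np.log(c) - (slope * t + intercept)
    ss_tot = float(np.sum((np.log(c) - np.log(c).mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    # a slope indistinguishable from zero at round-off scale is no
    # elimination phase either
    if slope >= -1e-12 / (t[-1] - t[0]):
        return TerminalFit(float("nan"), float("nan"), r2)
    lambda_z = -float(slope)
    return TerminalFit(lambda_z, math.log(2.0) / lambda_z, r2)


@dataclass
class NCAResult:
    """Exposure metrics of one concentration-time profile.

    ``cl_per_kg`` (primary, from AUC extrapolated to infinity) and
    ``cl_last_per_kg`` (from AUC to the last observation) are populated only
    when a dose was supplied; both satisfy CL * AUC = dose by construction.
    All AUCs in h·μg/mL, clearances in mL/h/kg.
    """

    auc_last: float
    auc_inf: float
    lambda_z: float
    t_half: float
    cmax: float
    tmax: float
    cl_per_kg: Optional[float]
    cl_last_per_kg: Optional[float]
    n_terminal_points: int
    regression_r2: float
    terminal_defined: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def nca_profile(times, concs, dose_ug_per_kg: Optional[float] = None,
                n_terminal: int = 3) -> NCAResult:
    """Full non-compartmental analysis of one mean profile.

    ``auc_inf = auc_last + C_last / lambda_z``. When the terminal phase is
    undefined (nonpositive terminal concentrations or nonnegative slope) the
    extrapolated quantities are NaN and ``terminal_defined`` is False.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    auc_last = auc_trapezoid(times, concs)
    imax = int(np.argmax(concs))
    cmax, tmax = float(concs[imax]), float(times[imax])

    try:
        term = terminal_halflife(times, concs, n_points=n_terminal)
        defined = math.isfinite(term.lambda_z)
    except ValueError:
        term = TerminalFit(float("nan"), float("nan"), float("nan"))
        defined = False

    if defined:
        auc_inf = auc_last + float(concs[-1]) / term.lambda_z
    else:
        auc_inf = float("nan")

    cl_inf = cl_last = None
    if dose_ug_per_kg is not None:
        cl_last = dose_ug_per_kg / auc_last
        cl_inf = dose_ug_per_kg / auc_inf if defined else None
    return NCAResult(
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=term.lambda_z,
        t_half=term.t_half,
        cmax=cmax,
        tmax=tmax,
        cl_per_kg=cl_inf,
        cl_last_per_kg=cl_last,
        n_terminal_points=n_terminal,
        regression_r2=term.r2,
        terminal_defined=defined,
    )


def tumor_plasma_ratio(auc_tumor: float, auc_plasma: float, sig_figs: int = 3) -> float:
    """Tumor-to-plasma exposure ratio, reported to 3 significant figures."""
    if auc_plasma <= 0:
        raise ValueError("plasma AUC must be > 0")
    return round_sig(auc_tumor / auc_plasma, sig_figs)


def round_sig(x: float, sig_figs: int = 3) -> float:
    """Round to ``sig_figs`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig_figs - 1 - int(math.floor(math.log10(abs(x)))))


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparison via seeded Monte-Carlo


def dunnett_max_t_samples(ns, n_control: int, df: int, n_draws: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw from the null distribution of max_i |t_i| for Dunnett contrasts.

    Under H0 with common variance, group means are independent normals with
    variance 1/n_i (in units of sigma^2) and the pooled variance estimate is
    an independent chi-square_df / df. Each comparison statistic is
    ``t_i = (mean_i - mean_0) / sqrt(s2 * (1/n_i + 1/n_0))``; the critical
    value of the familywise test is the (1-alpha) quantile of max_i |t_i|.
    """
    ns = np.asarray(ns, dtype=float)
    means = rng.standard_normal((n_draws, ns.size)) / np.sqrt(ns)
    mean0 = rng.standard_normal(n_draws) / math.sqrt(n_control)
    s2 = rng.chisquare(df, size=n_draws) / df
    t = (means - mean0[:, None]) / np.sqrt(s2[:, None] * (1.0 / ns + 1.0 / n_control))
    return np.max(np.abs(t), axis=1)


def dunnett_critical_value(ns, n_control: int, alpha: float = 0.05,
                           n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo two-sided Dunnett critical value for comparisons vs control."""
    ns = np.asarray(ns, dtype=int)
    df = int(ns.sum()) + n_control - ns.size - 1
    rng = np.random.default_rng(seed)
    samples = dunnett_max_t_samples(ns, n_control, df, n_draws, rng)
    return float(np.quantile(samples, 1.0 - alpha))


@dataclass
class DunnettResult:
    statistic: np.ndarray  # t statistic per comparison group
    critical_value: float
    p_adjusted: np.ndarray  # familywise-adjusted p per comparison
    reject: np.ndarray
    alpha: float
    df: int


def dunnett_mc(groups, control, alpha: float = 0.05, n_draws: int = 100_000,
               seed: int = 0) -> DunnettResult:
    """Dunnett's many-to-one test with Monte-Carlo max-|t| critical values.

    ``groups`` is a sequence of 1-D samples compared against ``control``.
    Adjusted p-values are the null probability that max_i |t_i| exceeds the
    observed |t_i|.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    control = np.asarray(control, dtype=float)
    if any(g.size < 2 for g in groups) or control.size < 2:
        raise ValueError("each group needs >= 2 replicates for the test")
    ns = np.array([g.size for g in groups])
    n0 = control.size
    df = int(ns.sum()) + n0 - len(groups) - 1
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    ss += float(np.sum((control - control.mean()) ** 2))
    s2 = ss / df
    t_obs = np.array([
        (g.mean() - control.mean()) / math.sqrt(s2 * (1.0 / g.size + 1.0 / n0))
        for g in groups
    ])
    rng = np.random.default_rng(seed)
    samples = dunnett_max_t_samples(ns, n0, df, n_draws, rng)
    crit = float(np.quantile(samples, 1.0 - alpha))
    p_adj = np.array([float(np.mean(samples >= abs(t))) for t in t_obs])
    return DunnettResult(
        statistic=t_obs,
        critical_value=crit,
        p_adjusted=p_adj,
        reject=np.abs(t_obs) > crit,
        alpha=alpha,
        df=df,
    )


@dataclass
class ExposureComparison:
    """Per-assay exposures compared against a reference assay.

    ``percent_difference`` is ``100 * (reference - test) / reference`` — a
    positive value means the test assay under-reads relative to the
    reference. The ANOVA/Dunnett branch runs only when every assay supplies
    replicate values; with point estimates it is flagged as skipped.
    """

    reference: str
    exposures: dict  # assay -> mean exposure
    ratio_to_reference: dict
    percent_difference: dict
    anova_f: Optional[float] = None
    anova_p: Optional[float] = None
    dunnett_flags: dict = field(default_factory=dict)
    dunnett_p: dict = field(default_factory=dict)
    test_skipped: bool = False
    skip_reason: str = ""


def compare_assays(exposures_by_assay: dict, reference: str, alpha: float = 0.05,
                   n_draws: int = 100_000, seed: int = 0) -> ExposureComparison:
    """Compare per-assay exposures against a reference assay.

    ``exposures_by_assay`` maps assay name to either a scalar exposure or a
    sequence of replicate exposures. Point estimates give percent
    differences only; with >= 2 replicates per assay a one-way ANOVA and the
    Monte-Carlo Dunnett test against ``reference`` are run at ``alpha``.
    """
    if reference not in exposures_by_assay:
        raise ValueError(f"reference assay {reference!r} not among groups")
    if len(exposures_by_assay) < 2:
        raise ValueError("need at least 2 assays to compare")

    arrays = {a: np.atleast_1d(np.asarray(v, dtype=float))
              for a, v in exposures_by_assay.items()}
    means = {a: float(v.mean()) for a, v in arrays.items()}
    ref_mean = means[reference]
    result = ExposureComparison(
        reference=reference,
        exposures=means,
        ratio_to_reference={a: m / ref_mean for a, m in means.items()},
        percent_difference={a: 100.0 * (ref_mean - m) / ref_mean
                            for a, m in means.items()},
    )

    if any(v.size < 2 for v in arrays.values()):
        result.test_skipped = True
        result.skip_reason = (
            "single exposure value per assay; ANOVA/Dunnett require replicates"
        )
        return result

    others = [a for a in arrays if a != reference]
    f_stat, p_val = stats.f_oneway(*arrays.values())
    result.anova_f, result.anova_p = float(f_stat), float(p_val)
    dn = dunnett_mc([arrays[a] for a in others], arrays[reference],
                    alpha=alpha, n_draws=n_draws, seed=seed)
    result.dunnett_flags = {a: bool(r) for a, r in zip(others, dn.reject)}
    result.dunnett_p = {a: float(p) for a, p in zip(others, dn.p_adjusted)}
    result.dunnett_flags[reference] = False
    return result


def nca_report(dataset, dose_groups=None, matrices=("plasma", "tumor"),
               assays=None, n_terminal: int = 3) -> pd.DataFrame:
    """NCA of every (dose, matrix, assay) mean profile in a dataset.

    One row per profile with AUC, CL (plasma only), Cmax, T1/2 and the
    tumor-to-plasma AUC ratio attached to tumor rows.
    """
    design = dataset.design
    dose_groups = list(design.doses) if dose_groups is None else list(dose_groups)
    assays = list(design.assays) if assays is None else list(assays)
    rows = []
    plasma_auc: dict = {}
    for dose in dose_groups:
        for assay in assays:
            for matrix in matrices:
                times, means = dataset.mean_profile(dose, matrix, assay)
                if times.size < 2:
                    continue
                dose_per_kg = dose * 1000.0 if matrix == "plasma" else None  # μg/kg
                res = nca_profile(times, means, dose_ug_per_kg=dose_per_kg,
                                  n_terminal=n_terminal)
                row = {"dose_group": dose, "matrix": matrix, "assay": assay,
                       **res.to_dict()}
                if matrix == "plasma":
                    plasma_auc[(dose, assay)] = res.auc_last
                else:
                    ref = plasma_auc.get((dose, assay))
                    row["tumor_plasma_auc_ratio"] = (
                        tumor_plasma_ratio(res.auc_last, ref) if ref else float("nan")
                    )
                rows.append(row)
    return pd.DataFrame(rows)
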