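"""Adjusted between-group contrasts from generalized estimating equations.

The repeated follow-up measurements (T1, T2) are modelled with an
identity-link Gaussian GEE: fixed effects for group, the later-timepoint
indicator, their interaction, endocrine therapy, and the baseline score as
a covariate; an exchangeable working correlation absorbs within-subject
dependence and a robust (sandwich) covariance protects inference against
its misspecification.  Entering baseline as a covariate (rather than as a
response) is the parameterization under which per-timepoint group
contrasts are directly identified: the group main effect is the adjusted
difference at the first follow-up, and group + group x time at the second.

When fitted on an :class:`~trialcea.imputation.ImputationSet`, coefficient
vectors and sandwich covariances are combined by Rubin's rules; contrasts
then carry Rubin small-sample degrees of freedom.

Effect sizes follow the convention of dividing the adjusted mean
difference by the pooled unadjusted baseline SD (Cohen d), and the
distribution-based minimally important clinical difference (MICD) is half
the baseline SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .imputation import ImputationSet

__all__ = [
    "GEEFit",
    "ContrastResult",
    "fit_gee",
    "group_contrast",
    "pooled_baseline_sd",
    "cohens_d",
    "micd",
]


@dataclass
class GEEFit:
    """A (possibly multiply-imputed, Rubin-pooled) GEE fit."""

    outcome: str
    exog_names: list[str]
    params: np.ndarray
    cov: np.ndarray            # total (Rubin) robust covariance
    within_cov: np.ndarray
    between_cov: np.ndarray
    alpha: float               # working exchangeable correlation
    n_subjects: int
    m: int
    converged: bool
    timepoints: tuple[str, ...]

    def param(self, name: str) -> float:
        return float(self.params[self.exog_names.index(name)])


@dataclass
class ContrastResult:
    """Adjusted between-group mean difference at one timepoint."""

    outcome: str
    timepoint: str
    adjusted_mean_difference: float
    se: float
    ci_95: tuple[float, float]
    p_raw: float
    p_bonferroni: float
    cohen_d: float | None
    micd: float | None
    exceeds_micd: bool | None
    df: float


def pooled_baseline_sd(sd_a: float, sd_b: float, n_a: int, n_b: int) -> float:
    """Two-sample pooled SD: sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2))."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    return float(np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)))


def cohens_d(adjusted_mean_difference: float, pooled_sd: float) -> float:
    """Adjusted mean difference divided by the pooled unadjusted baseline SD."""
    if pooled_sd <= 0:
        raise ValueError("pooled_sd must be positive")
    return adjusted_mean_difference / pooled_sd


def micd(baseline_sd: float) -> float:
    """Distribution-based minimally important clinical difference: SD / 2."""
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive")
    return 0.5 * baseline_sd


def _design(panel: pd.DataFrame, outcome: str, covariates, timepoints) -> tuple:
    """Long follow-up design with baseline entered as a covariate."""
    base = (
        panel[panel["timepoint"] == "T0"]
        .set_index("participant_id")[outcome]
        .rename("baseline")
    )
    rows = panel[panel["timepoint"].isin(timepoints)].copy()
    rows = rows.join(base, on="participant_id")
    rows["group"] = (rows["arm"] == "intervention").astype(float)

    names = ["const", "group"]
    cols = [np.ones(len(rows)), rows["group"].to_numpy()]
    for tp in timepoints[1:]:
        ind = rows["timepoint"].eq(tp).astype(float).to_numpy()
        cols += [ind, rows["group"].to_numpy() * ind]
        names += [f"time_{tp}", f"group:time_{tp}"]
    for cov in covariates:
        cols.append(rows[cov].to_numpy(dtype=float))
        names.append(cov)
    cols.append(rows["baseline"].to_numpy(dtype=float))
    names.append("baseline")

    X = np.column_stack(cols)
    y = rows[outcome].to_numpy(dtype=float)
    groups = rows["participant_id"].to_numpy()
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    return y[keep], X[keep], groups[keep], names


def _fit_single(panel, outcome, covariates, timepoints, working, maxiter, tol):
    y, X, groups, names = _design(panel, outcome, covariates, timepoints)
    cov_struct = (
        sm.cov_struct.Exchangeable() if working == "exchangeable" else sm.cov_struct.Independence()
    )
    # a subject observed at a single timepoint cannot inform exchangeable alpha
    if working == "exchangeable" and pd.Series(groups).value_counts().max() == 1:
        cov_struct = sm.cov_struct.Independence()
    model = sm.GEE(y, X, groups=groups, family=sm.families.Gaussian(), cov_struct=cov_struct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, ctol=tol, cov_type="robust")
    alpha = float(np.atleast_1d(res.cov_struct.dep_params)[0]) if working == "exchangeable" else 0.0
    converged = bool(getattr(res, "converged", True))
    return res.params, res.cov_params(), alpha, converged, names, len(np.unique(groups))


def fit_gee(
    data,
    outcome: str,
    covariates: tuple[str, ...] = ("endocrine_therapy",),
    timepoints: tuple[str, ...] = ("T1", "T2"),
    working: str = "exchangeable",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GEEFit:
    """Fit the adjusted GEE on a panel or on every panel of an imputation set.

    Rows with a missing response or covariate are dropped (complete-case
    path); pass an :class:`ImputationSet` for the intention-to-treat
    multiply-imputed analysis, whose coefficients and covariances are
    pooled by Rubin's rules.
    """
    panels = list(data) if isinstance(data, ImputationSet) else [data]
    fits = [
        _fit_single(p, outcome, covariates, timepoints, working, maxiter, tol) for p in panels
    ]
    names = fits[0][4]
    params = np.array([f[0] for f in fits])
    covs = np.array([f[1] for f in fits])
    m = len(fits)
    point = params.mean(axis=0)
    within = covs.mean(axis=0)
    if m > 1:
        dev = params - point
        between = dev.T @ dev / (m - 1)
    else:
        between = np.zeros_like(within)
    total = within + (1.0 + 1.0 / m) * between
    return GEEFit(
        outcome=outcome,
        exog_names=names,
        params=point,
        cov=total,
        within_cov=within,
        between_cov=between,
        alpha=float(np.mean([f[2] for f in fits])),
        n_subjects=fits[0][5],
        m=m,
        converged=all(f[3] for f in fits),
        timepoints=tuple(timepoints),
    )


def group_contrast(
    fit: GEEFit,
    timepoint: str,
    k_comparisons: int = 2,
    baseline_sd: float | None = None,
) -> ContrastResult:
    """Adjusted intervention-minus-control difference at one timepoint.

    ``p_bonferroni = min(1, k * p_raw)``.  When ``baseline_sd`` is given,
    Cohen d and the half-SD MICD flag are attached.
    """
    if not fit.converged:
        raise RuntimeError(f"GEE for {fit.outcome} did not converge; contrast unavailable")
    if timepoint not in fit.timepoints:
        raise ValueError(f"unknown timepoint '{timepoint}' (fit covers {fit.timepoints})")
    if k_comparisons < 1:
        raise ValueError("k_comparisons must be >= 1")

    L = np.zeros(len(fit.exog_names))
    L[fit.exog_names.index("group")] = 1.0
    inter = f"group:time_{timepoint}"
    if inter in fit.exog_names:
        L[fit.exog_names.index(inter)] = 1.0

    est = float(L @ fit.params)
    var_w = float(L @ fit.within_cov @ L)
    var_b = float(L @ fit.between_cov @ L)
    if fit.m > 1 and var_b > 0:
        total = var_w + (1.0 + 1.0 / fit.m) * var_b
        df = (fit.m - 1) * (1.0 + var_w / ((1.0 + 1.0 / fit.m) * var_b)) ** 2
    else:
        total = var_w
        df = np.inf
    se = float(np.sqrt(total))
    dist = stats.t(df) if np.isfinite(df) else stats.norm
    q = dist.ppf(0.975)
    p_raw = float(2 * dist.sf(abs(est / se))) if se > 0 else (0.0 if est != 0 else 1.0)
    p_bonf = min(1.0, k_comparisons * p_raw)

    d = thr = exceeds = None
    if baseline_sd is not None:
        d = cohens_d(est, baseline_sd)
        thr = micd(baseline_sd)
        exceeds = bool(abs(est) > thr)
    return ContrastResult(
        outcome=fit.outcome,
        timepoint=timepoint,
        adjusted_mean_difference=est,
        se=se,
        ci_95=(est - q * se, est + q * se),
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        cohen_d=d,
        micd=thr,
        exceeds_micd=exceeds,
        df=float(df),
    )
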