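"""Synthetic two-arm repeated-measures RCT generator.

Scores are drawn per participant from a multivariate normal across the
three assessments with an exchangeable within-subject correlation, shifted
by the control-arm drift and (in the intervention arm) the additive
treatment effect at each follow-up, then truncated to the instrument range
and rounded on integer scales.  The SF-36 physical and mental component
scores are additionally cross-correlated, so the affine utility surrogate
applied to them reproduces the configured baseline utility dispersion.

Missingness is monotone dropout at the follow-ups.  Under MCAR every
participant drops with the target probability; under MAR the dropout
probability is a logistic function of the standardized baseline stigma
score and arm, with the intercept calibrated so the expected overall
dropout equals the target rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import ARMS, INSTRUMENTS, TrialConfig, ConfigError
from .panel import PANEL_COLUMNS, USAGE_MODULES, ANALYSIS_COLUMNS, validate_panel

__all__ = ["generate_trial", "apply_missingness", "lognormal_from_median_iqr"]

_Z_QUARTILE = 0.6744897501960817  # standard-normal upper quartile


def _exchangeable_corr(t: int, rho: float) -> np.ndarray:
    return np.full((t, t), rho) + (1.0 - rho) * np.eye(t)


def lognormal_from_median_iqr(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and quartiles."""
    mu = np.log(median)
    sigma = np.log(iqr[1] / iqr[0]) / (2.0 * _Z_QUARTILE)
    return mu, sigma


def _lognormal_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _draw_scores(cfg: TrialConfig, rng: np.random.Generator, n_total: int,
                 is_intervention: np.ndarray) -> dict[str, np.ndarray]:
    """Latent-normal draws for all instruments plus utility, shape (n, T)."""
    T = len(cfg.timepoints)
    R_time = _exchangeable_corr(T, cfg.within_subject_rho)
    chol_time = np.linalg.cholesky(R_time)

    # PCS and MCS jointly: Kronecker of the 2x2 cross-instrument block with
    # the exchangeable time correlation (PSD as a Kronecker of PSD factors).
    R_pm = np.kron(_exchangeable_corr(2, cfg.pcs_mcs_rho), R_time)
    chol_pm = np.linalg.cholesky(R_pm)

    out: dict[str, np.ndarray] = {}
    for name in INSTRUMENTS:
        if name in ("PCS", "MCS"):
            continue
        z = rng.standard_normal((n_total, T)) @ chol_time.T
        out[name] = z
    z_pm = rng.standard_normal((n_total, 2 * T)) @ chol_pm.T
    out["PCS"], out["MCS"] = z_pm[:, :T], z_pm[:, T:]
    out["utility"] = rng.standard_normal((n_total, T)) @ chol_time.T

    params = dict(cfg.outcome_params)
    params["utility"] = cfg.utility_params
    for name, z in out.items():
        p = params[name]
        mean = p.baseline_mean + np.concatenate(([0.0], np.asarray(p.control_drift)))
        effect = np.concatenate(([0.0], np.asarray(p.effect)))
        vals = mean + effect * is_intervention[:, None] + p.baseline_sd * z
        lo, hi = p.score_range
        vals = np.clip(vals, lo, hi)
        if p.integer_scale:
            vals = np.rint(vals)
        out[name] = vals
    return out


def _draw_usage(cfg: TrialConfig, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    up = cfg.usage_params
    mu_d, sg_d = lognormal_from_median_iqr(up.duration_median, up.duration_iqr)
    mu_l, sg_l = lognormal_from_median_iqr(up.logins_median, up.logins_iqr)
    r = up.log_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]], size=n)
    minutes = np.exp(mu_d + sg_d * z[:, 0])
    logins = np.maximum(1, np.rint(np.exp(mu_l + sg_l * z[:, 1]))).astype(int)

    out = {"usage_minutes_total": minutes, "usage_logins_total": logins}
    w_min = np.array([up.module_duration_medians[m] for m in USAGE_MODULES], dtype=float)
    w_log = np.array([up.module_login_medians[m] for m in USAGE_MODULES], dtype=float)
    share_min = rng.dirichlet(up.dirichlet_concentration * w_min / w_min.sum(), size=n)
    share_log = rng.dirichlet(up.dirichlet_concentration * w_log / w_log.sum(), size=n)
    login_split = np.array([rng.multinomial(l, p) for l, p in zip(logins, share_log)])
    for j, mod in enumerate(USAGE_MODULES):
        out[f"usage_minutes_{mod}"] = minutes * share_min[:, j]
        out[f"usage_logins_{mod}"] = login_split[:, j]
    return out


def generate_trial(config: TrialConfig) -> pd.DataFrame:
    """Generate the complete (pre-missingness) long-format outcome panel.

    Deterministic given ``config.seed``.  Returns one row per participant
    per timepoint, sorted by participant then timepoint.
    """
    config.validate()
    rng = np.random.default_rng(config.stage_seed("generate"))
    n = config.n_per_arm
    n_total = 2 * n
    T = len(config.timepoints)

    arm = np.repeat(np.array(ARMS), n)
    is_int = (arm == "intervention").astype(float)
    endocrine = np.empty(n_total, dtype=int)
    for a in ARMS:
        mask = arm == a
        endocrine[mask] = rng.binomial(1, config.endocrine_prevalence[a], size=mask.sum())

    scores = _draw_scores(config, rng, n_total, is_int)

    direct = np.empty(n_total)
    inpatient = np.empty(n_total, dtype=int)
    visits = np.empty(n_total, dtype=int)
    cp = config.cost_params
    for a in ARMS:
        mask = arm == a
        mu, sg = _lognormal_from_mean_sd(cp.direct_mean[a], cp.direct_sd[a])
        direct[mask] = np.exp(mu + sg * rng.standard_normal(mask.sum()))
        inpatient[mask] = rng.poisson(cp.inpatient_days_mean[a], size=mask.sum())
        visits[mask] = rng.poisson(cp.clinic_visits_mean[a], size=mask.sum())

    usage = _draw_usage(config, rng, n)  # intervention arm only

    rows = {
        "participant_id": np.repeat(np.arange(1, n_total + 1), T),
        "arm": np.repeat(arm, T),
        "endocrine_therapy": np.repeat(endocrine, T),
        "timepoint": np.tile(np.array(config.timepoints), n_total),
        "time_years": np.tile(np.asarray(config.times_years, dtype=float), n_total),
    }
    for name in ANALYSIS_COLUMNS:
        rows[name] = scores[name].reshape(-1)
    for col, vals in (
        ("direct_cost", direct),
        ("inpatient_days", inpatient),
        ("clinic_visits", visits),
    ):
        rows[col] = np.repeat(vals, T)
    for col in usage:
        full = np.full(n_total, np.nan)
        full[:n] = usage[col]
        rows[col] = np.repeat(full, T)

    panel = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    validate_panel(panel)
    return panel


def apply_missingness(
    panel: pd.DataFrame,
    rate: float,
    mechanism: str = "MAR",
    seed: int | np.random.SeedSequence | None = None,
    baseline_coef: float = 0.5,
    arm_coef: float = 0.2,
) -> pd.DataFrame:
    """Impose monotone follow-up dropout on a complete panel.

    A dropout either misses both follow-ups (dropped before T1) or only the
    last one, with equal probability.  Baseline rows are never masked, and
    cost/usage records stay complete.  Under MAR, dropout is more likely
    for participants with higher baseline stigma (``baseline_coef`` per SD)
    and in the intervention arm (``arm_coef``); the logistic intercept is
    solved so the expected dropout fraction equals ``rate``.
    """
    if not 0 <= rate < 1:
        raise ConfigError("dropout rate must be in [0, 1)")
    if mechanism not in ("MAR", "MCAR"):
        raise ConfigError("mechanism must be 'MAR' or 'MCAR'")
    validate_panel(panel)
    out = panel.copy()
    if rate == 0:
        return out

    rng = np.random.default_rng(seed)
    t0 = panel[panel["timepoint"] == "T0"].set_index("participant_id")
    pids = t0.index.to_numpy()
    if mechanism == "MCAR":
        p = np.full(len(pids), rate)
    else:
        z_sis = (t0["SIS"] - t0["SIS"].mean()) / t0["SIS"].std(ddof=1)
        lin = baseline_coef * z_sis.to_numpy() + arm_coef * (t0["arm"] == "intervention").to_numpy()
        c = brentq(lambda c0: expit(c0 + lin).mean() - rate, -30.0, 30.0)
        p = expit(c + lin)

    dropout = rng.random(len(pids)) < p
    early = rng.random(len(pids)) < 0.5  # dropped before T1 (else only T2 missing)
    drop_t1 = set(pids[dropout & early])
    drop_t2 = set(pids[dropout])

    mask_t1 = out["timepoint"].eq("T1") & out["participant_id"].isin(drop_t1)
    mask_t2 = out["timepoint"].eq("T2") & out["participant_id"].isin(drop_t2)
    out.loc[mask_t1 | mask_t2, list(ANALYSIS_COLUMNS)] = np.nan
    return out
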