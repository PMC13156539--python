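"""Multiple imputation of missing follow-up outcomes, with Rubin pooling.

Two engines are provided:

``chained``
    Sequential regression with predictive-mean matching (PMM).  Because
    dropout is monotone (a participant missing T1 is missing T2), one pass
    per variable suffices: T1 is imputed from arm, endocrine therapy and
    the baseline score; T2 additionally conditions on the (completed) T1
    value.  Regression coefficients and the residual variance are drawn
    from their approximate posterior before prediction (proper imputation),
    and each missing cell receives the observed value of a randomly chosen
    donor among the ``k`` nearest predicted matches — so imputed values are
    automatically in range and on the instrument's integer grid.

``mcmc``
    A joint multivariate-normal draw: for each outcome the (T0, T1, T2)
    triple is regressed on arm and endocrine therapy among complete cases,
    the residual covariance and coefficients are drawn from their
    approximate posterior (inverse-Wishart / matrix normal), and missing
    components are drawn from the implied conditional normal, then clipped
    to the instrument range.  This mirrors a Markov-chain Monte-Carlo
    joint-model sensitivity analysis.

Non-missing cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SCORE_RANGES
from .panel import ANALYSIS_COLUMNS, validate_panel

__all__ = ["ImputationSet", "PooledEstimate", "impute", "pool"]

_RANGES = dict(SCORE_RANGES)
_RANGES["utility"] = (0.0, 1.0)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation estimates."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pool(points, variances=None) -> PooledEstimate:
    """Pool per-imputation point estimates and variances by Rubin's rules.

    ``total_var = within + (1 + 1/m) * between``;  the degrees of freedom
    use the classical small-sample formula and are infinite when the
    between-imputation variance vanishes (including m = 1).
    """
    if variances is None:
        pairs = list(points)
        points = [p for p, _ in pairs]
        variances = [v for _, v in pairs]
    points = np.asarray(list(points), dtype=float)
    variances = np.asarray(list(variances), dtype=float)
    if points.size == 0:
        raise ValueError("pool() requires at least one estimate")
    if points.shape != variances.shape:
        raise ValueError("points and variances must have equal length")
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    m = points.size
    point = float(points.mean())
    within = float(variances.mean())
    between = float(points.var(ddof=1)) if m > 1 else 0.0
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
    else:
        df = np.inf
    return PooledEstimate(point, within, between, total, float(df), m)


@dataclass
class ImputationSet:
    """m completed copies of an outcome panel."""

    panels: list[pd.DataFrame]
    method: str
    seed: int | None = None
    source: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)


def _wide(panel: pd.DataFrame, var: str) -> pd.DataFrame:
    w = panel.pivot(index="participant_id", columns="timepoint", values=var)
    meta = panel[panel["timepoint"] == "T0"].set_index("participant_id")
    w["_arm"] = (meta["arm"] == "intervention").astype(float)
    w["_endo"] = meta["endocrine_therapy"].astype(float)
    return w


def _posterior_ols_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Draw (beta*, sigma*) from the approximate OLS posterior."""
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    rss = float(resid @ resid)
    sigma2 = rss / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2 * XtX_inv
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    return beta, np.sqrt(sigma2), beta_hat


def _pmm_fill(X_obs, y_obs, X_mis, rng, k=5):
    """Predictive-mean-matching draws for the missing rows."""
    beta, _, _ = _posterior_ols_draw(X_obs, y_obs, rng)
    pred_obs = X_obs @ beta
    pred_mis = X_mis @ beta
    filled = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        order = np.argsort(np.abs(pred_obs - pm))[: min(k, len(pred_obs))]
        filled[i] = y_obs[rng.choice(order)]
    return filled


def _chained_context(panel: pd.DataFrame):
    """Precompute numpy views reused across the m imputation draws."""
    t0 = panel[panel["timepoint"] == "T0"].set_index("participant_id")
    subjects = t0.index.to_numpy()
    arm = (t0["arm"] == "intervention").to_numpy(float)
    endo = t0["endocrine_therapy"].to_numpy(float)
    long_idx = pd.MultiIndex.from_arrays(
        [panel["participant_id"].to_numpy(), panel["timepoint"].to_numpy()]
    )
    tps = ("T0", "T1", "T2")
    pos = {
        tp: long_idx.get_indexer(
            pd.MultiIndex.from_arrays([subjects, np.full(len(subjects), tp, dtype=object)])
        )
        for tp in tps
    }
    wides = {
        var: np.column_stack([panel[var].to_numpy(float)[pos[tp]] for tp in tps])
        for var in ANALYSIS_COLUMNS
    }
    return arm, endo, pos, wides


def _impute_chained_once(panel: pd.DataFrame, rng: np.random.Generator,
                         ctx=None) -> pd.DataFrame:
    arm, endo, pos, wides = ctx if ctx is not None else _chained_context(panel)
    ones = np.ones(len(arm))
    out = panel.copy()
    for var in ANALYSIS_COLUMNS:
        W = wides[var].copy()
        # T1 from (arm, endocrine, baseline); T2 additionally from the
        # completed T1 (monotone-dropout sequential regression).
        for t_idx, extra in ((1, ()), (2, (1,))):
            y = W[:, t_idx]
            miss = np.isnan(y)
            if not miss.any():
                continue
            X = np.column_stack([ones, arm, endo, W[:, 0]] + [W[:, j] for j in extra])
            obs = ~miss & ~np.isnan(X).any(axis=1)
            W[miss, t_idx] = _pmm_fill(X[obs], y[obs], X[miss], rng)
        col = panel[var].to_numpy(float).copy()
        for t_idx, tp in enumerate(("T0", "T1", "T2")):
            col[pos[tp]] = W[:, t_idx]
        out[var] = col
    return out


def _impute_mcmc_once(panel: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    out = panel.copy()
    tps = ["T0", "T1", "T2"]
    for var in ANALYSIS_COLUMNS:
        w = _wide(panel, var)
        Y = w[tps].to_numpy()
        X = np.column_stack([np.ones(len(w)), w["_arm"].to_numpy(), w["_endo"].to_numpy()])
        complete = ~np.isnan(Y).any(axis=1)
        if complete.all():
            continue
        Xc, Yc = X[complete], Y[complete]
        n, p = Xc.shape
        XtX_inv = np.linalg.pinv(Xc.T @ Xc)
        B_hat = XtX_inv @ Xc.T @ Yc
        E = Yc - Xc @ B_hat
        S = E.T @ E
        dof = max(n - p, len(tps) + 2)
        Sigma = stats.invwishart.rvs(df=dof, scale=S, random_state=rng)
        # matrix-normal coefficient draw: B* = B_hat + chol(XtX_inv) Z chol(Sigma)'
        A = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
        C = np.linalg.cholesky(Sigma)
        B = B_hat + A @ rng.standard_normal((p, len(tps))) @ C.T
        Mu = X @ B

        lo, hi = _RANGES[var]
        integer = var in SCORE_RANGES and panel[var].dropna().mod(1).eq(0).all()
        for i in np.flatnonzero(~complete):
            miss = np.isnan(Y[i])
            obs = ~miss
            S11 = Sigma[np.ix_(miss, miss)]
            if obs.any():
                S12 = Sigma[np.ix_(miss, obs)]
                S22i = np.linalg.pinv(Sigma[np.ix_(obs, obs)])
                mu_c = Mu[i, miss] + S12 @ S22i @ (Y[i, obs] - Mu[i, obs])
                cov_c = S11 - S12 @ S22i @ S12.T
            else:
                mu_c, cov_c = Mu[i, miss], S11
            draw = rng.multivariate_normal(mu_c, cov_c, method="svd")
            draw = np.clip(draw, lo, hi)
            if integer:
                draw = np.rint(draw)
            pid = w.index[i]
            for j, t in enumerate(np.array(tps)[miss]):
                out.loc[out["timepoint"].eq(t) & out["participant_id"].eq(pid), var] = draw[j]
    return out


def impute(
    panel: pd.DataFrame,
    m: int = 20,
    method: str = "chained",
    seed: int | np.random.SeedSequence | None = None,
) -> ImputationSet:
    """Produce ``m`` completed panels.  Deterministic given ``seed``.

    Missingness must be confined to follow-up analysis variables; missing
    baseline values violate the study design and raise.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if method not in ("chained", "mcmc"):
        raise ValueError("method must be 'chained' or 'mcmc'")
    validate_panel(panel)  # rejects missing baselines

    if not panel[list(ANALYSIS_COLUMNS)].isna().any().any():
        return ImputationSet([panel.copy() for _ in range(m)], method, seed, source=panel)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if method == "chained":
        ctx = _chained_context(panel)
        panels = [
            _impute_chained_once(panel, np.random.default_rng(child), ctx)
            for child in ss.spawn(m)
        ]
    else:
        panels = [_impute_mcmc_once(panel, np.random.default_rng(child)) for child in ss.spawn(m)]
    for completed in panels:
        # structure is inherited from the validated source; only
        # completeness can change
        if completed[list(ANALYSIS_COLUMNS)].isna().any().any():
            raise RuntimeError("imputation left missing analysis values")
    return ImputationSet(panels, method, seed, source=panel)
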