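"""Cost-effectiveness evaluation: incremental analysis, ICER/dominance,
net monetary benefit, stratified bootstrap with BCa intervals, the
cost-effectiveness plane, and the acceptability curve (CEAC).

Participants are resampled with replacement within arm (stratified, which
preserves the 1:1 design); each replicate recomputes covariate-adjusted
arm differences in total cost and QALYs — costs adjusted for endocrine
therapy, QALYs additionally for baseline utility — via least squares.
BCa intervals correct the percentile interval for median bias (z0, from
the fraction of replicates below the point estimate) and for skewness
(acceleration a, from jackknife leave-one-out estimates).

The acceptability curve reports, for each willingness-to-pay value
lambda, the fraction of replicates with positive net monetary benefit
lambda * dE - dC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CEADraws",
    "CEAResult",
    "ICERLabel",
    "icer",
    "nmb",
    "bootstrap_cea",
    "bca_interval",
    "ce_plane",
    "ceac",
    "run_cea",
]

#: |dE| below this is treated as zero effect (report NMB, not a ratio).
ICER_EPSILON = 1e-9


@dataclass(frozen=True)
class ICERLabel:
    """ICER as a labelled point on the cost-effectiveness plane."""

    kind: str                  # 'ratio' | 'intervention-dominant' | 'control-dominant' | 'indeterminate'
    value: float | None = None # US$ per QALY when kind == 'ratio'

    def __str__(self) -> str:
        return f"{self.value:,.2f} $/QALY" if self.kind == "ratio" else self.kind


def icer(delta_cost: float, delta_qaly: float) -> ICERLabel:
    """Label the incremental cost-effectiveness ratio.

    More effective and cheaper -> intervention dominates; less effective
    and at least as costly -> control dominates; negligible QALY
    difference -> indeterminate (decide on NMB instead); otherwise the
    ratio dC/dE (also for the less-effective-and-cheaper quadrant, where
    the ratio is read against the threshold from the other side).
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_qaly)):
        raise ValueError("delta_cost and delta_qaly must be finite")
    if abs(delta_qaly) < ICER_EPSILON:
        return ICERLabel("indeterminate")
    if delta_qaly > 0 and delta_cost <= 0:
        return ICERLabel("intervention-dominant")
    if delta_qaly < 0 and delta_cost >= 0:
        return ICERLabel("control-dominant")
    return ICERLabel("ratio", delta_cost / delta_qaly)


def nmb(delta_cost: float, delta_qaly: float, lam: float) -> float:
    """Net monetary benefit lambda * dE - dC at willingness-to-pay lambda."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * delta_qaly - delta_cost


@dataclass
class CEADraws:
    """Bootstrap replicates of (incremental cost, incremental QALYs)."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    point_delta_cost: float
    point_delta_qaly: float
    jackknife_delta_cost: np.ndarray
    jackknife_delta_qaly: np.ndarray
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.delta_cost)


def _adjusted_deltas(df: pd.DataFrame) -> tuple[float, float]:
    """Covariate-adjusted arm differences (intervention - control)."""
    g = (df["arm"] == "intervention").to_numpy(float)
    endo = df["endocrine_therapy"].to_numpy(float)
    Xc = np.column_stack([np.ones(len(df)), g, endo])
    dc = np.linalg.lstsq(Xc, df["total_cost"].to_numpy(float), rcond=None)[0][1]
    Xq = np.column_stack([Xc, df["baseline_utility"].to_numpy(float)])
    de = np.linalg.lstsq(Xq, df["qaly"].to_numpy(float), rcond=None)[0][1]
    return float(dc), float(de)


def _raw_deltas(df: pd.DataFrame) -> tuple[float, float]:
    by = df.groupby("arm")[["total_cost", "qaly"]].mean()
    d = by.loc["intervention"] - by.loc["control"]
    return float(d["total_cost"]), float(d["qaly"])


def bootstrap_cea(
    data: pd.DataFrame,
    B: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    adjusted: bool = True,
) -> CEADraws:
    """Stratified participant-level bootstrap of (dC, dE).

    ``data`` holds one row per participant with columns ``arm,
    endocrine_therapy, baseline_utility, total_cost, qaly``.  Resampling
    is with replacement within arm; ``adjusted=False`` is an unadjusted
    fast path (plain arm-mean differences, vectorized) used for large
    property studies.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    for arm in ("intervention", "control"):
        if (data["arm"] == arm).sum() < 2:
            raise ValueError(f"need at least 2 participants in arm '{arm}'")
    rng = np.random.default_rng(seed)
    estimator = _adjusted_deltas if adjusted else _raw_deltas

    point_dc, point_de = estimator(data)

    idx_int = np.flatnonzero((data["arm"] == "intervention").to_numpy())
    idx_ctl = np.flatnonzero((data["arm"] == "control").to_numpy())

    if not adjusted:
        cost = data["total_cost"].to_numpy(float)
        qaly = data["qaly"].to_numpy(float)
        ri = rng.integers(0, len(idx_int), size=(B, len(idx_int)))
        rc = rng.integers(0, len(idx_ctl), size=(B, len(idx_ctl)))
        dc = cost[idx_int[ri]].mean(axis=1) - cost[idx_ctl[rc]].mean(axis=1)
        de = qaly[idx_int[ri]].mean(axis=1) - qaly[idx_ctl[rc]].mean(axis=1)
    else:
        dc = np.empty(B)
        de = np.empty(B)
        for b in range(B):
            take = np.concatenate(
                [idx_int[rng.integers(0, len(idx_int), len(idx_int))],
                 idx_ctl[rng.integers(0, len(idx_ctl), len(idx_ctl))]]
            )
            dc[b], de[b] = estimator(data.iloc[take])

    # jackknife (leave-one-out) estimates for the BCa acceleration
    n = len(data)
    jdc = np.empty(n)
    jde = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        jdc[i], jde[i] = estimator(data.iloc[np.flatnonzero(keep)])
        keep[i] = True

    return CEADraws(dc, de, point_dc, point_de, jdc, jde,
                    seed=seed if isinstance(seed, (int, np.integer)) else None)


def bca_interval(
    draws: np.ndarray,
    point_estimate: float,
    jackknife_estimates: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    z0 from the fraction of replicates below the point estimate;
    acceleration from the jackknife third-moment skewness; endpoints are
    percentiles of the replicates at the adjusted quantiles.  Degenerate
    replicate sets collapse to (point, point).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 bootstrap replicates for interval reporting")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.ptp(draws) == 0:
        return (float(point_estimate), float(point_estimate))

    prop = np.mean(draws < point_estimate) + 0.5 * np.mean(draws == point_estimate)
    prop = min(max(prop, 1.0 / (2 * draws.size)), 1.0 - 1.0 / (2 * draws.size))
    z0 = stats.norm.ppf(prop)

    jk = np.asarray(jackknife_estimates, dtype=float)
    dev = jk.mean() - jk
    denom = 6.0 * np.sum(dev**2) ** 1.5
    a = float(np.sum(dev**3) / denom) if denom > 0 else 0.0

    lo, hi = [], []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        (lo if z_alpha < 0 else hi).append(stats.norm.cdf(adj))
    return (
        float(np.quantile(draws, lo[0])),
        float(np.quantile(draws, hi[0])),
    )


def ce_plane(draws: CEADraws) -> dict[str, float]:
    """Quadrant proportions of the bootstrap cloud on the CE plane.

    Tie rule: dE = 0 counts as east (at least as effective), dC = 0 as
    south (no extra cost), so NE = (dE >= 0, dC > 0), SE = (dE >= 0,
    dC <= 0), SW = (dE < 0, dC <= 0), NW = (dE < 0, dC > 0); the four
    proportions partition the replicates.
    """
    if draws.B == 0:
        raise ValueError("no bootstrap draws")
    east = draws.delta_qaly >= 0
    north = draws.delta_cost > 0
    B = draws.B
    return {
        "NE": float(np.sum(east & north)) / B,
        "SE": float(np.sum(east & ~north)) / B,
        "SW": float(np.sum(~east & ~north)) / B,
        "NW": float(np.sum(~east & north)) / B,
    }


def ceac(draws: CEADraws, lambda_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    probability(lambda) = fraction of replicates with lambda*dE - dC > 0.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("lambda grid must be non-empty and non-negative")
    probs = [
        float(np.mean(lam * draws.delta_qaly - draws.delta_cost > 0)) for lam in grid
    ]
    return pd.DataFrame({"wtp": grid, "probability": probs})


@dataclass
class CEAResult:
    """Point incremental analysis plus bootstrap uncertainty summaries."""

    delta_cost: float
    delta_qaly: float
    icer_label: ICERLabel
    nmb_at_threshold: float
    threshold_lambda: float
    bca_ci_delta_cost: tuple[float, float]
    bca_ci_delta_qaly: tuple[float, float]
    quadrant_proportions: dict[str, float]
    ceac_curve: pd.DataFrame = field(repr=False)
    prob_ce_at_threshold: float
    B: int


def run_cea(
    draws: CEADraws,
    threshold_lambda: float = 37_530.0,
    lambda_grid=None,
    alpha: float = 0.05,
) -> CEAResult:
    """Assemble the full cost-effectiveness result from bootstrap draws."""
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 200_000.0 + 250.0, 500.0)
    curve = ceac(draws, lambda_grid)
    at_thr = float(
        np.mean(threshold_lambda * draws.delta_qaly - draws.delta_cost > 0)
    )
    return CEAResult(
        delta_cost=draws.point_delta_cost,
        delta_qaly=draws.point_delta_qaly,
        icer_label=icer(draws.point_delta_cost, draws.point_delta_qaly),
        nmb_at_threshold=nmb(draws.point_delta_cost, draws.point_delta_qaly, threshold_lambda),
        threshold_lambda=threshold_lambda,
        bca_ci_delta_cost=bca_interval(
            draws.delta_cost, draws.point_delta_cost, draws.jackknife_delta_cost, alpha
        ),
        bca_ci_delta_qaly=bca_interval(
            draws.delta_qaly, draws.point_delta_qaly, draws.jackknife_delta_qaly, alpha
        ),
        quadrant_proportions=ce_plane(draws),
        ceac_curve=curve,
        prob_ce_at_threshold=at_thr,
        B=draws.B,
    )
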