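"""Pipeline orchestration and rendering of study-style tables and figures.

``run_pipeline`` executes the whole synthetic study end-to-end —
simulate -> dropout -> multiple imputation -> GEE effectiveness table ->
sensitivity (joint-MVN) imputation -> societal costs -> QALYs -> bootstrap
cost-effectiveness — and writes five comma-separated tables, three
figures and a JSON run manifest with checksums, so that a run is
reproducible byte-for-byte (data tables; figures excepted) from the
config and seed alone.

Display rounding is half-up to two decimals and happens only at render
time; all computation upstream is full precision.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .config import INSTRUMENTS, TrialConfig
from .panel import USAGE_MODULES, baseline_table, write_panel
from .synthetic import generate_trial, apply_missingness
from .imputation import ImputationSet, impute
from .effectiveness import fit_gee, group_contrast, pooled_baseline_sd
from .costs import participant_costs
from .qaly import panel_qalys
from .cea import CEADraws, bootstrap_cea, run_cea

__all__ = ["summarize_usage", "UsageSummary", "effects_table", "run_pipeline", "RunManifest"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for money and table display."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# usage summaries
# --------------------------------------------------------------------------

@dataclass
class UsageSummary:
    """Per-module usage statistics plus the expected-use rate."""

    table: pd.DataFrame
    expected_use_flags: pd.Series
    expected_use_rate: float


def summarize_usage(
    usage: pd.DataFrame,
    min_logins: int = 10,
    min_minutes: float = 50.0,
) -> UsageSummary:
    """Summaries of app usage records (one row per participant).

    Expects ``usage_minutes_*`` / ``usage_logins_*`` columns for the
    modules and ``_total``.  A participant meets expected use when total
    logins >= ``min_logins`` AND total minutes >= ``min_minutes`` (both
    thresholds inclusive).
    """
    if len(usage) == 0:
        raise ValueError("no usage records")
    units = ("total",) + USAGE_MODULES
    rows = []
    for unit in units:
        minutes = usage[f"usage_minutes_{unit}"].astype(float)
        logins = usage[f"usage_logins_{unit}"].astype(float)
        if (minutes < 0).any() or (logins < 0).any():
            raise ValueError("usage values must be non-negative")
        rows.append(
            {
                "unit": "entire_program" if unit == "total" else unit,
                "duration_median": minutes.median(),
                "duration_q1": minutes.quantile(0.25),
                "duration_q3": minutes.quantile(0.75),
                "duration_mean": minutes.mean(),
                "duration_sd": minutes.std(ddof=1) if len(minutes) > 1 else 0.0,
                "duration_max": minutes.max(),
                "logins_median": logins.median(),
                "logins_q1": logins.quantile(0.25),
                "logins_q3": logins.quantile(0.75),
                "logins_mean": logins.mean(),
                "logins_sd": logins.std(ddof=1) if len(logins) > 1 else 0.0,
                "logins_max": logins.max(),
            }
        )
    flags = (usage["usage_logins_total"] >= min_logins) & (
        usage["usage_minutes_total"] >= min_minutes
    )
    return UsageSummary(
        table=pd.DataFrame(rows).set_index("unit"),
        expected_use_flags=flags,
        expected_use_rate=float(flags.mean()),
    )


# --------------------------------------------------------------------------
# effectiveness table
# --------------------------------------------------------------------------

def effects_table(
    data,
    source_panel: pd.DataFrame,
    outcomes=INSTRUMENTS,
    k_comparisons: int = 2,
) -> pd.DataFrame:
    """Adjusted per-timepoint contrasts for each outcome, table-style.

    ``data`` is a panel or ImputationSet; ``source_panel`` supplies the
    unadjusted baseline arm SDs for Cohen d and the MICD threshold.
    """
    base = baseline_table(source_panel)
    rows = []
    for outcome in outcomes:
        sd = pooled_baseline_sd(
            base.loc["intervention", f"{outcome}_sd"],
            base.loc["control", f"{outcome}_sd"],
            int(base.loc["intervention", "n"]),
            int(base.loc["control", "n"]),
        )
        fit = fit_gee(data, outcome)
        for tp in fit.timepoints:
            c = group_contrast(fit, tp, k_comparisons=k_comparisons, baseline_sd=sd)
            rows.append(
                {
                    "outcome": outcome,
                    "timepoint": tp,
                    "adjusted_mean_difference": c.adjusted_mean_difference,
                    "ci_low": c.ci_95[0],
                    "ci_high": c.ci_95[1],
                    "p_raw": c.p_raw,
                    "p_bonferroni": c.p_bonferroni,
                    "cohen_d": c.cohen_d,
                    "micd": c.micd,
                    "exceeds_micd": c.exceeds_micd,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cost-effectiveness assembly
# --------------------------------------------------------------------------

def _cea_inputs(completed_panel: pd.DataFrame, config: TrialConfig) -> pd.DataFrame:
    costs = participant_costs(completed_panel, config.cost_params)
    qalys = panel_qalys(completed_panel)
    df = costs.join(qalys[["baseline_utility", "qaly"]])
    df = df.rename(columns={"total": "total_cost"})
    return df.reset_index()


def mi_bootstrap_cea(
    imputation_set: ImputationSet,
    config: TrialConfig,
    B: int | None = None,
    seed=None,
    mi_mode: str = "concat",
) -> CEADraws:
    """Bootstrap (dC, dE) across an imputation set.

    ``concat`` runs B/m replicates on each completed dataset and pools the
    draws (imputation noise propagates into the cloud); ``first`` uses only
    the first completed dataset.  Point estimates average the per-dataset
    adjusted differences; the jackknife for the BCa acceleration comes
    from the first completed dataset.
    """
    if mi_mode not in ("concat", "first"):
        raise ValueError("mi_mode must be 'concat' or 'first'")
    B = int(B if B is not None else config.bootstrap_replicates)
    panels = imputation_set.panels if mi_mode == "concat" else imputation_set.panels[:1]
    m = len(panels)
    per = max(100, B // m)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(m)
    parts = [
        bootstrap_cea(_cea_inputs(p, config), B=per, seed=child)
        for p, child in zip(panels, children)
    ]
    return CEADraws(
        delta_cost=np.concatenate([d.delta_cost for d in parts]),
        delta_qaly=np.concatenate([d.delta_qaly for d in parts]),
        point_delta_cost=float(np.mean([d.point_delta_cost for d in parts])),
        point_delta_qaly=float(np.mean([d.point_delta_qaly for d in parts])),
        jackknife_delta_cost=parts[0].jackknife_delta_cost,
        jackknife_delta_qaly=parts[0].jackknife_delta_qaly,
    )


def _cost_utility_table(
    imputation_set: ImputationSet, config: TrialConfig, cea_result
) -> pd.DataFrame:
    """Arm-level cost / utility / QALY accounting table."""
    costs = participant_costs(imputation_set.panels[0], config.cost_params)
    by_arm = costs.groupby("arm")[["fixed_share", "direct", "indirect", "total"]].agg(
        ["mean", "sem"]
    )
    rows = []
    for comp in ("fixed_share", "direct", "indirect", "total"):
        rows.append(
            {
                "row": f"cost_{comp}",
                "intervention_mean": by_arm.loc["intervention", (comp, "mean")],
                "intervention_se": by_arm.loc["intervention", (comp, "sem")],
                "control_mean": by_arm.loc["control", (comp, "mean")],
                "control_se": by_arm.loc["control", (comp, "sem")],
                "difference": by_arm.loc["intervention", (comp, "mean")]
                - by_arm.loc["control", (comp, "mean")],
            }
        )
    # utilities by timepoint, averaged over completed datasets
    for tp in config.timepoints:
        vals = []
        for p in imputation_set.panels:
            sub = p[p["timepoint"] == tp]
            g = sub.groupby("arm")["utility"]
            vals.append((g.mean(), g.sem()))
        mean = sum(v[0] for v in vals) / len(vals)
        se = sum(v[1] for v in vals) / len(vals)
        rows.append(
            {
                "row": f"utility_{tp}",
                "intervention_mean": mean["intervention"],
                "intervention_se": se["intervention"],
                "control_mean": mean["control"],
                "control_se": se["control"],
                "difference": mean["intervention"] - mean["control"],
            }
        )
    qaly_means = []
    for p in imputation_set.panels:
        g = panel_qalys(p).groupby("arm")["qaly"]
        qaly_means.append((g.mean(), g.sem()))
    qmean = sum(v[0] for v in qaly_means) / len(qaly_means)
    qse = sum(v[1] for v in qaly_means) / len(qaly_means)
    rows.append(
        {
            "row": "qaly_T0_T2",
            "intervention_mean": qmean["intervention"],
            "intervention_se": qse["intervention"],
            "control_mean": qmean["control"],
            "control_se": qse["control"],
            "difference": cea_result.delta_qaly,
        }
    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# manifest and pipeline
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run."""

    config: dict
    seed: int
    versions: dict
    tables: list[str] = field(default_factory=list)
    figures: list[str] = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _render(df: pd.DataFrame, path: Path, ndigits: int = 4) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: round_half_up(v, ndigits) if pd.notna(v) else v)
    out.to_csv(path, index=False)


def _fig_outcomes(panel: pd.DataFrame, path: Path, config: TrialConfig) -> None:
    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
    for ax, name in zip(axes.ravel(), INSTRUMENTS):
        for arm, style in (("intervention", "-o"), ("control", "--s")):
            sub = panel[panel["arm"] == arm]
            means = sub.groupby("timepoint")[name].mean().reindex(config.timepoints)
            ax.plot(config.times_years, means.to_numpy(), style, label=arm)
        ax.set_title(name)
        ax.set_xlabel("years")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_ce_plane(draws: CEADraws, threshold: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws.delta_qaly, draws.delta_cost, s=4, alpha=0.25, rasterized=True)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    xs = np.linspace(*ax.get_xlim(), 10)
    ax.plot(xs, threshold * xs, "r--", lw=1, label=f"threshold {threshold:,.0f} $/QALY")
    ax.plot([draws.point_delta_qaly], [draws.point_delta_cost], "r*", ms=12)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (US$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_ceac(curve: pd.DataFrame, threshold: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability"])
    ax.axvline(threshold, color="r", ls="--", lw=1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("willingness to pay (US$ per QALY)")
    ax.set_ylabel("probability cost-effective")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: TrialConfig, out_dir, seed: int | None = None) -> RunManifest:
    """Run the whole synthetic study and write tables, figures, manifest.

    Stages: simulate -> missingness -> impute (chained) -> effectiveness
    table -> sensitivity (joint-MVN) table -> costs -> QALYs -> bootstrap
    CEA -> usage summary.  Idempotent given the config and seed: data
    tables are byte-identical across reruns.
    """
    if seed is not None:
        config = TrialConfig.from_dict(config.to_dict())
        config.seed = int(seed)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = generate_trial(config)
    observed = apply_missingness(
        panel,
        config.dropout_rate,
        config.missing_mechanism,
        seed=config.stage_seed("missingness"),
        baseline_coef=config.mar_baseline_coef,
        arm_coef=config.mar_arm_coef,
    )
    write_panel(panel, out / "panel_complete.csv")
    write_panel(observed, out / "panel_observed.csv")

    imp = impute(observed, config.m_imputations, config.imputation_method,
                 seed=config.stage_seed("impute"))
    imp_mcmc = impute(observed, config.m_imputations, "mcmc",
                      seed=config.stage_seed("impute_mcmc"))

    table1 = baseline_table(observed).reset_index()
    table2 = effects_table(imp, observed, k_comparisons=config.bonferroni_k)
    table3 = effects_table(imp_mcmc, observed, outcomes=("BIS", "SIS"),
                           k_comparisons=config.bonferroni_k)

    draws = mi_bootstrap_cea(imp, config, seed=config.stage_seed("bootstrap"))
    cea_result = run_cea(draws, threshold_lambda=config.wtp_threshold,
                         lambda_grid=config.wtp_grid)
    table4 = _cost_utility_table(imp, config, cea_result)

    usage = summarize_usage(
        panel[(panel["arm"] == "intervention") & (panel["timepoint"] == "T0")],
        min_logins=config.usage_params.expected_use_min_logins,
        min_minutes=config.usage_params.expected_use_min_minutes,
    )
    table5 = usage.table.reset_index()

    summary = pd.DataFrame(
        [
            {
                "delta_cost": cea_result.delta_cost,
                "delta_qaly": cea_result.delta_qaly,
                "icer": str(cea_result.icer_label),
                "nmb_at_threshold": cea_result.nmb_at_threshold,
                "threshold": cea_result.threshold_lambda,
                "prob_ce_at_threshold": cea_result.prob_ce_at_threshold,
                "dc_ci_low": cea_result.bca_ci_delta_cost[0],
                "dc_ci_high": cea_result.bca_ci_delta_cost[1],
                "de_ci_low": cea_result.bca_ci_delta_qaly[0],
                "de_ci_high": cea_result.bca_ci_delta_qaly[1],
                "expected_use_rate": usage.expected_use_rate,
                **{f"quadrant_{k}": v for k, v in cea_result.quadrant_proportions.items()},
            }
        ]
    )

    tables = {
        "table1_baseline.csv": table1,
        "table2_effects.csv": table2,
        "table3_sensitivity.csv": table3,
        "table4_cost_utility.csv": table4,
        "table5_usage.csv": table5,
        "cea_summary.csv": summary,
        "ceac_curve.csv": cea_result.ceac_curve,
    }
    for fname, df in tables.items():
        _render(df, out / fname)

    figures = {
        "fig_outcomes.png": lambda p: _fig_outcomes(panel, p, config),
        "fig_ce_plane.png": lambda p: _fig_ce_plane(draws, config.wtp_threshold, p),
        "fig_ceac.png": lambda p: _fig_ceac(cea_result.ceac_curve, config.wtp_threshold, p),
    }
    for fname, drawfn in figures.items():
        drawfn(out / fname)

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        versions={
            "trialcea": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        tables=sorted(tables) + ["panel_complete.csv", "panel_observed.csv"],
        figures=sorted(figures),
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    for fname in manifest.tables:
        manifest.checksums[fname] = _sha256(out / fname)
    manifest.to_json(out / "manifest.json")
    return manifest
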