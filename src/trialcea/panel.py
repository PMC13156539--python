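"""Long-format outcome panel: schema, validation and CSV round-trip.

One row per participant x timepoint.  Score and utility cells may be
missing (empty in CSV, NaN in memory) at follow-ups only; baseline rows are
always complete.  Cumulative six-month cost and usage totals are repeated
on every row of a participant (one value per participant).

Column dictionary
-----------------
participant_id      integer, unique within arm-combined cohort
arm                 'intervention' or 'control'
endocrine_therapy   0/1, baseline covariate the analysis adjusts for
timepoint           'T0', 'T1', 'T2'
time_years          assessment time in years from baseline
BIS..MCS            instrument totals (see config.SCORE_RANGES)
utility             health utility in [0, 1]
direct_cost         cumulative six-month direct medical cost, US$
inpatient_days      inpatient days over the six months
clinic_visits       outpatient clinic visits over the six months
usage_minutes_*     app usage duration, minutes (intervention arm only)
usage_logins_*      app login counts (intervention arm only)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ARMS, INSTRUMENTS, SCORE_RANGES, TIMEPOINTS

USAGE_MODULES = ("library", "yoga", "practice")
USAGE_COLUMNS = tuple(
    f"usage_{kind}_{mod}" for kind in ("minutes", "logins") for mod in USAGE_MODULES + ("total",)
)

ANALYSIS_COLUMNS = INSTRUMENTS + ("utility",)

PANEL_COLUMNS = (
    ("participant_id", "arm", "endocrine_therapy", "timepoint", "time_years")
    + ANALYSIS_COLUMNS
    + ("direct_cost", "inpatient_days", "clinic_visits")
    + USAGE_COLUMNS
)


class PanelError(ValueError):
    """The table does not satisfy the outcome-panel schema."""


def validate_panel(panel: pd.DataFrame, require_complete: bool = False) -> None:
    """Raise :class:`PanelError` unless ``panel`` is a valid outcome panel."""
    missing_cols = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing_cols:
        raise PanelError(f"panel is missing columns: {missing_cols}")
    if not set(panel["arm"].unique()) <= set(ARMS):
        raise PanelError(f"arm labels must be within {ARMS}")
    bad_tp = set(panel["timepoint"].unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise PanelError(f"unknown timepoints: {sorted(bad_tp)}")
    counts = panel.groupby("participant_id", sort=False)["timepoint"].agg(["size", "nunique"])
    if (counts["size"] != len(TIMEPOINTS)).any() or (counts["nunique"] != len(TIMEPOINTS)).any():
        raise PanelError("expected exactly one row per participant per timepoint")
    baseline = panel[panel["timepoint"] == TIMEPOINTS[0]]
    if baseline[list(ANALYSIS_COLUMNS)].isna().any().any():
        raise PanelError("baseline (T0) analysis variables must be complete")
    for col in ("direct_cost", "inpatient_days", "clinic_visits"):
        if (panel[col] < 0).any():
            raise PanelError(f"{col} must be non-negative")
    usage = panel.loc[panel["arm"] == "intervention", list(USAGE_COLUMNS)]
    if (usage < 0).any().any():
        raise PanelError("usage columns must be non-negative")
    for name in INSTRUMENTS:
        lo, hi = SCORE_RANGES[name]
        vals = panel[name].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise PanelError(f"{name} outside its score range [{lo}, {hi}]")
    util = panel["utility"].dropna()
    if ((util < 0) | (util > 1)).any():
        raise PanelError("utility outside [0, 1]")
    if require_complete and panel[list(ANALYSIS_COLUMNS)].isna().any().any():
        raise PanelError("panel contains missing analysis values")


def write_panel(panel: pd.DataFrame, path) -> None:
    validate_panel(panel)
    panel.to_csv(path, index=False, columns=list(PANEL_COLUMNS))


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(
        path,
        dtype={"participant_id": np.int64, "arm": str, "timepoint": str},
    )
    validate_panel(panel)
    return panel


def baseline_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-arm baseline means/SDs and endocrine-therapy prevalence."""
    t0 = panel[panel["timepoint"] == TIMEPOINTS[0]]
    rows = []
    for arm, grp in t0.groupby("arm"):
        row = {"arm": arm, "n": len(grp), "endocrine_therapy_prop": grp["endocrine_therapy"].mean()}
        for name in ANALYSIS_COLUMNS:
            row[f"{name}_mean"] = grp[name].mean()
            row[f"{name}_sd"] = grp[name].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("arm").sort_index()
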