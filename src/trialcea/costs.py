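"""Societal cost model: amortized fixed program costs, direct medical
costs, and human-capital indirect costs (2023 US$).

Fixed one-time and recurring program costs are amortized over the program
horizon as an annuity-due (the first recurring payment falls at the start
of year one, undiscounted) and divided into equal per-participant shares
per six-month period.  Indirect costs value time lost to care at the
average daily labor income, counting an outpatient clinic visit as half a
day.  Monetary amounts are carried at full precision; rounding to cents is
a reporting concern (see :mod:`trialcea.reporting`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FixedCostInputs, CostParams

__all__ = [
    "amortize_fixed_costs",
    "per_participant_period_share",
    "daily_income",
    "indirect_cost",
    "total_cost",
    "convert_currency",
    "participant_costs",
]


def amortize_fixed_costs(inputs: FixedCostInputs) -> float:
    """Present value of fixed program costs over the horizon.

    PV = one_time + sum_{t=0..Y-1} annual / (1 + r)^t  (annuity-due).
    """
    inputs.validate()
    r = inputs.discount_rate
    t = np.arange(inputs.horizon_years)
    return float(inputs.one_time_costs + np.sum(inputs.annual_recurring / (1.0 + r) ** t))


def per_participant_period_share(
    total_pv: float,
    horizon_years: int,
    periods_per_year: int,
    n_participants: int,
) -> float:
    """Equal per-participant share of the fixed-cost PV for one period."""
    if total_pv < 0:
        raise ValueError("total_pv must be non-negative")
    divisor = horizon_years * periods_per_year * n_participants
    if divisor <= 0:
        raise ValueError("horizon, periods and participant count must be positive")
    return total_pv / divisor


def daily_income(annual_income: float, working_days_per_year: float) -> float:
    """Average daily labor income (annual income / working days)."""
    if working_days_per_year <= 0:
        raise ValueError("working_days_per_year must be positive")
    if annual_income < 0:
        raise ValueError("annual_income must be non-negative")
    return annual_income / working_days_per_year


def indirect_cost(inpatient_days: float, clinic_visits: float, daily_income_: float) -> float:
    """Human-capital productivity loss: (days + visits/2) x daily income."""
    if inpatient_days < 0 or clinic_visits < 0:
        raise ValueError("utilisation counts must be non-negative")
    return (inpatient_days + 0.5 * clinic_visits) * daily_income_


def total_cost(direct: float, indirect: float, fixed_share: float) -> float:
    """Six-month societal total: direct + indirect + fixed share."""
    if min(direct, indirect, fixed_share) < 0:
        raise ValueError("cost components must be non-negative")
    return direct + indirect + fixed_share


def convert_currency(amount: float, rate: float) -> float:
    """Convert an amount to US$ given an exchange rate in CNY per USD."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount / rate


def participant_costs(panel: pd.DataFrame, cost_params: CostParams) -> pd.DataFrame:
    """Per-participant six-month cost breakdown from an outcome panel.

    The fixed-cost share applies to intervention participants only (the
    program was not delivered to the control arm).  Returns one row per
    participant with columns ``arm, endocrine_therapy, fixed_share,
    direct, indirect, total``.
    """
    fx = cost_params.fixed
    share = per_participant_period_share(
        amortize_fixed_costs(fx),
        fx.horizon_years,
        fx.periods_per_year,
        fx.n_program_participants,
    )
    day = daily_income(cost_params.annual_income, cost_params.working_days_per_year)

    rows = panel[panel["timepoint"] == "T0"].set_index("participant_id")
    out = pd.DataFrame(index=rows.index)
    out["arm"] = rows["arm"]
    out["endocrine_therapy"] = rows["endocrine_therapy"]
    out["fixed_share"] = np.where(rows["arm"] == "intervention", share, 0.0)
    out["direct"] = convert_currency(rows["direct_cost"], cost_params.exchange_rate)
    out["indirect"] = [
        indirect_cost(d, v, day) for d, v in zip(rows["inpatient_days"], rows["clinic_visits"])
    ]
    out["total"] = out["fixed_share"] + out["direct"] + out["indirect"]
    return out
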