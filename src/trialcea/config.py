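"""Trial and analysis configuration.

All tunable parameters of the synthetic two-arm trial and of the downstream
analysis live in :class:`TrialConfig`.  Defaults describe a 2x96-participant
randomized trial of an app-based supportive-care program for breast-cancer
survivors: six psychometric instruments measured at baseline, 3 months and
6 months, an SF-6D-style health utility, societal costs (amortized program
fixed costs, direct medical costs, productivity losses) and app-usage logs.

Configs round-trip through plain YAML files so a run is fully described by
one text file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

ARMS = ("intervention", "control")
TIMEPOINTS = ("T0", "T1", "T2")
TIMES_YEARS = (0.0, 0.25, 0.5)

#: Instrument score columns of the outcome panel, in reporting order.
INSTRUMENTS = ("BIS", "SIS", "PSQI", "MSPSS", "PCS", "MCS")

#: Closed score ranges of each instrument (totals, not items).
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "BIS": (0.0, 30.0),      # body image distress; higher = worse
    "SIS": (24.0, 96.0),     # perceived stigma; higher = worse
    "PSQI": (0.0, 21.0),     # sleep quality; higher = worse
    "MSPSS": (12.0, 84.0),   # social support; higher = better
    "PCS": (0.0, 100.0),     # SF-36 physical component
    "MCS": (0.0, 100.0),     # SF-36 mental component
}


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class OutcomeParams:
    """Marginal parameters of one outcome across the three timepoints.

    ``control_drift`` is the additive change of the control-arm mean at
    (T1, T2) relative to baseline; ``effect`` is the additional additive
    shift in the intervention arm at (T1, T2).  Scores are drawn on the
    latent normal scale and then truncated to ``score_range`` (and rounded
    when ``integer_scale``), so extreme parameter choices bias marginal
    means; defaults sit mid-range where truncation is negligible.
    """

    baseline_mean: float
    baseline_sd: float
    control_drift: tuple[float, float]
    effect: tuple[float, float]
    score_range: tuple[float, float]
    integer_scale: bool = False

    def validate(self, name: str) -> None:
        if not self.baseline_sd > 0:
            raise ConfigError(f"outcome_params[{name}].baseline_sd must be > 0")
        lo, hi = self.score_range
        if not lo < hi:
            raise ConfigError(f"outcome_params[{name}].score_range must be increasing")
        if len(self.control_drift) != 2 or len(self.effect) != 2:
            raise ConfigError(
                f"outcome_params[{name}]: control_drift and effect need one value per follow-up"
            )


@dataclass
class FixedCostInputs:
    """One-time and recurring program costs to be amortized (2023 US$)."""

    one_time_costs: float = 15_761.19          # app development + maintenance + video production
    annual_recurring: float = 4_298.51         # therapist consultation fees per year
    horizon_years: int = 5
    discount_rate: float = 0.03
    periods_per_year: int = 2                  # 6-month analytic periods
    n_program_participants: int = 96

    def validate(self) -> None:
        if self.one_time_costs < 0 or self.annual_recurring < 0:
            raise ConfigError("fixed costs must be non-negative")
        if self.horizon_years < 1:
            raise ConfigError("fixed.horizon_years must be >= 1")
        if self.discount_rate < 0:
            raise ConfigError("fixed.discount_rate must be >= 0")
        if self.periods_per_year < 1 or self.n_program_participants < 1:
            raise ConfigError("fixed cost divisors must be positive")


@dataclass
class CostParams:
    """Societal cost generator/valuation parameters (2023 US$).

    Direct medical costs are cumulative six-month amounts per participant,
    drawn lognormal (non-negative, right-skewed).  Indirect costs follow the
    human-capital approach: lost days valued at the average daily income,
    with a clinic visit counting half a day.
    """

    direct_mean: dict[str, float] = field(
        default_factory=lambda: {"intervention": 9_113.58, "control": 9_002.69}
    )
    direct_sd: dict[str, float] = field(
        # arm SE ~1,034/1,022 at n=96 implies these cohort SDs
        default_factory=lambda: {"intervention": 10_134.0, "control": 10_017.0}
    )
    inpatient_days_mean: dict[str, float] = field(
        default_factory=lambda: {"intervention": 2.54, "control": 2.37}
    )
    clinic_visits_mean: dict[str, float] = field(
        default_factory=lambda: {"intervention": 2.0, "control": 2.0}
    )
    annual_income: float = 10_606.27
    working_days_per_year: float = 260.0
    exchange_rate: float = 1.0                 # CNY per USD; 1.0 = amounts already in USD
    fixed: FixedCostInputs = field(default_factory=FixedCostInputs)

    def validate(self) -> None:
        for d, label in ((self.direct_mean, "direct_mean"), (self.direct_sd, "direct_sd")):
            for arm in ARMS:
                if d.get(arm, -1) <= 0:
                    raise ConfigError(f"cost_params.{label}[{arm}] must be > 0")
        for d, label in (
            (self.inpatient_days_mean, "inpatient_days_mean"),
            (self.clinic_visits_mean, "clinic_visits_mean"),
        ):
            for arm in ARMS:
                if d.get(arm, -1) < 0:
                    raise ConfigError(f"cost_params.{label}[{arm}] must be >= 0")
        if self.annual_income <= 0 or self.working_days_per_year <= 0:
            raise ConfigError("cost_params income parameters must be > 0")
        if self.exchange_rate <= 0:
            raise ConfigError("cost_params.exchange_rate must be > 0")
        self.fixed.validate()


@dataclass
class UsageParams:
    """App-usage generator parameters (intervention arm, 3-month window).

    Total usage duration (minutes) and login count are drawn from a
    correlated bivariate lognormal calibrated by median and interquartile
    range; per-module splits are Dirichlet shares proportional to the
    module medians.
    """

    duration_median: float = 199.60
    duration_iqr: tuple[float, float] = (70.90, 451.31)
    logins_median: float = 39.50
    logins_iqr: tuple[float, float] = (19.0, 86.5)
    log_correlation: float = 0.8
    module_duration_medians: dict[str, float] = field(
        default_factory=lambda: {"library": 25.54, "yoga": 3.89, "practice": 124.06}
    )
    module_login_medians: dict[str, float] = field(
        default_factory=lambda: {"library": 11.0, "yoga": 2.0, "practice": 22.0}
    )
    dirichlet_concentration: float = 2.0
    expected_use_min_logins: int = 10
    expected_use_min_minutes: float = 50.0

    def validate(self) -> None:
        for med, iqr, label in (
            (self.duration_median, self.duration_iqr, "duration"),
            (self.logins_median, self.logins_iqr, "logins"),
        ):
            if med <= 0 or not 0 < iqr[0] < med < iqr[1]:
                raise ConfigError(f"usage_params.{label} median/IQR must satisfy 0 < q1 < median < q3")
        if not -1 < self.log_correlation < 1:
            raise ConfigError("usage_params.log_correlation must be in (-1, 1)")


def _default_outcomes() -> dict[str, OutcomeParams]:
    # Baseline mean/SD, control drift at (T1, T2), and additive intervention
    # effect at (T1, T2) for each instrument, on the reported cohort scale.
    defaults = {
        "BIS": (6.71, 6.09, (0.61, 1.52), (-0.99, -1.91), True),
        "SIS": (52.58, 9.50, (3.75, 3.34), (-5.83, -7.79), True),
        "PSQI": (7.54, 3.88, (-0.25, -0.51), (-0.20, 0.07), True),
        "MSPSS": (66.04, 9.34, (-0.28, -4.13), (-1.44, 2.71), True),
        "PCS": (36.01, 10.38, (2.10, 3.71), (1.58, 2.02), False),
        "MCS": (40.76, 10.37, (1.03, 1.46), (4.44, 2.14), False),
    }
    return {
        name: OutcomeParams(m, s, drift, eff, SCORE_RANGES[name], integer_scale=integer)
        for name, (m, s, drift, eff, integer) in defaults.items()
    }


def _default_utility() -> OutcomeParams:
    # Baseline SF-6D-style utility 0.663 with cohort SD 0.1372 (SE 0.014 at
    # n=96); control drift and intervention shifts per follow-up.
    return OutcomeParams(
        baseline_mean=0.663,
        baseline_sd=0.1372,
        control_drift=(0.004, 0.011),
        effect=(0.018, 0.007),
        score_range=(0.0, 1.0),
        integer_scale=False,
    )


@dataclass
class TrialConfig:
    """Full description of one synthetic trial and its analysis."""

    n_per_arm: int = 96
    timepoints: tuple[str, ...] = TIMEPOINTS
    times_years: tuple[float, ...] = TIMES_YEARS
    outcome_params: dict[str, OutcomeParams] = field(default_factory=_default_outcomes)
    utility_params: OutcomeParams = field(default_factory=_default_utility)
    within_subject_rho: float = 0.5
    pcs_mcs_rho: float = 0.3
    endocrine_prevalence: dict[str, float] = field(
        default_factory=lambda: {"intervention": 0.521, "control": 0.667}
    )
    dropout_rate: float = 0.193
    missing_mechanism: str = "MAR"
    mar_baseline_coef: float = 0.5   # logit slope per baseline-SIS SD
    mar_arm_coef: float = 0.2        # extra logit for the intervention arm
    cost_params: CostParams = field(default_factory=CostParams)
    usage_params: UsageParams = field(default_factory=UsageParams)
    m_imputations: int = 20
    imputation_method: str = "chained"
    bootstrap_replicates: int = 10_000
    wtp_threshold: float = 37_530.0  # 3 x 2023 GDP per capita (12,510 US$)
    wtp_grid_max: float = 200_000.0
    wtp_grid_step: float = 500.0
    bonferroni_k: int = 2            # the two follow-up contrasts per outcome
    seed: int = 20_240_424

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be >= 2")
        if len(self.timepoints) != len(self.times_years):
            raise ConfigError("timepoints and times_years must have equal length")
        t = np.asarray(self.times_years, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ConfigError("times_years must increase strictly from 0")
        if not 0 <= self.within_subject_rho < 1:
            raise ConfigError("within_subject_rho must be in [0, 1)")
        if not -1 < self.pcs_mcs_rho < 1:
            raise ConfigError("pcs_mcs_rho must be in (-1, 1)")
        for arm in ARMS:
            p = self.endocrine_prevalence.get(arm)
            if p is None or not 0 <= p <= 1:
                raise ConfigError(f"endocrine_prevalence[{arm}] must be in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.missing_mechanism not in ("MAR", "MCAR"):
            raise ConfigError("missing_mechanism must be 'MAR' or 'MCAR'")
        for name, op in self.outcome_params.items():
            op.validate(name)
        self.utility_params.validate("utility")
        if self.utility_params.score_range != (0.0, 1.0):
            raise ConfigError("utility_params.score_range must be (0, 1)")
        self.cost_params.validate()
        self.usage_params.validate()
        if self.m_imputations < 1:
            raise ConfigError("m_imputations must be >= 1")
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")
        if self.wtp_threshold < 0 or self.wtp_grid_max <= 0 or self.wtp_grid_step <= 0:
            raise ConfigError("willingness-to-pay parameters must be positive")
        if self.bonferroni_k < 1:
            raise ConfigError("bonferroni_k must be >= 1")

    # ------------------------------------------------------------------
    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic child seed for a pipeline stage.

        A single global seed expands into independent per-stage streams so
        each stage is reproducible on its own.
        """
        stages = ("generate", "missingness", "impute", "impute_mcmc", "bootstrap")
        if stage not in stages:
            raise ConfigError(f"unknown stage '{stage}'")
        return np.random.SeedSequence(self.seed).spawn(len(stages))[stages.index(stage)]

    @property
    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_grid_max + self.wtp_grid_step / 2, self.wtp_grid_step)

    @property
    def follow_up_timepoints(self) -> tuple[str, ...]:
        return tuple(self.timepoints[1:])

    # -------------------------- serialisation -------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["times_years"] = list(self.times_years)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialConfig":
        d = dict(d)
        if "outcome_params" in d:
            d["outcome_params"] = {
                k: v if isinstance(v, OutcomeParams) else OutcomeParams(**_tuplify(v))
                for k, v in d["outcome_params"].items()
            }
        if "utility_params" in d and not isinstance(d["utility_params"], OutcomeParams):
            d["utility_params"] = OutcomeParams(**_tuplify(d["utility_params"]))
        if "cost_params" in d and not isinstance(d["cost_params"], CostParams):
            cp = dict(d["cost_params"])
            if "fixed" in cp and not isinstance(cp["fixed"], FixedCostInputs):
                cp["fixed"] = FixedCostInputs(**cp["fixed"])
            d["cost_params"] = CostParams(**cp)
        if "usage_params" in d and not isinstance(d["usage_params"], UsageParams):
            d["usage_params"] = UsageParams(**_tuplify(d["usage_params"]))
        for key in ("timepoints", "times_years"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tuplify(d: Mapping) -> dict:
    out = dict(d)
    for k, v in out.items():
        if isinstance(v, list):
            out[k] = tuple(v)
    return out


def default_config(seed: int | None = None, **overrides) -> TrialConfig:
    """The study-default configuration, optionally reseeded/overridden."""
    cfg = TrialConfig(**overrides)
    if seed is not None:
        cfg.seed = int(seed)
    cfg.validate()
    return cfg
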