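import numpy as np
import pandas as pd
import pytest

from trialcea import default_config, generate_trial, apply_missingness


@pytest.fixture(scope="session")
def small_config():
    """A reduced trial for fast structural tests."""
    cfg = default_config(seed=424242)
    cfg.n_per_arm = 40
    cfg.m_imputations = 3
    cfg.bootstrap_replicates = 400
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def complete_panel(small_config):
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def observed_panel(small_config, complete_panel):
    return apply_missingness(
        complete_panel,
        small_config.dropout_rate,
        "MAR",
        seed=small_config.stage_seed("missingness"),
    )


@pytest.fixture(scope="session")
def study_scale_config():
    """Study-scale configuration (96 per arm, default effects)."""
    return default_config(seed=20240)


def arm_time_mean(panel: pd.DataFrame, var: str, arm: str, timepoint: str) -> float:
    sub = panel[(panel["arm"] == arm) & (panel["timepoint"] == timepoint)]
    return float(sub[var].mean())


def raw_arm_difference(panel: pd.DataFrame, var: str, timepoint: str) -> float:
    return arm_time_mean(panel, var, "intervention", timepoint) - arm_time_mean(
        panel, var, "control", timepoint
    )
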