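"""Synthetic-cohort generator: structure, determinism, marginal recovery,
and the monotone-dropout missingness mechanism."""

import numpy as np
import pandas as pd
import pytest

from trialcea import (
    ConfigError,
    INSTRUMENTS,
    SCORE_RANGES,
    default_config,
    generate_trial,
    apply_missingness,
)
from trialcea.panel import ANALYSIS_COLUMNS

from conftest import raw_arm_difference


def test_panel_shape_and_schema(study_scale_config):
    panel = generate_trial(study_scale_config)
    assert len(panel) == 2 * 96 * 3
    assert panel["participant_id"].nunique() == 192
    counts = panel.groupby("participant_id")["timepoint"].nunique()
    assert (counts == 3).all()


def test_determinism_byte_identical(small_config):
    a = generate_trial(small_config).to_csv(index=False)
    b = generate_trial(small_config).to_csv(index=False)
    assert a == b


def test_different_seed_differs(small_config):
    cfg2 = default_config(seed=small_config.seed + 1)
    cfg2.n_per_arm = small_config.n_per_arm
    assert not generate_trial(small_config)[INSTRUMENTS[0]].equals(
        generate_trial(cfg2)[INSTRUMENTS[0]]
    )


def test_scores_respect_instrument_ranges(complete_panel):
    for name in INSTRUMENTS:
        lo, hi = SCORE_RANGES[name]
        assert complete_panel[name].between(lo, hi).all()
    assert complete_panel["utility"].between(0, 1).all()
    # integer totals on the questionnaire scales
    for name in ("BIS", "SIS", "PSQI", "MSPSS"):
        assert (complete_panel[name] % 1 == 0).all()


def test_null_effect_arm_differences_centred_at_zero():
    """With zero effects the arm difference is a mean-zero contrast of
    independent samples; its Monte-Carlo average over seeds must sit
    within 3 standard errors of zero."""
    n_seeds, n_per_arm = 200, 96
    diffs = []
    for s in range(n_seeds):
        cfg = default_config(seed=50_000 + s)
        cfg.n_per_arm = n_per_arm
        cfg.within_subject_rho = 0.0
        for p in cfg.outcome_params.values():
            p.effect = (0.0, 0.0)
        diffs.append(raw_arm_difference(generate_trial(cfg), "SIS", "T1"))
    diffs = np.asarray(diffs)
    theo_sd = 9.50 * np.sqrt(2.0 / n_per_arm)
    assert abs(diffs.mean()) < 3 * theo_sd / np.sqrt(n_seeds)


def test_configured_effect_recovered_at_large_n():
    """Law of large numbers: the raw T1 stigma difference converges to the
    configured additive effect."""
    cfg = default_config(seed=77)
    cfg.n_per_arm = 2000
    panel = generate_trial(cfg)
    se = 9.50 * np.sqrt(2.0 / 2000)
    assert abs(raw_arm_difference(panel, "SIS", "T1") - (-5.83)) < 3 * se


def test_within_subject_correlation_recovered():
    cfg = default_config(seed=11)
    cfg.n_per_arm = 2500  # 5000 participants
    panel = generate_trial(cfg)
    wide = panel.pivot(index="participant_id", columns="timepoint", values="MCS")
    r = np.corrcoef(wide["T0"], wide["T1"])[0, 1]
    mc_err = (1 - cfg.within_subject_rho**2) / np.sqrt(len(wide))
    # rounding/truncation attenuates slightly; allow 5 MC errors
    assert abs(r - cfg.within_subject_rho) < 5 * mc_err


def test_marginal_mean_recovery_with_no_dropout():
    cfg = default_config(seed=13)
    cfg.n_per_arm = 2000
    panel = generate_trial(cfg)
    ctl_t2 = panel[(panel["arm"] == "control") & (panel["timepoint"] == "T2")]["SIS"]
    target = 52.58 + 3.34  # baseline + control drift
    assert abs(ctl_t2.mean() - target) < 3 * 9.50 / np.sqrt(2000)
    assert abs(ctl_t2.std(ddof=1) - 9.50) < 0.5


def test_config_yaml_round_trip(tmp_path, small_config):
    path = tmp_path / "config.yaml"
    small_config.to_yaml(path)
    from trialcea import TrialConfig

    loaded = TrialConfig.from_yaml(path)
    assert loaded == small_config
    pd.testing.assert_frame_equal(generate_trial(loaded), generate_trial(small_config))


def test_config_validation_names_field():
    cfg = default_config()
    cfg.dropout_rate = 1.5
    with pytest.raises(ConfigError, match="dropout_rate"):
        cfg.validate()
    cfg = default_config()
    cfg.outcome_params["SIS"].baseline_sd = -1
    with pytest.raises(ConfigError, match="SIS"):
        cfg.validate()


# ---------------------------------------------------------------- dropout

def test_zero_rate_leaves_panel_unchanged(complete_panel):
    out = apply_missingness(complete_panel, 0.0, "MCAR", seed=1)
    pd.testing.assert_frame_equal(out, complete_panel)


def test_rate_outside_unit_interval_rejected(complete_panel):
    with pytest.raises(ConfigError):
        apply_missingness(complete_panel, 1.0, "MCAR", seed=1)
    with pytest.raises(ConfigError):
        apply_missingness(complete_panel, -0.1, "MCAR", seed=1)


def test_baseline_never_masked_and_dropout_monotone(observed_panel):
    t0 = observed_panel[observed_panel["timepoint"] == "T0"]
    assert not t0[list(ANALYSIS_COLUMNS)].isna().any().any()
    wide = observed_panel.pivot(index="participant_id", columns="timepoint", values="SIS")
    assert not (wide["T1"].isna() & wide["T2"].notna()).any()


@pytest.mark.parametrize("mechanism", ["MCAR", "MAR"])
def test_overall_dropout_rate_calibrated(study_scale_config, mechanism):
    """Mean fraction of participants with any missing follow-up matches the
    requested rate (the study lost 37/192, a 19.3% attrition)."""
    panel = generate_trial(study_scale_config)
    fracs = []
    for s in range(60):
        obs = apply_missingness(panel, 0.193, mechanism, seed=1000 + s)
        wide = obs.pivot(index="participant_id", columns="timepoint", values="SIS")
        fracs.append((wide[["T1", "T2"]].isna().any(axis=1)).mean())
    mc_se = np.sqrt(0.193 * 0.807 / 192 / 60)
    assert abs(np.mean(fracs) - 0.193) < 4 * mc_se


def test_mar_dropouts_have_higher_baseline_stigma(study_scale_config):
    """The MAR mechanism loads positively on baseline stigma, so dropouts
    must average higher baseline SIS than completers."""
    panel = generate_trial(study_scale_config)
    gaps = []
    for s in range(40):
        obs = apply_missingness(panel, 0.25, "MAR", seed=2000 + s)
        wide = obs.pivot(index="participant_id", columns="timepoint", values="SIS")
        dropped = wide[["T1", "T2"]].isna().any(axis=1)
        gaps.append(wide.loc[dropped, "T0"].mean() - wide.loc[~dropped, "T0"].mean())
    assert np.mean(gaps) > 0


def test_costs_and_usage_survive_missingness(observed_panel):
    assert observed_panel["direct_cost"].notna().all()
    usage = observed_panel.loc[observed_panel["arm"] == "intervention", "usage_minutes_total"]
    assert usage.notna().all()
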