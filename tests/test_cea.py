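"""Incremental analysis: ICER labelling, net monetary benefit, stratified
bootstrap, BCa intervals, CE-plane quadrants and the acceptability curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trialcea import (
    icer,
    nmb,
    bootstrap_cea,
    bca_interval,
    ce_plane,
    ceac,
    run_cea,
)
from trialcea.cea import CEADraws


def _cohort(rng, n=60, cost_mu=(9000.0, 9000.0), qaly_mu=(0.34, 0.33),
            cost_sd=800.0, qaly_sd=0.02):
    arms = ["intervention"] * n + ["control"] * n
    mu_c = np.repeat(cost_mu, n)
    mu_q = np.repeat(qaly_mu, n)
    return pd.DataFrame(
        {
            "arm": arms,
            "endocrine_therapy": rng.integers(0, 2, 2 * n),
            "baseline_utility": np.clip(rng.normal(0.66, 0.1, 2 * n), 0, 1),
            "total_cost": rng.normal(mu_c, cost_sd),
            "qaly": rng.normal(mu_q, qaly_sd),
        }
    )


def _draws(dc, de):
    dc = np.asarray(dc, float)
    de = np.asarray(de, float)
    return CEADraws(dc, de, float(dc.mean()), float(de.mean()), dc[:5], de[:5])


# ----------------------------------------------------------------- icer

def test_icer_worked_ratio():
    label = icer(155.45, 0.008)
    assert label.kind == "ratio"
    assert label.value == pytest.approx(19_431.25)


def test_icer_dominance_and_guard():
    assert icer(-10.0, 0.01).kind == "intervention-dominant"
    assert icer(100.0, -0.01).kind == "control-dominant"
    assert icer(100.0, 0.0).kind == "indeterminate"
    assert icer(-100.0, -0.01).kind == "ratio"  # cheaper and less effective
    with pytest.raises(ValueError):
        icer(np.nan, 0.01)


# ------------------------------------------------------------------ nmb

def test_nmb_hand_values():
    assert nmb(155.45, 0.008, 37_530) == pytest.approx(144.79)
    assert nmb(155.45, 0.008, 0.0) == pytest.approx(-155.45)
    # break-even at lambda = dC/dE
    assert nmb(200.0, 0.004, 200.0 / 0.004) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        nmb(1.0, 0.01, -5.0)


def test_nmb_zero_at_point_icer():
    label = icer(155.45, 0.008)
    assert nmb(155.45, 0.008, label.value) == pytest.approx(0.0, abs=1e-9)


# ------------------------------------------------------------ bootstrap

def test_bootstrap_deterministic_and_constant_degenerate():
    df = _cohort(np.random.default_rng(0), n=10)
    df["total_cost"] = np.where(df["arm"] == "intervention", 100.0, 90.0)
    df["qaly"] = np.where(df["arm"] == "intervention", 0.4, 0.39)
    d1 = bootstrap_cea(df, B=200, seed=5, adjusted=False)
    d2 = bootstrap_cea(df, B=200, seed=5, adjusted=False)
    np.testing.assert_array_equal(d1.delta_cost, d2.delta_cost)
    # constant arm data: every draw equals the point estimate
    assert np.allclose(d1.delta_cost, 10.0)
    assert np.allclose(d1.delta_qaly, 0.01)


def test_bootstrap_requires_two_per_arm():
    df = _cohort(np.random.default_rng(1), n=5)
    with pytest.raises(ValueError):
        bootstrap_cea(df[df["arm"] == "control"], B=10)


def test_bootstrap_adjusted_point_matches_regression():
    rng = np.random.default_rng(3)
    df = _cohort(rng, n=80)
    d = bootstrap_cea(df, B=150, seed=1, adjusted=True)
    g = (df["arm"] == "intervention").to_numpy(float)
    X = np.column_stack([np.ones(len(df)), g, df["endocrine_therapy"],
                         df["baseline_utility"]])
    beta = np.linalg.lstsq(X, df["qaly"].to_numpy(), rcond=None)[0]
    assert d.point_delta_qaly == pytest.approx(beta[1], abs=1e-10)


def test_monte_carlo_error_shrinks_with_B():
    """Draw-mean variability across seeds scales ~1/sqrt(B); the point
    estimate does not depend on B."""
    df = _cohort(np.random.default_rng(7), n=50)
    means_small, means_big = [], []
    points = set()
    for s in range(40):
        small = bootstrap_cea(df, B=100, seed=100 + s, adjusted=False)
        big = bootstrap_cea(df, B=1600, seed=500 + s, adjusted=False)
        means_small.append(small.delta_cost.mean())
        means_big.append(big.delta_cost.mean())
        points.add((small.point_delta_cost, big.point_delta_cost))
    assert len(points) == 1
    ratio = np.std(means_small) / np.std(means_big)
    assert 2.0 < ratio < 8.0  # expect ~4 = sqrt(1600/100)


# ------------------------------------------------------------------ bca

def test_bca_symmetric_draws_close_to_percentile():
    rng = np.random.default_rng(11)
    draws = rng.normal(0.0, 1.0, 20_000)
    jack = rng.normal(0.0, 1.0 / np.sqrt(50), 50)  # symmetric -> a ~ 0
    lo, hi = bca_interval(draws, 0.0, jack)
    plo, phi = np.quantile(draws, [0.025, 0.975])
    assert lo == pytest.approx(plo, abs=0.06)
    assert hi == pytest.approx(phi, abs=0.06)


def test_bca_degenerate_draws_collapse():
    draws = np.full(500, 3.2)
    assert bca_interval(draws, 3.2, np.full(20, 3.2)) == (3.2, 3.2)


def test_bca_requires_enough_replicates():
    with pytest.raises(ValueError):
        bca_interval(np.arange(50.0), 25.0, np.arange(10.0))


def test_bca_matches_textbook_oracle_on_same_draws():
    """Independent oracle: the textbook BCa construction (bias correction
    from the sub-point fraction, acceleration from jackknife skewness,
    percentile lookup at the adjusted levels) computed from scratch on
    the same replicates."""
    rng = np.random.default_rng(23)
    x = rng.exponential(1.0, size=10)           # skewed small instance
    point = x.mean()
    B = 2_000
    draws = rng.choice(x, size=(B, x.size), replace=True).mean(axis=1)
    jack = np.array([np.delete(x, i).mean() for i in range(x.size)])

    # oracle, written from the textbook definition
    z0 = stats.norm.ppf((np.sum(draws < point) + 0.5 * np.sum(draws == point)) / B)
    d = jack.mean() - jack
    a = np.sum(d**3) / (6.0 * np.sum(d**2) ** 1.5)
    z = stats.norm.ppf([0.025, 0.975])
    levels = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    expected = np.quantile(draws, levels)

    got = bca_interval(draws, point, jack)
    resolution = np.diff(np.sort(draws)).max()
    assert got[0] == pytest.approx(expected[0], abs=resolution)
    assert got[1] == pytest.approx(expected[1], abs=resolution)


# ------------------------------------------------------------- ce plane

def test_ce_plane_single_and_symmetric():
    assert ce_plane(_draws([1.0], [1.0])) == {"NE": 1.0, "SE": 0.0, "SW": 0.0, "NW": 0.0}
    props = ce_plane(_draws([1.0, 1.0, -1.0, -1.0], [1.0, -1.0, -1.0, 1.0]))
    assert props == {"NE": 0.25, "SE": 0.25, "SW": 0.25, "NW": 0.25}


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_ce_plane_partitions_any_cloud(seed):
    rng = np.random.default_rng(seed)
    props = ce_plane(_draws(rng.normal(size=200), rng.normal(size=200)))
    assert sum(props.values()) == pytest.approx(1.0)
    assert all(0.0 <= v <= 1.0 for v in props.values())


# ----------------------------------------------------------------- ceac

def test_ceac_enumerated_three_draws():
    d = _draws([100.0, -50.0, 300.0], [0.01, 0.002, -0.001])
    curve = ceac(d, [37_530.0])
    assert curve["probability"].iloc[0] == pytest.approx(2.0 / 3.0)


def test_ceac_analytic_limits():
    rng = np.random.default_rng(5)
    d = _draws(rng.normal(50, 100, 2_000), rng.normal(0.004, 0.01, 2_000))
    curve = ceac(d, [0.0, 1e12])
    assert curve["probability"].iloc[0] == pytest.approx(np.mean(d.delta_cost < 0))
    assert curve["probability"].iloc[-1] == pytest.approx(np.mean(d.delta_qaly > 0))
    assert curve["probability"].between(0, 1).all()


def test_ceac_rejects_bad_grid():
    d = _draws([1.0, 2.0], [0.1, 0.2])
    with pytest.raises(ValueError):
        ceac(d, [])
    with pytest.raises(ValueError):
        ceac(d, [-5.0])


# --------------------------------------------------------------- run_cea

def test_run_cea_consistency():
    rng = np.random.default_rng(17)
    df = _cohort(rng, n=60, cost_mu=(9100.0, 9000.0), qaly_mu=(0.345, 0.335))
    draws = bootstrap_cea(df, B=800, seed=9)
    res = run_cea(draws, threshold_lambda=37_530.0, lambda_grid=np.arange(0, 100_001, 1000.0))
    assert res.nmb_at_threshold == pytest.approx(
        37_530.0 * res.delta_qaly - res.delta_cost
    )
    assert sum(res.quadrant_proportions.values()) == pytest.approx(1.0)
    # point label consistent with the point's quadrant
    if res.icer_label.kind == "ratio" and res.delta_qaly > 0:
        assert res.delta_cost / res.delta_qaly == pytest.approx(res.icer_label.value)
    assert 0.0 <= res.prob_ce_at_threshold <= 1.0
    lo, hi = res.bca_ci_delta_qaly
    assert lo <= res.delta_qaly <= hi
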