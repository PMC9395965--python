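"""Two-stage switching adjustment: AFT recovery, counterfactuals, Cox HRs."""
import numpy as np
import pandas as pd
import pytest

from psmcea.crossover import (
    EstimationError, cox_hr, counterfactual_times, estimate_accel_factor,
    two_stage_adjust,
)
from psmcea.ipd import default_scenario, simulate_trial


def _toy_control(post_times, switched, pfs=3.0):
    n = len(post_times)
    return pd.DataFrame({
        "arm": "control",
        "pfs_time": pfs,
        "pfs_event": 1,
        "os_time": pfs + np.asarray(post_times, dtype=float),
        "os_event": 1,
        "switched": np.asarray(switched, dtype=int),
        "switch_time": np.where(np.asarray(switched) == 1, pfs, np.nan),
    })


def test_null_acceleration_ci_covers_one():
    sc = default_scenario(n_per_arm=1500, seed=13, crossover_prob=0.5,
                          crossover_accel=1.0)
    ipd = simulate_trial(sc)
    acc = estimate_accel_factor(ipd[ipd["arm"] == "control"])
    assert acc.ci_low < 1.0 < acc.ci_high


def test_acceleration_factor_recovery():
    sc = default_scenario(n_per_arm=2000, seed=17, crossover_prob=0.5,
                          crossover_accel=1.5)
    ipd = simulate_trial(sc)
    acc = estimate_accel_factor(ipd[ipd["arm"] == "control"])
    assert acc.factor == pytest.approx(1.5, rel=0.10)


def test_exact_factor_on_doubled_toy_data():
    # switchers' post-progression times are exactly double the non-switchers'
    base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0])
    df = _toy_control(np.concatenate([base, 2 * base]),
                      np.concatenate([np.zeros(8), np.ones(8)]))
    acc = estimate_accel_factor(df, covariates=())
    assert acc.factor == pytest.approx(2.0, rel=1e-3)


def test_no_common_support_raises():
    df = _toy_control([1, 2, 3], [1, 1, 1])
    with pytest.raises(EstimationError):
        estimate_accel_factor(df)


def test_counterfactual_arithmetic_and_identity():
    df = _toy_control([9.0], [1], pfs=6.0)  # switch at 6, OS 15? no: pfs=6, os=15
    df.loc[0, "os_time"] = 12.0
    adj = counterfactual_times(df, 2.0, recensor=False)
    assert adj.loc[0, "os_time"] == pytest.approx(9.0)  # 6 + (12-6)/2
    same = counterfactual_times(df, 1.0, recensor=False)
    pd.testing.assert_frame_equal(same, df)


def test_counterfactual_monotone_and_nonswitchers_fixed():
    df = _toy_control([2.0, 4.0, 8.0], [0, 1, 1])
    a = counterfactual_times(df, 1.5, recensor=False)
    b = counterfactual_times(df, 3.0, recensor=False)
    assert a.loc[0, "os_time"] == df.loc[0, "os_time"]
    assert (b.loc[[1, 2], "os_time"] <= a.loc[[1, 2], "os_time"]).all()


def test_counterfactual_recensoring_flags_events():
    df = _toy_control([30.0, 2.0], [1, 0])
    adj = counterfactual_times(df, 2.0, recensor=True, censor_time=24.0)
    c_star = 12.0  # 24 / 2
    assert (adj["os_time"] <= c_star + 1e-12).all()
    assert adj.loc[0, "os_event"] == 0
    with pytest.raises(ValueError):
        counterfactual_times(df, 2.0, recensor=True)  # censor_time required


def test_counterfactual_validates_switch_times():
    df = _toy_control([5.0], [1])
    df.loc[0, "switch_time"] = 99.0
    with pytest.raises(ValueError):
        counterfactual_times(df, 2.0, recensor=False)


def test_cox_hr_symmetry_weights_and_exponential_truth(rng):
    n = 5000
    a = pd.DataFrame({"os_time": rng.exponential(5.0, n), "os_event": 1})
    b = pd.DataFrame({"os_time": a["os_time"], "os_event": 1})
    hr, _ = cox_hr(a, b)
    assert hr == pytest.approx(1.0, abs=1e-6)

    # exponential proportional hazards: rates 0.2 vs 0.4 give HR 0.5
    act = pd.DataFrame({"os_time": rng.exponential(1 / 0.2, n), "os_event": 1})
    ctl = pd.DataFrame({"os_time": rng.exponential(1 / 0.4, n), "os_event": 1})
    hr, se = cox_hr(act, ctl)
    assert hr == pytest.approx(0.5, rel=0.05)
    assert se > 0

    w = np.ones(2 * n)
    hr_w, _ = cox_hr(act, ctl, weights=w)
    hr_2w, _ = cox_hr(act, ctl, weights=2 * w)
    assert hr_2w == pytest.approx(hr_w, rel=1e-9)  # scale invariance
    assert hr_w == pytest.approx(hr, rel=1e-6)     # uniform weights = unweighted


def test_cox_hr_requires_events():
    df = pd.DataFrame({"os_time": [1.0, 2.0], "os_event": [0, 0]})
    with pytest.raises(EstimationError):
        cox_hr(df, df)


def test_itt_hazard_ratio_diluted_toward_one():
    """Crossover with acceleration > 1 biases the ITT OS HR toward 1."""
    kw = dict(n_per_arm=3000, seed=23, crossover_accel=1.6)
    with_x = simulate_trial(default_scenario(crossover_prob=0.8, **kw))
    without = simulate_trial(default_scenario(crossover_prob=0.0, **kw))
    hr_itt, _ = cox_hr(with_x[with_x.arm == "active"], with_x[with_x.arm == "control"])
    hr_true, _ = cox_hr(without[without.arm == "active"], without[without.arm == "control"])
    assert hr_true < hr_itt < 1.0


def test_two_stage_moves_hr_away_from_one():
    sc = default_scenario(n_per_arm=2000, seed=29, crossover_prob=0.6,
                          crossover_accel=1.5)
    ipd = simulate_trial(sc)
    res = two_stage_adjust(ipd, censor_time=sc.censor_time)
    assert res.hr_adjusted < res.hr_unadjusted < 1.0
    assert res.recensored and res.n_switchers > 0
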