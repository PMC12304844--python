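"""Acceleration factors, time rescaling, Poisson fits, KS test, rates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import mlmetad as m
from mlmetad.trajectory import Trajectory


def _bias_traj(bias, cv=None):
    n = len(bias)
    cv = np.zeros(n) if cv is None else np.asarray(cv, float)
    return Trajectory(times=np.arange(n) * 1.0, cv_matrix=cv[:, None],
                      cv_names=["d"], bias_energy=np.asarray(bias, float))


BOUND_ALL = m.BoundStateDef(cv_name="d", cutoff=1.0, commit_frames=1)


def test_alpha_is_one_without_bias(thermo):
    tr = _bias_traj(np.zeros(5))
    a = m.acceleration_series(tr, thermo, BOUND_ALL)
    assert np.allclose(a, 1.0)


def test_alpha_arithmetic_three_frames(thermo):
    # beta V = {0, ln 2, ln 4} -> running mean of e^{beta V} ends at 7/3
    tr = _bias_traj([0.0, math.log(2.0), math.log(4.0)])
    a = m.acceleration_series(tr, thermo, BOUND_ALL)
    assert a[-1] == pytest.approx(7.0 / 3.0)


def test_alpha_constant_bias(thermo):
    tr = _bias_traj(np.full(10, math.log(10.0)))
    a = m.acceleration_series(tr, thermo, BOUND_ALL)
    assert np.allclose(a, 10.0)


def test_alpha_undefined_before_first_bound_frame(thermo):
    cv = np.array([5.0, 5.0, 0.0, 0.0])  # first two frames unbound
    tr = _bias_traj(np.zeros(4), cv=cv)
    a = m.acceleration_series(tr, thermo, BOUND_ALL)
    assert np.isnan(a[0]) and np.isnan(a[1]) and a[2] == 1.0


def test_rescaled_time_values():
    assert m.rescaled_time(5.0, 1.0) == 5.0  # unbiased limit
    assert m.rescaled_time(2.0, 7.0 / 3.0) == pytest.approx(14.0 / 3.0)
    with pytest.raises(ValueError, match="no event"):
        m.rescaled_time(2.0, 1.5, event=False)


def test_more_bias_gives_longer_rescaled_time(thermo):
    """Recomputing t_rel on the same trajectory with doubled bias energies
    strictly increases the rescaled time (monotonicity in deposited bias)."""
    rng = np.random.default_rng(0)
    v = rng.uniform(0.0, 0.5, size=50)
    t1 = m.transition_record(_bias_traj(v), thermo, BOUND_ALL, True, 40.0)
    t2 = m.transition_record(_bias_traj(2 * v), thermo, BOUND_ALL, True, 40.0)
    assert t2.t_rel > t1.t_rel


def test_cumulative_rescaling_option(thermo):
    tr = _bias_traj(np.zeros(11))
    # zero bias: integral of dt over the trajectory = total time
    assert m.rescaled_time_cumulative(tr, thermo) == pytest.approx(11.0)


def test_transition_record_alpha_floor():
    with pytest.raises(ValueError, match=">= 1"):
        m.TransitionRecord(seed=0, t_sim=1.0, alpha=0.5, t_rel=0.5)


def test_exponential_fit_mean_and_error_rule():
    fit = m.fit_exponential([1.0, 2.0, 3.0])
    assert fit.tau == pytest.approx(2.0)
    fit_c = m.fit_exponential([4.0, 4.0, 4.0])
    assert fit_c.tau == pytest.approx(4.0)
    # the stated error rule: sigma_tau = sqrt(tau) (tau = 9 -> 3), with the
    # conventional MLE error tau / sqrt(n) reported alongside
    fit9 = m.fit_exponential([9.0, 9.0, 9.0, 9.0])
    assert fit9.sigma_tau == pytest.approx(3.0)
    assert fit9.sigma_tau_mle == pytest.approx(9.0 / 2.0)


def test_exponential_fit_errors():
    with pytest.raises(ValueError, match="at least 3"):
        m.fit_exponential([1.0, 2.0])
    with pytest.raises(ValueError, match="positive"):
        m.fit_exponential([1.0, -2.0, 3.0])


def test_ks_statistic_at_fitted_quantiles():
    # samples at F^{-1}((i - 0.5)/n) -> D = 0.5/n exactly
    tau, n = 2.0, 16
    q = (np.arange(1, n + 1) - 0.5) / n
    t = -tau * np.log1p(-q)
    D, p = m.ks_test(t, tau)
    assert D == pytest.approx(0.5 / n)
    assert p > 0.99


def test_ks_single_sample_two_sided_jump():
    D, _ = m.ks_test([3.0], 3.0)
    assert D == pytest.approx(1.0 - math.exp(-1.0))


def test_ks_matches_scipy_reference():
    rng = np.random.default_rng(5)
    t = rng.exponential(2.0, size=25)
    D, p = m.ks_test(t, 2.0)
    ref = sps.kstest(t, lambda x: 1.0 - np.exp(-x / 2.0))
    assert D == pytest.approx(ref.statistic, abs=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.floats(min_value=0.01, max_value=1e4))
def test_ks_scale_equivariance(c):
    """Multiplying all times by c scales tau by c and leaves (D, p) fixed."""
    rng = np.random.default_rng(11)
    t = rng.exponential(1.0, size=16)
    f1 = m.fit_exponential(t)
    f2 = m.fit_exponential(c * t)
    assert f2.tau == pytest.approx(c * f1.tau, rel=1e-9)
    assert f2.D == pytest.approx(f1.D, abs=1e-9)
    assert f2.p == pytest.approx(f1.p, abs=1e-9)


def test_ks_bootstrap_is_consistent_for_good_fit():
    rng = np.random.default_rng(2)
    t = rng.exponential(3.0, size=16)
    fit = m.fit_exponential(t)
    D, p_boot = m.ks_test_bootstrap(t, fit.tau, n_boot=199, seed=0)
    assert D == pytest.approx(fit.D)
    assert p_boot > 0.05


def test_relative_kon_table_values():
    # unit relative off-rate with K_D = 0.6 +/- 0.06 uM (a 10% relative
    # error) gives k_on_rel = 1/0.6 = 1.667 uM^-1 with the same 10% error
    kon, err = m.relative_kon(1.0, 0.0, 0.6, 0.06)
    assert kon == pytest.approx(1.667, abs=5e-4)
    assert err / kon == pytest.approx(0.10)
    # both input errors zero -> zero output error
    assert m.relative_kon(1.0, 0.0, 0.6, 0.0)[1] == 0.0
    # linearity in the off-rate
    assert m.relative_kon(2.0, 0.0, 0.6, 0.0)[0] == pytest.approx(2 * kon, abs=1e-3)
    with pytest.raises(ValueError):
        m.relative_kon(1.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        m.relative_kon(-1.0, 0.0, 0.6, 0.0)


def _kd_table():
    return pd.DataFrame([
        {"ligand": "A", "kd": 0.6, "kd_err": 0.06},
        {"ligand": "B", "kd": 1.5, "kd_err": 0.3},
    ])


def test_report_schema_and_flags():
    rng = np.random.default_rng(4)
    events = {"A": rng.exponential(5.0, size=16),
              "B": rng.exponential(50.0, size=16)}
    df = m.kinetics_report(events, _kd_table())
    assert len(df) == 2
    assert set(["ligand", "tau", "ks_p", "ks_pass", "k_off_rel",
                "k_on_rel", "in_ranking"]).issubset(df.columns)
    assert ((df["ks_p"] >= 0) & (df["ks_p"] <= 1)).all()
    assert (df["ks_pass"] == (df["ks_p"] > 0.05)).all()


def test_report_failing_ks_excluded_from_ranking():
    # near-degenerate times: a terrible exponential fit, small p
    bad = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.001, 0.999])
    good = np.random.default_rng(1).exponential(2.0, size=16)
    df = m.kinetics_report({"A": bad, "B": good}, _kd_table())
    row = df[df["ligand"] == "A"].iloc[0]
    assert row["ks_p"] <= 0.05 and not row["in_ranking"]
    assert "A" in df["ligand"].values  # present in the full table


def test_report_missing_kd_keeps_row_without_rates():
    t = np.random.default_rng(2).exponential(1.0, size=8)
    df = m.kinetics_report({"C": t}, _kd_table())
    row = df.iloc[0]
    assert np.isnan(row["k_on_rel"]) and np.isnan(row["kd"])
    assert not row["in_ranking"]
    assert row["tau"] > 0  # the fit itself is still reported


def test_report_too_few_events_raises():
    with pytest.raises(ValueError, match="'A' has only 2"):
        m.kinetics_report({"A": [1.0, 2.0]}, _kd_table())
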