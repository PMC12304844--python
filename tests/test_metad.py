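"""Well-tempered metadynamics: bias sums, tempering, FES, bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mlmetad as m
from mlmetad import presets

from conftest import make_ledger


def test_empty_ledger_bias_is_zero(thermo):
    led = make_ledger(thermo, [], [], [0.2])
    led.biased_variables = ["s0"]
    assert led.bias_energy(np.array([0.3])) == 0.0


def test_single_hill_bias_values(thermo):
    led = make_ledger(thermo, [[1.0]], [0.7], [0.2])
    assert led.bias_energy(np.array([1.0])) == pytest.approx(0.7)
    # displaced by one sigma on one axis: height * exp(-1/2)
    assert led.bias_energy(np.array([1.2])) == pytest.approx(0.7 * math.exp(-0.5))


def test_two_dim_hill_and_gradient(thermo):
    led = make_ledger(thermo, [[0.0, 0.0]], [1.0], [0.3, 0.5])
    s = np.array([0.1, -0.2])
    # finite-difference check of the analytic bias gradient
    h = 1e-7
    for j in range(2):
        sp, sm = s.copy(), s.copy()
        sp[j] += h
        sm[j] -= h
        fd = (led.bias_energy(sp) - led.bias_energy(sm)) / (2 * h)
        assert led.bias_gradient(s)[j] == pytest.approx(fd, abs=1e-6)


def test_bias_respects_time_cutoff(thermo):
    led = make_ledger(thermo, [[0.0], [0.0]], [1.0, 1.0], [0.2])
    assert led.bias_energy(np.array([0.0]), t_upto=1.5) == pytest.approx(1.0)
    assert led.bias_energy(np.array([0.0]), t_upto=2.5) == pytest.approx(2.0)


def test_next_hill_height_tempering_rule(thermo):
    led = make_ledger(thermo, [], [], [0.2], gamma=10.0)
    led.biased_variables = ["s0"]
    h0 = 1.5
    # no bias yet -> full height
    assert m.next_hill_height(led, np.array([0.0]), h0) == pytest.approx(h0)
    # V = kB DeltaT ln 2 -> h0 / 2
    v_half = (10.0 - 1.0) * thermo.kT * math.log(2.0)
    led2 = make_ledger(thermo, [[0.0]], [v_half], [0.2], gamma=10.0)
    assert m.next_hill_height(led2, np.array([0.0]), h0) == pytest.approx(h0 / 2)
    # untempered limit: gamma -> infinity gives h0 regardless of V
    led3 = make_ledger(thermo, [[0.0]], [5.0], [0.2], gamma=math.inf)
    assert m.next_hill_height(led3, np.array([0.0]), h0) == pytest.approx(h0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 2)),
                min_size=1, max_size=8),
       st.floats(-3, 3))
def test_bias_nonnegative_and_monotone_in_time(centers_heights, s):
    """V(s, t) >= 0 and non-decreasing in t at fixed s (positive heights)."""
    th = m.ThermoContext()
    centers = [[c] for c, _ in centers_heights]
    heights = [h for _, h in centers_heights]
    led = make_ledger(th, centers, heights, [0.3])
    prev = 0.0
    for t in range(len(centers) + 1):
        v = led.bias_energy(np.array([s]), t_upto=float(t) + 0.5)
        assert v >= prev - 1e-12
        prev = v
    assert prev >= 0.0


def test_deposited_heights_decrease_at_revisited_point(thermo):
    """Tempering: rerunning WT-MetaD in a narrow well, heights at the
    (repeatedly revisited) bound basin must be non-increasing overall."""
    surf = m.CustomPolynomial([0.0, 0.0, 8.0])  # stiff single well
    bv = [m.BiasVariable("x", np.array([1.0]))]
    mp = m.MetadParams(sigma=[0.2], h0=1.0, gamma=8.0, pace=0.25,
                       max_time=200.0)
    run = m.run_wtmetad(surf, bv, mp, thermo,
                        m.LangevinParams(n_steps=40_000, seed=4), stride=10)
    h = np.array([hill.height for hill in run.ledger.hills])
    assert h[0] <= mp.h0 + 1e-12
    assert np.all(h > 0)
    # first hills near h0, late hills strongly tempered
    assert h[:5].mean() > h[-5:].mean()


def test_pace_longer_than_budget_gives_zero_hills(thermo):
    dw = m.DoubleWell(a=2.0)
    bv = [m.BiasVariable("x", np.array([1.0]))]
    mp = m.MetadParams(sigma=[0.2], h0=1.0, gamma=10.0, pace=1000.0,
                       max_time=10.0)
    run = m.run_wtmetad(dw, bv, mp, thermo,
                        m.LangevinParams(n_steps=2000, seed=0), stride=10)
    assert len(run.ledger.hills) == 0 and run.event is False


def test_hill_count_matches_event_time(thermo):
    """With an event at t_e, the ledger holds floor(t_e / pace) hills."""
    sys = presets.funnel_system()
    dim = sys.surface.dim
    bv = [m.BiasVariable("d_exit", sys.cv_defs[0].linear_weights(dim)),
          m.BiasVariable("d_gate", sys.cv_defs[1].linear_weights(dim))]
    mp = m.MetadParams(sigma=[0.14, 0.24], h0=1.5, gamma=40.0, pace=1.0,
                       max_time=5000.0)
    run = m.run_wtmetad(sys.surface, bv, mp, thermo,
                        m.LangevinParams(n_steps=1_000_000, seed=42),
                        stop=sys.stop_condition(), stride=10)
    assert run.event
    assert len(run.ledger.hills) == int(run.event_time / mp.pace)


def test_metad_run_is_deterministic(thermo):
    dw = m.DoubleWell(a=3.0)
    bv = [m.BiasVariable("x", np.array([1.0]))]
    mp = m.MetadParams(sigma=[0.15], h0=0.5, gamma=10.0, pace=0.5,
                       max_time=100.0)
    lp = m.LangevinParams(n_steps=20_000, seed=21)
    a = m.run_wtmetad(dw, bv, mp, thermo, lp, stride=10)
    b = m.run_wtmetad(dw, bv, mp, thermo, lp, stride=10)
    assert np.array_equal(a.trajectory.cv_matrix, b.trajectory.cv_matrix)
    assert np.array_equal([h.height for h in a.ledger.hills],
                          [h.height for h in b.ledger.hills])


def test_recorded_frame_bias_matches_ledger_sum(thermo):
    """The per-frame V(s(t)) recorded by the engine (grid cache) agrees
    with the exact hill sum evaluated just before each frame's time."""
    dw = m.DoubleWell(a=3.0)
    bv = [m.BiasVariable("x", np.array([1.0]))]
    mp = m.MetadParams(sigma=[0.15], h0=0.5, gamma=10.0, pace=0.5,
                       max_time=50.0)
    run = m.run_wtmetad(dw, bv, mp, thermo,
                        m.LangevinParams(n_steps=10_000, seed=2), stride=25)
    tr = run.trajectory
    exact = np.array([run.ledger.bias_energy(tr.cv_matrix[i],
                                             t_upto=tr.times[i] - 1e-9)
                      for i in range(tr.n_frames)])
    assert np.max(np.abs(tr.bias_energy - exact)) < 0.02


def test_fes_prefactor_and_single_hill_shape(thermo):
    led = make_ledger(thermo, [[0.0]], [1.0], [0.3], gamma=40.0)
    fes = m.fes_from_hills(led, [(-2.0, 2.0, 401)])
    pref = 40.0 / 39.0
    assert fes.free_energy.min() == 0.0
    # min at the hill center; far away the FES rises to pref * height
    assert fes.min_location[0] == pytest.approx(0.0, abs=0.02)
    assert fes.free_energy[0] == pytest.approx(pref * 1.0, abs=1e-4)


def test_fes_empty_ledger_raises(thermo):
    led = make_ledger(thermo, [], [], [0.2])
    led.biased_variables = ["s0"]
    with pytest.raises(ValueError, match="empty ledger"):
        m.fes_from_hills(led, [(-1.0, 1.0, 11)])


def test_metad_params_invariants():
    with pytest.raises(ValueError):
        m.MetadParams(sigma=[0.0])
    with pytest.raises(ValueError):
        m.MetadParams(sigma=[0.1], gamma=1.0)
    with pytest.raises(ValueError):
        m.MetadParams(sigma=[0.1], h0=0.0)
    with pytest.raises(ValueError, match="1 or 2"):
        m.MetadParams(sigma=[0.1, 0.1, 0.1])
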