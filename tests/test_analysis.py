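"""Mechanistic observables: projections, coordination, distances, Delta RMSD."""

import numpy as np
import pytest

import mlmetad as m
from mlmetad.analysis import (coordination_number, delta_rmsd, end_to_end,
                              fes_projection)
from mlmetad.trajectory import Trajectory


def _traj_from_cv(values, name="s", positions=None):
    values = np.asarray(values, dtype=float)
    return Trajectory(times=np.arange(values.shape[0]) * 1.0,
                      cv_matrix=values[:, None], cv_names=[name],
                      positions=positions)


# ------------------------------------------------------------- projections

def test_unbiased_harmonic_projection_matches_half_k_s_squared(thermo):
    # Boltzmann samples of U = 0.5 k s^2 -> F(s) = 0.5 k s^2 (+ const)
    k = 4.0
    rng = np.random.default_rng(0)
    s = rng.normal(0.0, np.sqrt(thermo.kT / k), size=400_000)
    tr = _traj_from_cv(s)
    fes = fes_projection([tr], ["s"], [(-1.0, 1.0, 41)], thermo)
    ax = fes.axes[0]
    well = np.abs(ax) < 0.6
    expected = 0.5 * k * ax ** 2
    expected -= expected[well].min()
    assert np.max(np.abs(fes.free_energy[well] - expected[well])) < 0.15


def test_uniform_samples_give_flat_projection(thermo):
    rng = np.random.default_rng(1)
    tr = _traj_from_cv(rng.uniform(-1, 1, size=200_000))
    fes = fes_projection([tr], ["s"], [(-0.9, 0.9, 19)], thermo)
    assert fes.free_energy.max() - fes.free_energy.min() < 0.05
    assert fes.free_energy.min() == 0.0


def test_projection_grid_must_overlap_samples(thermo):
    tr = _traj_from_cv(np.zeros(100))
    with pytest.raises(ValueError, match="inside the projection grid"):
        fes_projection([tr], ["s"], [(5.0, 6.0, 10)], thermo)


def test_reweighted_projection_recovers_underlying_well(thermo):
    """Biased double-well run: reweighting by exp(+beta V_final) must
    restore the two minima to comparable depths."""
    dw = m.DoubleWell(a=4.0)
    bv = [m.BiasVariable("x", np.array([1.0]))]
    mp = m.MetadParams(sigma=[0.15], h0=0.5, gamma=10.0, pace=1.0,
                       max_time=5000.0)
    run = m.run_wtmetad(dw, bv, mp, thermo,
                        m.LangevinParams(n_steps=1_000_000, seed=6), stride=10)
    fes = fes_projection([run.trajectory], ["x"], [(-1.4, 1.4, 57)], thermo,
                         ledgers=[run.ledger])
    ax, f = fes.axes[0], fes.free_energy
    left = f[np.argmin(np.abs(ax + 1.0))]
    right = f[np.argmin(np.abs(ax - 1.0))]
    barrier = f[np.argmin(np.abs(ax))]
    assert abs(left - right) < 1.0
    assert barrier - min(left, right) == pytest.approx(4.0, abs=1.2)


# ------------------------------------------------------------ coordination

def test_coordination_limits_and_midpoint():
    assert coordination_number(np.array([1e-9]), r0=1.0)[0] == pytest.approx(1.0)
    assert coordination_number(np.array([1.0]), r0=1.0)[0] == pytest.approx(0.5)
    assert coordination_number(np.array([50.0]), r0=1.0)[0] == pytest.approx(0.0, abs=1e-9)
    # continuity through r = r0
    f = coordination_number(np.array([1.0 - 1e-8, 1.0 + 1e-8]), r0=1.0)
    assert np.allclose(f, 0.5, atol=1e-6)


def test_coordination_sums_over_partners():
    r = np.array([[1e-9, 50.0], [1e-9, 1e-9]])
    c = coordination_number(r, r0=1.0)
    assert c[0] == pytest.approx(1.0)
    assert c[1] == pytest.approx(2.0)


def test_coordination_invalid_inputs():
    with pytest.raises(ValueError, match="r0"):
        coordination_number(np.array([1.0]), r0=0.0)
    with pytest.raises(ValueError, match="non-negative"):
        coordination_number(np.array([-1.0]), r0=1.0)


# ------------------------------------------------------------- end to end

def test_end_to_end_basics():
    pos = np.zeros((5, 2))
    tr = _traj_from_cv(np.zeros(5), positions=pos)
    d = end_to_end(tr, ("coords", [0]), ("coords", [1]))
    assert np.allclose(d, 0.0)  # coincident endpoints
    d2 = end_to_end(tr, ("fixed", [0.0]), ("fixed", [3.0]))
    assert np.allclose(d2, 3.0)  # fixed endpoints at distance 3


def test_end_to_end_translation_invariance():
    rng = np.random.default_rng(3)
    pos = rng.normal(size=(20, 2))
    t1 = _traj_from_cv(np.zeros(20), positions=pos)
    t2 = _traj_from_cv(np.zeros(20), positions=pos + 7.5)
    d1 = end_to_end(t1, ("coords", [0]), ("coords", [1]))
    d2 = end_to_end(t2, ("coords", [0]), ("coords", [1]))
    assert np.allclose(d1, d2)


def test_end_to_end_missing_endpoint():
    tr = _traj_from_cv(np.zeros(5), positions=np.zeros((5, 2)))
    with pytest.raises(ValueError, match="out of range"):
        end_to_end(tr, ("coords", [0]), ("coords", [4]))


# -------------------------------------------------------------- delta rmsd

def test_delta_rmsd_identical_windows_is_zero():
    rng = np.random.default_rng(0)
    w = rng.normal(size=(200, 3))
    prof = delta_rmsd([w.copy()], w)
    assert np.allclose(prof.delta, 0.0)


def test_delta_rmsd_known_fluctuation_difference():
    rng = np.random.default_rng(1)
    n = 200_000
    ref = rng.normal(0.0, 1.0, size=(n, 1))
    win = rng.normal(5.0, 2.0, size=(n, 1))  # mean offset must not matter
    prof = delta_rmsd([win], ref)
    assert prof.delta[0] == pytest.approx(1.0, abs=0.02)


def test_delta_rmsd_permutation_invariance():
    rng = np.random.default_rng(2)
    ref = rng.normal(size=(500, 2))
    win = rng.normal(size=(500, 2))
    p1 = delta_rmsd([win], ref)
    p2 = delta_rmsd([win[rng.permutation(500)]], ref)
    assert np.allclose(p1.delta, p2.delta)


def test_delta_rmsd_roster_mismatch():
    with pytest.raises(ValueError, match="roster mismatch"):
        delta_rmsd([np.zeros((10, 3))], np.zeros((10, 2)))
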