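"""Shared fixtures: synthetic systems and pre-trained models.

Session-scoped fixtures cache the expensive pieces (a labeled two-state
trajectory and a trained SPIB model on the training funnel) so the unit
tests and the acceptance suite can share them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mlmetad as m
from mlmetad import presets
from mlmetad.cvs import compute_cvs


@pytest.fixture(scope="session")
def thermo():
    return m.ThermoContext()


@pytest.fixture(scope="session")
def two_state(thermo):
    """Unbiased double-well trajectory (3 kT barrier, frequent hopping)
    with one informative CV, three distractors, and cutoff labels."""
    sys = presets.double_well_system(name="dw3", barrier=3.0, n_distractors=3)
    lp = m.LangevinParams(n_steps=300_000, seed=5)
    traj = m.integrate_langevin(sys.surface, lp, thermo, stride=10)
    traj = compute_cvs(traj, sys.cv_defs)
    labels = m.initial_labels(traj, [("d_exit", ">", 0.0)])
    return sys, traj, labels


@pytest.fixture(scope="session")
def trained_funnel(thermo):
    """Round-1 WT-MetaD on the training funnel plus a trained SPIB model.

    Returns (system, round1 trajectory, labels, model, rc sigma).
    """
    sys = presets.funnel_system()
    dim = sys.surface.dim
    bv = [m.BiasVariable("d_exit", sys.cv_defs[0].linear_weights(dim)),
          m.BiasVariable("d_gate", sys.cv_defs[1].linear_weights(dim))]
    tr_u = m.integrate_langevin(
        sys.surface, m.LangevinParams(n_steps=100_000, seed=1), thermo,
        stride=10)
    tr_u = compute_cvs(tr_u, sys.cv_defs)
    sig = presets.sigma_from_std(tr_u.cv_matrix.std(axis=0)[:2], 0.75)
    mp = m.MetadParams(sigma=sig, h0=1.5, gamma=40.0, pace=1.0,
                       biased_variables=["d_exit", "d_gate"], max_time=5000.0)
    run = m.run_wtmetad(sys.surface, bv, mp, thermo,
                        m.LangevinParams(n_steps=1_000_000, seed=42),
                        stride=10)
    traj1 = compute_cvs(run.trajectory, sys.cv_defs)
    labels = m.initial_labels(traj1, [("d_exit", ">", presets.EXIT_CUTOFF)])
    bound_mask = labels.labels == 0
    cfg = m.SPIBConfig(lag=20, latent_dim=2, epochs=40, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = m.train_spib([traj1], [labels], cfg, norm_mask=bound_mask)
    rc = m.project_rc(model, traj1)
    stats = m.rc_statistics(rc, bound_mask)
    return sys, traj1, labels, model, stats.sigma


def make_ledger(thermo, centers, heights, sigma, gamma=10.0, names=None):
    """Small helper to build ledgers by hand in tests."""
    hills = [m.Hill(time=float(i + 1), center=np.atleast_1d(np.asarray(c, float)),
                    sigma=np.atleast_1d(np.asarray(sigma, float)),
                    height=float(h))
             for i, (c, h) in enumerate(zip(centers, heights))]
    nd = hills[0].center.size if hills else 1
    return m.HillsLedger(hills=hills, gamma=gamma, thermo=thermo,
                         biased_variables=names or [f"s{k}" for k in range(nd)])
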