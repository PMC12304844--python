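"""Mechanistic observables computed from (biased) trajectories.

These are the trajectory analyses used to characterize dissociation
mechanisms: free-energy projections onto chosen CVs with final-bias
reweighting, smooth coordination numbers via a rational switching
function, end-to-end distances, and per-coordinate flexibility changes
(Delta RMSD) between ligand-exit windows and an unbiased reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metad import FESGrid, HillsLedger
from .thermo import ThermoContext
from .trajectory import Trajectory


def fes_projection(trajs: list[Trajectory], cv_names: list[str],
                   grid: list[tuple[float, float, int]],
                   thermo: ThermoContext,
                   ledgers: list[HillsLedger] | None = None) -> FESGrid:
    """Reweighted free-energy projection onto one or two CVs.

    Histograms the visited CV values with per-frame weights
    exp(+beta V_final(s_i)) (final-bias well-tempered reweighting, where
    s_i are the frame's biased-variable values from the matching ledger),
    converts to F = -kT ln P, and min-shifts to zero.  With no ledgers the
    samples are treated as unbiased.
    """
    if len(cv_names) not in (1, 2):
        raise ValueError("project onto one or two CVs")
    if len(grid) != len(cv_names):
        raise ValueError("one (lo, hi, n) triple per projected CV")
    if ledgers is not None and len(ledgers) != len(trajs):
        raise ValueError("one ledger per trajectory (or None)")
    edges = [np.linspace(lo, hi, int(n) + 1) for lo, hi, n in grid]
    hist = np.zeros([int(n) for _, _, n in grid])
    for i, traj in enumerate(trajs):
        vals = np.column_stack([traj.cv(n) for n in cv_names])
        if ledgers is not None and ledgers[i].hills:
            led = ledgers[i]
            s = np.column_stack([traj.cv(n) for n in led.biased_variables])
            w = np.exp(thermo.beta * led.bias_energy(s))
        else:
            w = np.ones(traj.n_frames)
        h, _ = np.histogramdd(vals, bins=edges, weights=w)
        hist += h
    if hist.sum() <= 0:
        raise ValueError("no samples fall inside the projection grid")
    with np.errstate(divide="ignore"):
        f = -thermo.kT * np.log(hist / hist.sum())
    finite = np.isfinite(f)
    if not finite.any():
        raise ValueError("projection grid does not overlap the samples")
    f = f - f[finite].min()
    f[~finite] = np.nanmax(f[finite])  # empty bins pinned to the ceiling
    axes = [0.5 * (e[1:] + e[:-1]) for e in edges]
    return FESGrid(axes=axes, free_energy=f)


def coordination_number(r: np.ndarray, r0: float, n: int = 6, m: int = 12) -> np.ndarray:
    """Smooth neighbor count via the rational switching function.

    f(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m), continuous at r = r0 with the
    limiting value n/m; f -> 1 as r -> 0 and f -> 0 as r >> r0.  A 2-D
    input (frames x partners) is summed over partners.
    """
    if not (r0 > 0):
        raise ValueError("switching radius r0 must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    x = r / r0
    with np.errstate(invalid="ignore", divide="ignore"):
        num = 1.0 - x ** n
        den = 1.0 - x ** m
        f = np.where(np.abs(den) > 1e-10,
                     num / np.where(np.abs(den) > 1e-10, den, 1.0),
                     (n / m) * x ** (n - m))
    if f.ndim == 2:
        return f.sum(axis=1)
    return f


def _endpoint_series(spec: tuple, positions: np.ndarray) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        p = np.asarray(spec[1], dtype=float)
        return np.broadcast_to(p, (positions.shape[0], p.size))
    if kind == "coords":
        idx = list(spec[1])
        if max(idx) >= positions.shape[1]:
            raise ValueError(f"endpoint coordinate index {max(idx)} out of range")
        return positions[:, idx]
    raise ValueError(f"unknown endpoint kind {kind!r}")


def end_to_end(traj: Trajectory, endpoint_a: tuple, endpoint_b: tuple) -> np.ndarray:
    """Per-frame Euclidean distance between two endpoint definitions.

    Endpoints are ``("fixed", point)`` or ``("coords", indices)``; both
    must have the same dimensionality and be defined at every frame.
    """
    if traj.positions is None:
        raise ValueError("trajectory has no positions")
    a = _endpoint_series(endpoint_a, traj.positions)
    b = _endpoint_series(endpoint_b, traj.positions)
    if a.shape != b.shape:
        raise ValueError("endpoint definitions have mismatched dimensionality")
    return np.linalg.norm(a - b, axis=1)


@dataclass
class FlexibilityProfile:
    """Per-coordinate fluctuation change between exit and reference windows.

    delta[i] = mean over runs of RMSF_i(exit window) - RMSF_i(reference),
    where RMSF is the root-mean-square fluctuation about the window's own
    mean; identically zero when the windows are statistically identical.
    """

    delta: np.ndarray
    labels: list[str]
    n_runs: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("Delta RMSD must be finite")


def _rmsf(window: np.ndarray) -> np.ndarray:
    return window.std(axis=0)


def delta_rmsd(exit_windows: list[np.ndarray], reference: np.ndarray,
               labels: list[str] | None = None) -> FlexibilityProfile:
    """Flexibility change of each coordinate during ligand exit.

    ``exit_windows``: one (frames x coords) array per biased run (the
    frames around the dissociation event); ``reference``: frames x coords
    from the unbiased ligand-removed reference run.  All windows must share
    the coordinate roster.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[0] < 2:
        raise ValueError("reference window needs >= 2 frames")
    deltas = []
    for w in exit_windows:
        w = np.asarray(w, dtype=float)
        if w.ndim != 2 or w.shape[1] != ref.shape[1]:
            raise ValueError("exit window coordinate roster mismatch")
        if w.shape[0] < 2:
            raise ValueError("exit window needs >= 2 frames")
        deltas.append(_rmsf(w) - _rmsf(ref))
    if not deltas:
        raise ValueError("at least one exit window is required")
    labels = labels or [f"x{i}" for i in range(ref.shape[1])]
    if len(labels) != ref.shape[1]:
        raise ValueError("one label per coordinate is required")
    return FlexibilityProfile(delta=np.mean(deltas, axis=0), labels=labels,
                              n_runs=len(deltas))
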