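"""Langevin dynamics on model surfaces and the brute-force kinetics oracle.

The integrator is the symmetric BAOAB splitting (half kick, half drift,
Ornstein-Uhlenbeck thermal step, half drift, half kick), which samples the
canonical distribution with O(dt^2) configurational error.  Every run is a
pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .potentials import PotentialSurface
from .thermo import ThermoContext
from .trajectory import Trajectory

_STOP_MODES = {"above": _kernels.STOP_ABOVE,
               "abs_above": _kernels.STOP_ABS_ABOVE,
               "below": _kernels.STOP_BELOW}


@dataclass(frozen=True)
class LangevinParams:
    """Integrator settings: time step, friction, mass, steps, seed."""

    dt: float = 0.005
    friction: float = 1.0
    mass: float = 1.0
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if not (self.friction > 0):
            raise ValueError("friction must be > 0")
        if not (self.mass > 0):
            raise ValueError("mass must be > 0")
        if self.n_steps < 1:
            raise ValueError("at least one step must be requested")


@dataclass
class StopCondition:
    """Committed first-passage criterion on a linear function of positions.

    The event fires at the first step of an excursion that stays on the
    stop side of ``cutoff`` for ``commit_steps`` consecutive steps; the
    commitment requirement suppresses recrossing artifacts.
    """

    weights: np.ndarray  # (dim,)
    cutoff: float
    mode: str = "above"  # "above" | "abs_above" | "below"
    commit_steps: int = 50

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.mode not in _STOP_MODES:
            raise ValueError(f"unknown stop mode {self.mode!r}")
        if self.commit_steps < 1:
            raise ValueError("commit_steps must be >= 1")


def _no_bias(dim: int):
    z1 = np.zeros(1)
    return dict(bw=np.zeros((0, dim)), bmu=z1[:0], bsd=z1[:0],
                sigma=z1[:0], h0=0.0, gamma=2.0, pace_steps=0,
                grid_lo=np.zeros(1), grid_hi=np.ones(1),
                grid_n=np.array([2], dtype=np.int64),
                Vg=np.zeros(2), G0g=np.zeros(2), G1g=np.zeros(1))


def _no_stop(dim: int):
    return dict(stop_w=np.zeros(dim), stop_mu=0.0, stop_sd=1.0,
                stop_cutoff=0.0, stop_mode=_kernels.STOP_NONE, commit_m=1)


def _run_kernel(surface: PotentialSurface, params: LangevinParams,
                thermo: ThermoContext, stride: int,
                x0: np.ndarray | None = None,
                bias_args: dict | None = None,
                stop: StopCondition | None = None):
    dim = surface.dim
    x0 = surface.start_position.copy() if x0 is None else np.asarray(x0, float)
    if x0.shape != (dim,):
        raise ValueError(f"x0 must have shape ({dim},)")
    kw = _no_bias(dim)
    if bias_args is not None:
        kw.update(bias_args)
    skw = _no_stop(dim)
    if stop is not None:
        skw = dict(stop_w=stop.weights, stop_mu=0.0, stop_sd=1.0,
                   stop_cutoff=float(stop.cutoff),
                   stop_mode=_STOP_MODES[stop.mode],
                   commit_m=int(stop.commit_steps))
    out = _kernels.simulate(
        surface.kernel_code, surface.kernel_params, x0,
        params.dt, params.friction, params.mass, thermo.kT,
        params.n_steps, int(stride), params.seed,
        kw["bw"], kw["bmu"], kw["bsd"], kw["sigma"], kw["h0"], kw["gamma"],
        kw["pace_steps"], kw["grid_lo"], kw["grid_hi"], kw["grid_n"],
        kw["Vg"], kw["G0g"], kw["G1g"],
        skw["stop_w"], skw["stop_mu"], skw["stop_sd"], skw["stop_cutoff"],
        skw["stop_mode"], skw["commit_m"])
    err_step = int(out[11])
    if err_step >= 0:
        raise FloatingPointError(
            f"non-finite position or force at step {err_step}; "
            "reduce dt or check the surface parameters")
    return out


def integrate_langevin(surface: PotentialSurface, params: LangevinParams,
                       thermo: ThermoContext, stride: int = 1,
                       x0: np.ndarray | None = None,
                       stop: StopCondition | None = None) -> Trajectory:
    """Unbiased Langevin trajectory; positions recorded every ``stride`` steps.

    The returned trajectory has the raw coordinates as positions and an
    empty CV matrix (use :func:`mlmetad.cvs.compute_cvs` to populate it).
    Identical configuration and seed give a bit-identical trajectory.
    """
    (n_frames, times, frames, _bias, _nh, _hs, _hc, _hh, _hb,
     _event, _estep, _err) = _run_kernel(surface, params, thermo, stride,
                                         x0=x0, stop=stop)
    return Trajectory(
        times=times[:n_frames],
        cv_matrix=np.zeros((n_frames, 0)),
        cv_names=[],
        positions=frames[:n_frames],
        seed=params.seed,
        provenance=f"langevin:{surface.kernel_code}",
    )


@dataclass
class MFPTResult:
    """Brute-force mean first-passage time over independent seeded runs."""

    mean: float
    stderr: float  # nan when only one event was requested
    times: np.ndarray
    n_events: int


def mfpt_bruteforce(surface: PotentialSurface, params: LangevinParams,
                    thermo: ThermoContext, stop: StopCondition,
                    n_events: int, x0: np.ndarray | None = None) -> MFPTResult:
    """Unbiased first-exit times over ``n_events`` independent seeded runs.

    Run ``i`` uses seed ``params.seed + i`` with ``params.n_steps`` as the
    per-run budget.  Raises ``RuntimeError`` (reporting the count achieved)
    if any run exhausts its budget without an exit.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    times = np.empty(n_events)
    for i in range(n_events):
        p = LangevinParams(dt=params.dt, friction=params.friction,
                           mass=params.mass, n_steps=params.n_steps,
                           seed=params.seed + i)
        out = _run_kernel(surface, p, thermo, stride=max(1, params.n_steps),
                          x0=x0, stop=stop)
        event, estep = bool(out[9]), int(out[10])
        if not event:
            raise RuntimeError(
                f"event budget exhausted: {i} of {n_events} exits observed "
                f"within {params.n_steps} steps per run")
        times[i] = estep * params.dt
    mean = float(np.mean(times))
    stderr = float(np.std(times, ddof=1) / np.sqrt(n_events)) if n_events > 1 else float("nan")
    return MFPTResult(mean=mean, stderr=stderr, times=times, n_events=n_events)
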