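"""Well-tempered metadynamics: hill deposition, bias evaluation, FES.

The bias at time t is the sum of deposited Gaussian hills,

    V(s, t) = sum_{t_i <= t} h_i exp( -sum_j (s_j - c_ij)^2 / (2 sigma_j^2) ),

with tempered heights h_i = h0 exp(-V(c_i, t_i) / (kB DeltaT)), where
DeltaT = (gamma - 1) T and gamma > 1 is the bias factor.  The free-energy
surface is estimated from the final bias by the well-tempered relation
F(s) = -gamma/(gamma-1) V(s, t_final) + const, min-shifted to zero.

Hills are deposited on 1 or 2 biased variables, each a linear function of
the particle coordinates (a raw CV in protocol round 1, a learned reaction
coordinate in round 2); forces on the coordinates follow by the chain rule
through the linear map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .langevin import LangevinParams, StopCondition, _run_kernel
from .potentials import PotentialSurface
from .thermo import ThermoContext
from .trajectory import Trajectory


@dataclass(frozen=True)
class BiasVariable:
    """A biasable variable: value = (weights . x - mean) / std.

    ``mean``/``std`` default to the identity affine map; a learned reaction
    coordinate sets them from its stored normalization so that hill widths
    are expressed in the RC's own units.
    """

    name: str
    weights: np.ndarray
    mean: float = 0.0
    std: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if not (self.std > 0):
            raise ValueError("BiasVariable std must be > 0")

    def value(self, positions: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(positions) @ self.weights - self.mean) / self.std


@dataclass
class MetadParams:
    """WT-MetaD settings (sigma per biased variable, h0, gamma, pace).

    ``pace`` and ``max_time`` are in time units; pace must be at least the
    integrator step.
    """

    sigma: np.ndarray
    h0: float = 1.5
    gamma: float = 40.0
    pace: float = 1.0
    biased_variables: list[str] = field(default_factory=list)
    max_time: float = 1000.0

    def __post_init__(self) -> None:
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("every sigma component must be > 0")
        if self.sigma.size not in (1, 2):
            raise ValueError("1 or 2 biased variables are supported")
        if not (self.h0 > 0):
            raise ValueError("initial hill height h0 must be > 0")
        if not (self.gamma > 1):
            raise ValueError("bias factor gamma must be > 1")
        if not (self.pace > 0):
            raise ValueError("pace must be > 0")
        if not (self.max_time > 0):
            raise ValueError("max_time must be > 0")


@dataclass
class Hill:
    time: float
    center: np.ndarray
    sigma: np.ndarray
    height: float
    bias_at_deposit: float = float("nan")


@dataclass
class HillsLedger:
    """Time-ordered record of deposited hills; defines V(s, t)."""

    hills: list[Hill]
    gamma: float
    thermo: ThermoContext
    biased_variables: list[str]

    def __post_init__(self) -> None:
        t = [h.time for h in self.hills]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("hill times must be strictly increasing")
        dims = {h.center.size for h in self.hills}
        if len(dims) > 1:
            raise ValueError("all hills must share dimensionality")

    @property
    def n_dims(self) -> int:
        if self.hills:
            return int(self.hills[0].center.size)
        return len(self.biased_variables)

    def _arrays(self, t_upto: float | None):
        hs = self.hills if t_upto is None else [h for h in self.hills if h.time <= t_upto]
        if not hs:
            return None
        c = np.array([h.center for h in hs])
        s = np.array([h.sigma for h in hs])
        h = np.array([h.height for h in hs])
        return c, s, h

    def bias_energy(self, s: np.ndarray, t_upto: float | None = None) -> np.ndarray | float:
        """Exact hill sum V(s, t_upto); >= 0.  ``s``: point or (n, dims)."""
        s = np.asarray(s, dtype=float)
        single = s.ndim <= 1
        S = np.atleast_2d(s)
        if S.shape[1] != self.n_dims:
            raise ValueError(f"point dimensionality {S.shape[1]} != ledger {self.n_dims}")
        arrs = self._arrays(t_upto)
        if arrs is None:
            v = np.zeros(S.shape[0])
        else:
            c, sg, h = arrs
            v = np.empty(S.shape[0])
            # chunked so n_points x n_hills stays bounded in memory
            step = max(1, 2_000_000 // max(1, c.shape[0]))
            for i in range(0, S.shape[0], step):
                blk = S[i:i + step]
                d2 = ((blk[:, None, :] - c[None, :, :]) ** 2
                      / (2.0 * sg[None, :, :] ** 2)).sum(-1)
                v[i:i + step] = np.exp(-d2) @ h
        return float(v[0]) if single else v

    def bias_gradient(self, s: np.ndarray, t_upto: float | None = None) -> np.ndarray:
        """Analytic dV/ds of the hill sum."""
        s = np.asarray(s, dtype=float)
        single = s.ndim <= 1
        S = np.atleast_2d(s)
        arrs = self._arrays(t_upto)
        if arrs is None:
            g = np.zeros_like(S)
        else:
            c, sg, h = arrs
            g = np.empty_like(S)
            step = max(1, 2_000_000 // max(1, c.shape[0]))
            for i in range(0, S.shape[0], step):
                blk = S[i:i + step]
                diff = blk[:, None, :] - c[None, :, :]
                e = h * np.exp(-(diff ** 2 / (2.0 * sg[None, :, :] ** 2)).sum(-1))
                g[i:i + step] = -(e[:, :, None] * diff / sg[None, :, :] ** 2).sum(1)
        return g[0] if single else g


def next_hill_height(ledger: HillsLedger, s: np.ndarray, h0: float,
                     t_upto: float | None = None) -> float:
    """Tempered height h0 exp(-V(s)/(kB DeltaT)) of the next hill at s.

    In the gamma -> infinity limit the height is h0 (untempered).
    """
    gamma = ledger.gamma
    if math.isinf(gamma):
        return float(h0)
    v = float(ledger.bias_energy(s, t_upto))
    dT_energy = (gamma - 1.0) * ledger.thermo.kT  # kB * DeltaT
    return float(h0 * math.exp(-v / dT_energy))


@dataclass
class FESGrid:
    """Free energy on a regular lattice, min-shifted to zero."""

    axes: list[np.ndarray]
    free_energy: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.free_energy)):
            raise ValueError("free energy must be finite on the grid")

    @property
    def min_location(self) -> tuple:
        idx = np.unravel_index(int(np.argmin(self.free_energy)), self.free_energy.shape)
        return tuple(float(self.axes[d][i]) for d, i in enumerate(idx))


def fes_from_hills(ledger: HillsLedger, grid: list[tuple[float, float, int]]) -> FESGrid:
    """Well-tempered FES estimate from the final bias.

    ``grid`` is one ``(lo, hi, n)`` triple per biased variable.  The
    estimator applies the gamma/(gamma-1) prefactor to the summed bias and
    min-shifts the result to zero.
    """
    if not ledger.hills:
        raise ValueError("cannot estimate a free-energy surface from an empty ledger")
    if len(grid) != ledger.n_dims:
        raise ValueError("grid spec must match ledger dimensionality")
    axes = [np.linspace(lo, hi, int(n)) for lo, hi, n in grid]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    v = ledger.bias_energy(pts)
    gamma = ledger.gamma
    pref = 1.0 if math.isinf(gamma) else gamma / (gamma - 1.0)
    f = -pref * v
    f -= f.min()
    return FESGrid(axes=axes, free_energy=f.reshape([a.size for a in axes]))


def _grid_for(bvars: list[BiasVariable], sigma: np.ndarray,
              box: np.ndarray, nodes_per_sigma: float = 5.0,
              max_nodes: int = 4001):
    """Bias-grid bounds by interval arithmetic over the surface box."""
    lo = np.empty(len(bvars))
    hi = np.empty(len(bvars))
    for k, bv in enumerate(bvars):
        w = bv.weights
        a = np.where(w >= 0, box[:, 0], box[:, 1]) @ w
        b = np.where(w >= 0, box[:, 1], box[:, 0]) @ w
        lo[k] = (a - bv.mean) / bv.std - 6.0 * sigma[k]
        hi[k] = (b - bv.mean) / bv.std + 6.0 * sigma[k]
    n = np.minimum(
        np.ceil((hi - lo) / (sigma / nodes_per_sigma)).astype(int) + 1,
        max_nodes)
    n = np.maximum(n, 16)
    return lo, hi, n.astype(np.int64)


@dataclass
class MetadRun:
    """Result of one WT-MetaD run."""

    trajectory: Trajectory
    ledger: HillsLedger
    event: bool
    event_time: float  # nan when no event occurred


def run_wtmetad(surface: PotentialSurface, bias_vars: list[BiasVariable],
                params: MetadParams, thermo: ThermoContext,
                langevin: LangevinParams, stop: StopCondition | None = None,
                stride: int = 10, x0: np.ndarray | None = None,
                initial_ledger: HillsLedger | None = None) -> MetadRun:
    """Run WT-MetaD, depositing hills every ``pace`` until event or budget.

    The per-frame bias V(s(t)) is recorded before that frame's deposition.
    When ``stop`` fires (committed excursion), hills deposited after the
    event time are dropped from the ledger, so the hill count equals
    floor(event_time / pace); without an event the run uses the full
    min(max_time, n_steps * dt) budget and the event flag is False.
    """
    if len(bias_vars) != params.sigma.size:
        raise ValueError("one sigma per biased variable is required")
    if not (1 <= len(bias_vars) <= 2):
        raise ValueError("1 or 2 biased variables are supported")
    pace_steps = int(round(params.pace / langevin.dt))
    if pace_steps < 1:
        raise ValueError("pace must be at least the integrator time step")
    n_steps = min(langevin.n_steps, int(round(params.max_time / langevin.dt)))
    dim = surface.dim
    bw = np.array([bv.weights for bv in bias_vars])
    bmu = np.array([bv.mean for bv in bias_vars])
    bsd = np.array([bv.std for bv in bias_vars])
    glo, ghi, gn = _grid_for(bias_vars, params.sigma, surface.box)
    n0 = int(gn[0])
    n1 = int(gn[1]) if len(bias_vars) == 2 else 1
    Vg = np.zeros(n0 * n1)
    G0g = np.zeros(n0 * n1)
    G1g = np.zeros(n0 * n1) if len(bias_vars) == 2 else np.zeros(1)
    if initial_ledger is not None and initial_ledger.hills:
        _prefill(Vg, G0g, G1g, glo, ghi, gn, initial_ledger, len(bias_vars))
    bias_args = dict(bw=bw, bmu=bmu, bsd=bsd, sigma=params.sigma,
                     h0=params.h0, gamma=params.gamma, pace_steps=pace_steps,
                     grid_lo=glo, grid_hi=ghi, grid_n=gn,
                     Vg=Vg, G0g=G0g, G1g=G1g)
    lp = LangevinParams(dt=langevin.dt, friction=langevin.friction,
                        mass=langevin.mass, n_steps=n_steps,
                        seed=langevin.seed)
    (n_frames, times, frames, bias_frames, n_hills, hill_steps, hill_centers,
     hill_heights, hill_bias, event, event_step, _err) = _run_kernel(
        surface, lp, thermo, stride, x0=x0, bias_args=bias_args, stop=stop)
    event = bool(event)
    event_time = float(event_step * langevin.dt) if event else float("nan")
    keep = n_hills
    if event:
        keep = int(np.searchsorted(hill_steps[:n_hills], event_step, side="right"))
    hills = [Hill(time=float(hill_steps[i] * langevin.dt),
                  center=hill_centers[i, :len(bias_vars)].copy(),
                  sigma=params.sigma.copy(),
                  height=float(hill_heights[i]),
                  bias_at_deposit=float(hill_bias[i]))
             for i in range(keep)]
    ledger = HillsLedger(hills=hills, gamma=params.gamma, thermo=thermo,
                         biased_variables=[bv.name for bv in bias_vars])
    svals = (frames[:n_frames] @ bw.T - bmu) / bsd
    traj = Trajectory(
        times=times[:n_frames],
        cv_matrix=svals,
        cv_names=[bv.name for bv in bias_vars],
        positions=frames[:n_frames],
        bias_energy=np.maximum(bias_frames[:n_frames], 0.0),
        seed=langevin.seed,
        provenance=f"wtmetad:gamma={params.gamma}:pace={params.pace}",
    )
    return MetadRun(trajectory=traj, ledger=ledger, event=event,
                    event_time=event_time)


def _prefill(Vg, G0g, G1g, glo, ghi, gn, ledger: HillsLedger, nb: int) -> None:
    """Add an existing ledger's exact bias onto the kernel grids."""
    if nb == 1:
        ax = np.linspace(glo[0], ghi[0], int(gn[0]))
        pts = ax[:, None]
        Vg[:] = ledger.bias_energy(pts)
        G0g[:] = ledger.bias_gradient(pts)[:, 0]
    else:
        ax0 = np.linspace(glo[0], ghi[0], int(gn[0]))
        ax1 = np.linspace(glo[1], ghi[1], int(gn[1]))
        m0, m1 = np.meshgrid(ax0, ax1, indexing="ij")
        pts = np.column_stack([m0.ravel(), m1.ravel()])
        Vg[:] = ledger.bias_energy(pts)
        g = ledger.bias_gradient(pts)
        G0g[:] = g[:, 0]
        G1g[:] = g[:, 1]
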