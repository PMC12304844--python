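"""Analytic model landscapes for ligand-dissociation toy systems.

Three families are provided:

``double_well``
    1-D quartic ``U(x) = a (x^2 - 1)^2`` (barrier ``a`` at x = 0, minima at
    x = +/-1), optionally padded with independent harmonic "distractor"
    coordinates.  Setting ``a = 0`` gives a flat (free-diffusion) line.

``dissociation_funnel``
    A 2-D bound-basin / gated-exit landscape built from Gaussian wells and a
    Gaussian ridge, plus optional harmonic distractor coordinates and an
    optional internal "extension" mode.  Coordinate 0 is the exit distance
    (the analog of a ligand--binding-site separation), coordinate 1 is a
    gating coordinate (the analog of the hydration change that precedes
    release): the ridge blocking exit has a gap only near the gate value, so
    productive exit passes through an intermediate sub-state.  A quartic
    confining wall beyond the unbound plateau keeps unbound dwell finite.

``custom_polynomial``
    1-D polynomial with user coefficients.

Every surface exposes exact analytic ``energy`` and ``gradient`` plus a
compact ``(kernel_code, kernel_params)`` encoding consumed by the numba
simulation kernels; both code paths implement the same closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

KIND_DOUBLE_WELL = 0
KIND_FUNNEL = 1
KIND_POLYNOMIAL = 2

_KINDS = {
    "double_well": KIND_DOUBLE_WELL,
    "dissociation_funnel": KIND_FUNNEL,
    "custom_polynomial": KIND_POLYNOMIAL,
}


@dataclass
class PotentialSpec:
    """Declarative description of a model landscape.

    Parameters
    ----------
    kind : str
        One of ``double_well``, ``dissociation_funnel``, ``custom_polynomial``.
    parameters : dict
        Named real coefficients; unknown names raise at build time.
    """

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)


class PotentialSurface:
    """Base class: exact energy/gradient on R^dim."""

    dim: int
    kernel_code: int
    kernel_params: np.ndarray
    start_position: np.ndarray
    box: np.ndarray  # (dim, 2) sampling bounds used for bias grids

    def energy(self, x: np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        e = self._energy(np.atleast_2d(x))
        return float(e[0]) if single else e

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        g = self._gradient(np.atleast_2d(x))
        return g[0] if single else g

    def _energy(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _gradient(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _check_finite(params: dict[str, Any]) -> None:
    for k, v in params.items():
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValueError(f"non-finite potential parameter {k!r}: {v!r}")


class DoubleWell(PotentialSurface):
    """Quartic double well with optional harmonic distractor coordinates."""

    def __init__(self, a: float = 5.0, n_distractors: int = 0,
                 k_distractor: float = 1.0) -> None:
        if a < 0:
            raise ValueError("barrier parameter a must be >= 0")
        self.a = float(a)
        self.n_distractors = int(n_distractors)
        self.k_distractor = float(k_distractor)
        self.dim = 1 + self.n_distractors
        self.kernel_code = KIND_DOUBLE_WELL
        self.kernel_params = np.array([self.a, self.k_distractor], dtype=float)
        self.start_position = np.zeros(self.dim)
        self.start_position[0] = -1.0
        self.box = np.tile([-3.0, 3.0], (self.dim, 1))

    @property
    def barrier_height(self) -> float:
        return self.a

    def _energy(self, X: np.ndarray) -> np.ndarray:
        e = self.a * (X[:, 0] ** 2 - 1.0) ** 2
        if self.dim > 1:
            e = e + 0.5 * self.k_distractor * np.sum(X[:, 1:] ** 2, axis=1)
        return e

    def _gradient(self, X: np.ndarray) -> np.ndarray:
        g = np.zeros_like(X)
        g[:, 0] = 4.0 * self.a * X[:, 0] * (X[:, 0] ** 2 - 1.0)
        if self.dim > 1:
            g[:, 1:] = self.k_distractor * X[:, 1:]
        return g


# fixed slot layout shared with the numba kernel
_FUNNEL_NP = 26


class DissociationFunnel(PotentialSurface):
    """Gated 2-D dissociation landscape; see module docstring.

    Parameters (energy in kT, lengths in reduced units)
    ---------------------------------------------------
    depth_bound, x_bound, y_bound, width_bound : bound Gaussian well.
    depth_inter, x_inter, y_inter, width_inter : intermediate (gate) well.
    ridge_height, x_ridge, width_ridge : Gaussian ridge blocking direct exit.
    y_gate, width_gate : location/width of the gap in the ridge.
    k_gate : soft harmonic confinement of the gating coordinate.
    x_wall, x_lo, k_wall : quartic confining walls on the exit coordinate.
    y_wall : quartic wall on |gate coordinate|.
    n_distractors, k_distractor : uninformative harmonic coordinates.
    k_internal, u_bound, contraction, x_contract, width_contract :
        optional internal extension mode ``u`` whose preferred value shifts
        from ``u_bound`` to ``u_bound - contraction`` as the exit coordinate
        passes ``x_contract`` (logistic switch of width ``width_contract``);
        emulates a ligand that must compress to pass the exit bottleneck.
        ``k_internal = 0`` disables the mode (one fewer coordinate).
    """

    def __init__(self, depth_bound: float = 9.0, x_bound: float = 1.0,
                 y_bound: float = 0.0, width_bound: float = 0.35,
                 depth_inter: float = 5.0, x_inter: float = 1.35,
                 y_inter: float = 1.2, width_inter: float = 0.35,
                 ridge_height: float = 8.0, x_ridge: float = 2.2,
                 width_ridge: float = 0.35, y_gate: float = 1.2,
                 width_gate: float = 0.45, k_gate: float = 0.6,
                 x_wall: float = 5.0, x_lo: float = -0.5, k_wall: float = 10.0,
                 y_wall: float = 3.0, n_distractors: int = 2,
                 k_distractor: float = 1.0, k_internal: float = 0.0,
                 u_bound: float = 1.5, contraction: float = 0.6,
                 x_contract: float = 1.8, width_contract: float = 0.25) -> None:
        if depth_bound <= 0:
            raise ValueError("bound-well depth (the barrier) must be > 0")
        if ridge_height < 0:
            raise ValueError("ridge height must be >= 0")
        if x_wall <= x_ridge:
            raise ValueError("confining wall must lie beyond the exit ridge")
        for name, v in (("width_bound", width_bound),
                        ("width_inter", width_inter),
                        ("width_ridge", width_ridge),
                        ("width_gate", width_gate),
                        ("width_contract", width_contract)):
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        self.depth_bound = float(depth_bound)
        self.n_distractors = int(n_distractors)
        self.has_internal = k_internal > 0
        self.dim = 2 + self.n_distractors + (1 if self.has_internal else 0)
        p = np.zeros(_FUNNEL_NP)
        p[0:4] = [depth_bound, x_bound, y_bound, width_bound]
        p[4:8] = [depth_inter, x_inter, y_inter, width_inter]
        p[8:13] = [ridge_height, x_ridge, width_ridge, y_gate, width_gate]
        p[13] = k_gate
        p[14:17] = [x_wall, k_wall, x_lo]
        p[17] = k_distractor
        p[18] = self.n_distractors
        p[19] = 1.0 if self.has_internal else 0.0
        p[20:25] = [k_internal, u_bound, contraction, x_contract, width_contract]
        p[25] = y_wall
        self.kernel_code = KIND_FUNNEL
        self.kernel_params = p
        self.start_position = np.zeros(self.dim)
        self.start_position[0] = x_bound
        self.start_position[1] = y_bound
        if self.has_internal:
            self.start_position[-1] = u_bound
        box = [[x_lo, x_wall + 0.5], [-y_wall - 0.5, y_wall + 0.5]]
        box += [[-3.0, 3.0]] * self.n_distractors
        if self.has_internal:
            box += [[u_bound - 3.0, u_bound + 3.0]]
        self.box = np.asarray(box, dtype=float)

    # parameter access helpers
    def _p(self) -> np.ndarray:
        return self.kernel_params

    @property
    def unbound_threshold(self) -> float:
        """Exit-coordinate value past the ridge: committed-unbound cutoff."""
        p = self._p()
        return float(p[9] + 2.0 * p[10])

    def _split(self, X: np.ndarray):
        x, y = X[:, 0], X[:, 1]
        nd = self.n_distractors
        d = X[:, 2:2 + nd]
        u = X[:, -1] if self.has_internal else None
        return x, y, d, u

    def _energy(self, X: np.ndarray) -> np.ndarray:
        p = self._p()
        x, y, d, u = self._split(X)
        gb = np.exp(-((x - p[1]) ** 2 + (y - p[2]) ** 2) / (2 * p[3] ** 2))
        gi = np.exp(-((x - p[5]) ** 2 + (y - p[6]) ** 2) / (2 * p[7] ** 2))
        ridge = np.exp(-((x - p[9]) ** 2) / (2 * p[10] ** 2))
        gate = np.exp(-((y - p[11]) ** 2) / (2 * p[12] ** 2))
        e = -p[0] * gb - p[4] * gi + p[8] * ridge * (1.0 - gate)
        e = e + 0.5 * p[13] * y ** 2
        e = e + p[15] * np.where(x > p[14], (x - p[14]) ** 4, 0.0)
        e = e + p[15] * np.where(x < p[16], (p[16] - x) ** 4, 0.0)
        ay = np.abs(y)
        e = e + p[15] * np.where(ay > p[25], (ay - p[25]) ** 4, 0.0)
        if d.shape[1]:
            e = e + 0.5 * p[17] * np.sum(d ** 2, axis=1)
        if u is not None:
            s = 1.0 / (1.0 + np.exp(-(x - p[23]) / p[24]))
            upref = p[21] - p[22] * s
            e = e + 0.5 * p[20] * (u - upref) ** 2
        return e

    def _gradient(self, X: np.ndarray) -> np.ndarray:
        p = self._p()
        x, y, d, u = self._split(X)
        g = np.zeros_like(X)
        gb = np.exp(-((x - p[1]) ** 2 + (y - p[2]) ** 2) / (2 * p[3] ** 2))
        gi = np.exp(-((x - p[5]) ** 2 + (y - p[6]) ** 2) / (2 * p[7] ** 2))
        ridge = np.exp(-((x - p[9]) ** 2) / (2 * p[10] ** 2))
        gate = np.exp(-((y - p[11]) ** 2) / (2 * p[12] ** 2))
        # bound well
        g[:, 0] += p[0] * gb * (x - p[1]) / p[3] ** 2
        g[:, 1] += p[0] * gb * (y - p[2]) / p[3] ** 2
        # intermediate well
        g[:, 0] += p[4] * gi * (x - p[5]) / p[7] ** 2
        g[:, 1] += p[4] * gi * (y - p[6]) / p[7] ** 2
        # gated ridge
        g[:, 0] += -p[8] * (1.0 - gate) * ridge * (x - p[9]) / p[10] ** 2
        g[:, 1] += p[8] * ridge * gate * (y - p[11]) / p[12] ** 2
        # gate confinement + walls
        g[:, 1] += p[13] * y
        g[:, 0] += 4.0 * p[15] * np.where(x > p[14], (x - p[14]) ** 3, 0.0)
        g[:, 0] += -4.0 * p[15] * np.where(x < p[16], (p[16] - x) ** 3, 0.0)
        ay = np.abs(y)
        g[:, 1] += 4.0 * p[15] * np.sign(y) * np.where(ay > p[25], (ay - p[25]) ** 3, 0.0)
        nd = self.n_distractors
        if nd:
            g[:, 2:2 + nd] = p[17] * d
        if u is not None:
            s = 1.0 / (1.0 + np.exp(-(x - p[23]) / p[24]))
            upref = p[21] - p[22] * s
            dup_dx = -p[22] * s * (1.0 - s) / p[24]
            g[:, -1] += p[20] * (u - upref)
            g[:, 0] += -p[20] * (u - upref) * dup_dx
        return g


class CustomPolynomial(PotentialSurface):
    """1-D polynomial ``U(x) = sum_j c_j x^j`` (coefficients low -> high)."""

    def __init__(self, coefficients) -> None:
        c = np.asarray(coefficients, dtype=float)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("coefficients must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite polynomial coefficients")
        self.coefficients = c
        self.dim = 1
        self.kernel_code = KIND_POLYNOMIAL
        self.kernel_params = c.copy()
        self.start_position = np.zeros(1)
        self.box = np.array([[-5.0, 5.0]])

    def _energy(self, X: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(X[:, 0], self.coefficients)

    def _gradient(self, X: np.ndarray) -> np.ndarray:
        dc = np.polynomial.polynomial.polyder(self.coefficients)
        g = np.zeros_like(X)
        g[:, 0] = np.polynomial.polynomial.polyval(X[:, 0], dc)
        return g


def build_potential(spec: PotentialSpec) -> PotentialSurface:
    """Construct a :class:`PotentialSurface` from a :class:`PotentialSpec`.

    Raises
    ------
    ValueError
        For an unknown ``kind``, non-finite parameters, or parameters that
        violate the landscape invariants (non-positive barrier, wall inside
        the unbound threshold, ...).
    """
    if spec.kind not in _KINDS:
        raise ValueError(
            f"unknown potential kind {spec.kind!r}; expected one of {sorted(_KINDS)}"
        )
    _check_finite(spec.parameters)
    if spec.kind == "double_well":
        return DoubleWell(**spec.parameters)
    if spec.kind == "dissociation_funnel":
        return DissociationFunnel(**spec.parameters)
    return CustomPolynomial(**spec.parameters)
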