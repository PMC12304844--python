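"""Collective-variable definitions and extraction.

A :class:`CVDefinition` names a deterministic scalar function of particle
coordinates.  Extractors are small declarative specs so they can round-trip
through config files:

``("coord", i)``
    Coordinate ``i`` of the position vector.
``("linear", weights, offset)``
    ``weights . x + offset``; the biasable form (exact gradient is the
    weight vector), also the form a learned linear reaction coordinate
    compiles to.
``("distance", p, q)``
    Euclidean distance between two fixed points (a constant column; useful
    as a degenerate-distractor control).
``("noisy_copy", i, sigma, seed)``
    Coordinate ``i`` plus seeded Gaussian noise of scale ``sigma``; the
    standard uninformative-but-correlated distractor.

The ``informative`` flag is ground-truth metadata used only by tests and
the synthetic-data generator; nothing downstream reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory


@dataclass(frozen=True)
class CVDefinition:
    name: str
    extractor: tuple
    informative: bool = False

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        return extract(self.extractor, positions)

    def linear_weights(self, dim: int) -> np.ndarray:
        """Exact gradient w.r.t. positions for linear extractors.

        Raises ``ValueError`` for extractors that are not linear in the
        coordinates (only linear CVs can be biased directly).
        """
        kind = self.extractor[0]
        if kind == "coord":
            w = np.zeros(dim)
            w[int(self.extractor[1])] = 1.0
            return w
        if kind == "linear":
            w = np.asarray(self.extractor[1], dtype=float)
            if w.shape != (dim,):
                raise ValueError(f"linear CV {self.name!r} has weights of wrong length")
            return w
        raise ValueError(f"CV {self.name!r} ({kind}) is not linear; cannot be biased")


def extract(spec: tuple, positions: np.ndarray) -> np.ndarray:
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    kind = spec[0]
    if kind == "coord":
        i = int(spec[1])
        if i >= positions.shape[1]:
            raise ValueError(f"coord extractor index {i} out of range")
        return positions[:, i].copy()
    if kind == "linear":
        w = np.asarray(spec[1], dtype=float)
        offset = float(spec[2]) if len(spec) > 2 else 0.0
        return positions @ w + offset
    if kind == "distance":
        p = np.asarray(spec[1], dtype=float)
        q = np.asarray(spec[2], dtype=float)
        d = float(np.linalg.norm(p - q))
        return np.full(positions.shape[0], d)
    if kind == "noisy_copy":
        i = int(spec[1])
        sigma = float(spec[2])
        seed = int(spec[3])
        rng = np.random.default_rng(seed)
        return positions[:, i] + sigma * rng.standard_normal(positions.shape[0])
    raise ValueError(f"unknown CV extractor kind {kind!r}")


def compute_cvs(traj: Trajectory, defs: list[CVDefinition]) -> Trajectory:
    """Populate ``cv_matrix`` from positions, one column per definition.

    Column order follows ``defs``; an extractor failure reports the CV name
    and the first offending frame.
    """
    if not defs:
        raise ValueError("at least one CVDefinition is required")
    if traj.positions is None:
        raise ValueError("trajectory has no positions to extract CVs from")
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError(f"CV names must be unique, got {names}")
    cols = []
    for d in defs:
        try:
            col = d(traj.positions)
        except Exception as exc:
            raise ValueError(f"extractor for CV {d.name!r} failed: {exc}") from exc
        bad = ~np.isfinite(col)
        if bad.any():
            frame = int(np.argmax(bad))
            raise ValueError(f"CV {d.name!r} non-finite at frame {frame}")
        cols.append(col)
    return Trajectory(
        times=traj.times,
        cv_matrix=np.column_stack(cols),
        cv_names=names,
        positions=traj.positions,
        bias_energy=traj.bias_energy,
        seed=traj.seed,
        provenance=traj.provenance,
    )
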