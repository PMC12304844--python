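"""Named toy systems: the synthetic study conditions.

Each :class:`ToySystem` bundles a landscape, a CV roster, thermodynamic
context, integrator defaults and the bound-state definition.  The funnel
presets emulate the essential structure of a ligand--RNA dissociation
problem at desk scale:

* a metastable bound basin separated from an unbound plateau by a barrier
  (9 kT by default) far too high to cross unbiased in ~10^6 steps;
* an intermediate gating sub-state: the exit ridge has a gap only near a
  particular value of the gating coordinate, so productive dissociation
  passes through the intermediate (the analog of the ion acquiring an
  extra coordinating water before release);
* several named CVs of which only two are informative (exit distance and
  gate), the rest distractors;
* the cognate-ligand analog carries an internal extension mode whose
  preferred length contracts at the exit bottleneck.

The ligand library varies bound-well depth and gate geometry across toy
ligands (fixed, arbitrary variations standing in for chemistry) and maps
each to the experimentally measured dissociation constant of the compound
it is named after.  All runs use reduced units (k_B = 1, T = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cvs import CVDefinition
from .kinetics import BoundStateDef
from .langevin import LangevinParams, StopCondition
from .potentials import DissociationFunnel, DoubleWell, PotentialSurface
from .thermo import ThermoContext

#: default unbound cutoff on the exit coordinate (past the exit ridge)
EXIT_CUTOFF = 3.0
#: committed-exit requirement, in integrator steps
COMMIT_STEPS = 500


@dataclass
class ToySystem:
    """A named system: landscape + CV roster + simulation defaults."""

    name: str
    surface: PotentialSurface
    cv_defs: list[CVDefinition]
    thermo: ThermoContext = field(default_factory=ThermoContext)
    langevin: LangevinParams = field(default_factory=LangevinParams)
    bound: BoundStateDef = field(default_factory=lambda: BoundStateDef(
        cv_name="d_exit", cutoff=EXIT_CUTOFF, commit_frames=50))
    round1_cvs: tuple[str, str] = ("d_exit", "d_gate")

    def stop_condition(self) -> StopCondition:
        """Committed-exit stop on the bound-state CV (kernel form)."""
        d = [c for c in self.cv_defs if c.name == self.bound.cv_name]
        if not d:
            raise KeyError(f"system lacks bound-state CV {self.bound.cv_name!r}")
        return StopCondition(weights=d[0].linear_weights(self.surface.dim),
                             cutoff=self.bound.cutoff,
                             mode="above" if self.bound.bound_below else "below",
                             commit_steps=COMMIT_STEPS)


def _funnel_cvs(surface: DissociationFunnel) -> list[CVDefinition]:
    defs = [
        CVDefinition("d_exit", ("coord", 0), informative=True),
        CVDefinition("d_gate", ("coord", 1), informative=True),
    ]
    for i in range(surface.n_distractors):
        defs.append(CVDefinition(f"d_noise{i + 1}", ("coord", 2 + i)))
    return defs


def funnel_system(name: str = "toy26", **overrides) -> ToySystem:
    """A dissociation-funnel system; overrides go to the landscape."""
    surface = DissociationFunnel(**overrides)
    return ToySystem(name=name, surface=surface, cv_defs=_funnel_cvs(surface))


def double_well_system(name: str = "dw", barrier: float = 6.0,
                       n_distractors: int = 3) -> ToySystem:
    """1-D double well (plus distractors) with exit = reaching the far well.

    Used for the kinetics oracle (unbiased exits feasible at moderate
    barrier) and for SPIB identifiability (coordinate 0 is the single
    informative CV).
    """
    surface = DoubleWell(a=barrier, n_distractors=n_distractors)
    defs = [CVDefinition("d_exit", ("coord", 0), informative=True)]
    for i in range(n_distractors):
        defs.append(CVDefinition(f"d_noise{i + 1}", ("coord", 1 + i)))
    return ToySystem(
        name=name, surface=surface, cv_defs=defs,
        bound=BoundStateDef(cv_name="d_exit", cutoff=0.5, commit_frames=50),
    )


# toy-ligand landscape variations: fixed stand-ins for ligand chemistry.
# depths in kT; the cognate analog carries the internal contraction mode.
_LIGAND_VARIANTS: dict[str, dict] = {
    "toyZMP": dict(depth_bound=9.5, depth_inter=5.5, k_internal=4.0),
    "toy1": dict(depth_bound=9.0, depth_inter=5.0),
    "toy2": dict(depth_bound=8.0, depth_inter=4.5),
    "toy23": dict(depth_bound=8.8, depth_inter=5.0),
    "toy25": dict(depth_bound=8.7, depth_inter=4.8),
    "toy26": dict(depth_bound=9.0, depth_inter=5.0),
    "toy27": dict(depth_bound=8.5, depth_inter=5.2),
    "toy4p": dict(depth_bound=8.3, depth_inter=4.6),
}

#: experimental dissociation constants (ITC, mean +/- sd, micromolar) for
#: the compounds each toy ligand is named after; the 4-piperidinyl analog
#: has no tabulated value and exercises the missing-K_D reporting path.
_KD_UM: dict[str, tuple[float, float] | None] = {
    "toyZMP": (0.32, 0.13),
    "toy1": (0.6, 0.06),
    "toy2": (13.5, 7.85),
    "toy23": (0.778, 0.28),
    "toy25": (0.864, 0.21),
    "toy26": (1.46, 0.21),
    "toy27": (3.18, 0.44),
    "toy4p": None,
}

TRAINING_LIGAND = "toy26"


def ligand_library(names: list[str] | None = None) -> dict[str, ToySystem]:
    """The toy-ligand roster (all eight by default)."""
    names = names or list(_LIGAND_VARIANTS)
    out = {}
    for n in names:
        if n not in _LIGAND_VARIANTS:
            raise KeyError(f"unknown toy ligand {n!r}; have {list(_LIGAND_VARIANTS)}")
        out[n] = funnel_system(name=n, **_LIGAND_VARIANTS[n])
    return out


def kd_table(names: list[str] | None = None) -> pd.DataFrame:
    """Experimental K_D table (ligand, kd, kd_err, units) for the roster."""
    names = names or list(_KD_UM)
    rows = [dict(ligand=n, kd=_KD_UM[n][0], kd_err=_KD_UM[n][1], units="uM")
            for n in names if _KD_UM.get(n) is not None]
    return pd.DataFrame(rows)


def sigma_from_std(stds: np.ndarray, fraction: float) -> np.ndarray:
    """WT-MetaD hill widths as a fraction of CV/RC standard deviations.

    The protocol uses 0.75 x std of the unbiased run for round-1 CV biasing
    and 0.25 x the bound-state RC std for round-2 RC biasing.
    """
    stds = np.atleast_1d(np.asarray(stds, dtype=float))
    if np.any(stds <= 0):
        raise ValueError("cannot derive sigma from a zero standard deviation")
    return fraction * stds
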