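"""Thermodynamic context: temperature, inverse temperature and unit system.

Two unit systems are supported:

``reduced``
    Energies in units of :math:`k_B T_{ref}` with :math:`k_B = 1`; the toy
    presets use this system with ``temperature = 1``.
``kJ/mol``
    Energies in kJ/mol with temperature in kelvin
    (:math:`k_B = 0.0083144621` kJ/mol/K), matching typical biomolecular
    simulation settings such as T = 303.15 K and 1.5 kJ/mol hill heights.
"""

from __future__ import annotations

from dataclasses import dataclass

KB_KJ_PER_MOL_K = 0.0083144621

_UNIT_SYSTEMS = ("reduced", "kJ/mol")


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and derived inverse temperature for a simulation.

    Parameters
    ----------
    temperature : float
        Temperature in kelvin (``kJ/mol`` system) or in reduced units.
    units : str
        ``"reduced"`` (k_B = 1) or ``"kJ/mol"``.
    """

    temperature: float = 1.0
    units: str = "reduced"

    def __post_init__(self) -> None:
        if self.units not in _UNIT_SYSTEMS:
            raise ValueError(
                f"unknown unit system {self.units!r}; expected one of {_UNIT_SYSTEMS}"
            )
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")

    @property
    def kB(self) -> float:
        return 1.0 if self.units == "reduced" else KB_KJ_PER_MOL_K

    @property
    def kT(self) -> float:
        """Thermal energy k_B T in the context's energy units."""
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B T); always positive."""
        return 1.0 / self.kT
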