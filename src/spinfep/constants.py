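"""Physical constants and unit conventions.

The package works in a single fixed unit system throughout:

========  ======================
energy    kJ mol^-1
length    angstrom (Å)
mass      amu (g mol^-1)
time      fs
T         K
========  ======================

In these units 1 amu Å² fs^-2 equals 1.0e4 kJ mol^-1, which is what
:data:`ENERGY_PER_INTERNAL` encodes; the integrator works in internal
(amu, Å, fs) units and converts energies at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kJ mol^-1 K^-1 (CODATA molar gas constant / 1000).
KB: float = 0.00831446

#: kJ mol^-1 per (amu Å² fs^-2).
ENERGY_PER_INTERNAL: float = 1.0e4


@dataclass(frozen=True)
class PhysicalConstants:
    """Single source of truth for constants shared across modules."""

    k_B: float = KB

    @property
    def kT(self) -> float:  # pragma: no cover - trivial helper
        raise AttributeError("use k_B * T explicitly; no default temperature")


def kt(temperature: float) -> float:
    """k_B * T in kJ mol^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
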