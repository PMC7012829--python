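"""Closed-form thermodynamic and kinetic conversions.

Transition-state-theory dissociation rate (Eyring), the dissociation
constant / standard-free-energy relation, the standard-state volume, and
the linear elastic-strain estimate.  Constants are CODATA 2018; the default
temperature is 300 K (the simulation temperature).

The Eyring rate is applied here with the activation free energy set equal
to the magnitude of the standard binding free energy — an upper-bound-style
convention (no extra barrier beyond the binding free energy) that the
accompanying analyses also adopt; a ~30 kT binding free energy then maps to
k_off ≈ 0.6 s⁻¹ at 300 K.

Sign conventions: ``delta_G_standard`` is the (negative) binding free
energy.  K_d = C0·exp(ΔG°/kT) with C0 = 1 M, so stronger binding (more
negative ΔG°) gives smaller K_d.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    AVOGADRO,
    H_J_S,
    KB_J_PER_K,
    STANDARD_STATE_VOLUME_A3,
)
from .units import KT, Energy


def _as_kt(delta_g: Energy | float, temperature: float) -> float:
    if isinstance(delta_g, Energy):
        return delta_g.in_kt(temperature)
    return float(delta_g)


def eyring_koff(delta_g_activation: Energy | float, temperature: float = 300.0) -> float:
    """Transition-state-theory dissociation rate (1/s).

    k_off = (k_B T / h) · exp(-ΔG‡ / k_B T); a bare float is interpreted as
    kT units (use :class:`~pacsfe.units.Energy` for kcal/mol inputs).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg_kt = _as_kt(delta_g_activation, temperature)
    return (KB_J_PER_K * temperature / H_J_S) * math.exp(-dg_kt)


def kd_from_dg(delta_g_standard: Energy | float, temperature: float = 300.0) -> float:
    """Dissociation constant (molar): K_d = C0 · exp(ΔG°_bind / k_B T), C0 = 1 M."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(_as_kt(delta_g_standard, temperature))


def elastic_strain(pressure_mpa: float, youngs_modulus_gpa: float) -> float:
    """Linear elastic strain (dimensionless fraction) = pressure / modulus."""
    if youngs_modulus_gpa <= 0:
        raise ValueError("Young's modulus must be positive")
    return pressure_mpa / (youngs_modulus_gpa * 1000.0)


def standard_state_volume() -> float:
    """Volume per molecule at 1 M, in Å³ (≈ 1661 Å³ at display precision)."""
    return STANDARD_STATE_VOLUME_A3


def concentration_from_volume(volume_a3: float) -> float:
    """Molar concentration of one molecule per ``volume_a3`` (inverse of
    the standard-state volume: 1661 Å³ → 1.000 M)."""
    if volume_a3 <= 0:
        raise ValueError("volume must be positive")
    return 1e27 / (volume_a3 * AVOGADRO)


@dataclass(frozen=True)
class KineticsResult:
    """Bundle of the closed-form outputs, self-consistent by construction:
    K_d = C0 exp(ΔG°/kT) and k_off = (kT/h) exp(-ΔG°... magnitude /kT)."""

    delta_G_standard: Energy
    temperature: float
    k_off: float
    K_d: float
    C0: float = 1.0

    @classmethod
    def from_binding_free_energy(
        cls, delta_g_standard: Energy | float, temperature: float = 300.0
    ) -> "KineticsResult":
        if not isinstance(delta_g_standard, Energy):
            delta_g_standard = Energy(float(delta_g_standard), KT)
        dg_kt = delta_g_standard.in_kt(temperature)
        return cls(
            delta_G_standard=delta_g_standard,
            temperature=temperature,
            k_off=eyring_koff(abs(dg_kt), temperature),
            K_d=kd_from_dg(dg_kt, temperature),
        )

    def check_identities(self, rtol: float = 1e-12) -> None:
        dg_kt = self.delta_G_standard.in_kt(self.temperature)
        kd = self.C0 * math.exp(dg_kt)
        koff = (KB_J_PER_K * self.temperature / H_J_S) * math.exp(-abs(dg_kt))
        if not math.isclose(kd, self.K_d, rel_tol=rtol):
            raise AssertionError("K_d identity violated")
        if not math.isclose(koff, self.k_off, rel_tol=rtol):
            raise AssertionError("k_off identity violated")
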