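"""Model parameters: elastic, energetic, kinetic and environmental constants.

All free energies are expressed in units of kBT, positions in nm, rates in
s^-1 and concentrations in mM.  kBT itself is derived from the solution
temperature rather than fixed at the often-quoted ~4 pN nm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

#: Boltzmann constant, pN nm / K.
BOLTZMANN_PN_NM = 0.0138065

#: Actin helical (target-zone) repeat, nm.  One binding site per repeat.
SITE_SPACING_NM = 36.0


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


def kBT_from_temperature(temperature_C: float) -> float:
    """Thermal energy in pN nm at the given temperature in Celsius.

    Raises
    ------
    ParameterError
        If the temperature is at or below absolute zero.
    """
    if temperature_C <= -273.15:
        raise ParameterError(
            f"temperature {temperature_C} degC is at or below absolute zero"
        )
    return BOLTZMANN_PN_NM * (temperature_C + 273.15)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the seven-state cross-bridge model.

    Positions ``x1 >= x11 >= x2 >= x3`` are the free-energy minima of the
    attached states along the strain axis; the two power-stroke sub-strokes
    are ``d1 = x11 - x2`` and ``d2 = x2 - x3``.  Only differences of
    positions enter any rate or energy expression, so parameter sets are
    free to carry their own origin.
    """

    # --- elastic / structural -------------------------------------------
    k_s: float = 2.8          # cross-bridge stiffness, pN/nm
    x1: float = 7.2           # minimum of AMDP_PP, nm
    x11: float = 6.7          # minimum of AMDP_PiR and AMD_L, nm
    x2: float = 1.0           # minimum of AMD_H, nm
    x3: float = 0.0           # minimum of AM/AMD (rigor), nm
    x_crit: float = 0.6       # strain-sensitivity length of k2(x), nm

    # --- free-energy drops between successive minima, kBT ---------------
    dG_w: float = 0.0         # MDP -> weakly bound AMDP (lumped, kept for bookkeeping)
    dG_on: float = 0.7        # MDP -> AMDP_PP
    dG_PiR: float = 1.0       # AMDP_PP -> AMDP_PiR
    dG_LH: float = 14.0       # AMD_L -> AMD_H (main power stroke)
    dG_HD: float = 2.0        # AMD_H -> AM/AMD (second sub-stroke)
    dG_ATP_const: float = 13.1  # ATP hydrolysis free-energy offset, kBT

    # --- kinetic constants, s^-1 unless noted ---------------------------
    kon_prime: float = 130.0      # attachment prefactor
    kPr_prime: float = 3000.0     # entry into the Pi-release state
    kP_plus: float = 10000.0      # Pi release (strain-insensitive)
    kLH_minus: float = 2000.0     # power-stroke reversal
    kLH_plus_cap: float = 6000.0  # optional cap on the forward stroke (unused by default)
    k5_minus: float = 2000.0      # reversal of the second sub-stroke
    k2_zero: float = 2000.0       # ATP-induced detachment at zero rigor strain
    k6: float = 5000.0            # ADP dissociation
    k3_sum: float = 220.0         # k+3 + k-3, recovery stroke + hydrolysis
    K3: float = 10.0              # k+3 / k-3
    K1: float = 1.7               # MgATP binding to AM/AMD, mM^-1
    KC: float = 10.0              # Pi dissociation constant, mM

    # --- environment -----------------------------------------------------
    mgatp: float = 5.0        # [MgATP], mM
    pi: float = 0.5           # [Pi], mM
    mgadp: float = 0.0        # [MgADP], mM (fixed 0; AM/AMD -> MT irreversible)
    temperature_C: float = 30.0

    # --- numerical rate caps, s^-1 ---------------------------------------
    r_max_iso: float = 1.0e5
    r_max_shortening: float = 1.0e6
    r_min: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.k_s <= 0:
            raise ParameterError("cross-bridge stiffness k_s must be positive")
        for name in (
            "kon_prime", "kPr_prime", "kP_plus", "kLH_minus", "k5_minus",
            "k2_zero", "k6", "k3_sum", "r_max_iso", "r_max_shortening", "r_min",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"rate constant {name} must be positive")
        if self.K3 <= 0 or self.KC <= 0 or self.K1 <= 0:
            raise ParameterError("equilibrium constants K1, K3, KC must be positive")
        for name in ("mgatp", "pi", "mgadp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"concentration {name} must be non-negative")
        if not (self.x1 >= self.x11 >= self.x2 >= self.x3):
            raise ParameterError(
                "free-energy minima must be ordered x1 >= x11 >= x2 >= x3, got "
                f"({self.x1}, {self.x11}, {self.x2}, {self.x3})"
            )
        if self.temperature_C <= -273.15:
            raise ParameterError("temperature at or below absolute zero")
        if self.x_crit < 0:
            raise ParameterError("x_crit must be non-negative")

    # ------------------------------------------------------------------
    @property
    def kBT(self) -> float:
        """Thermal energy, pN nm."""
        return kBT_from_temperature(self.temperature_C)

    @property
    def d1(self) -> float:
        """First power-stroke sub-stroke amplitude, nm."""
        return self.x11 - self.x2

    @property
    def d2(self) -> float:
        """Second power-stroke sub-stroke amplitude, nm."""
        return self.x2 - self.x3

    @property
    def k3_plus(self) -> float:
        """Forward recovery-stroke + hydrolysis rate (MT -> MDP), s^-1."""
        return self.k3_sum * self.K3 / (1.0 + self.K3)

    @property
    def k3_minus(self) -> float:
        """Reverse recovery-stroke rate (MDP -> MT), s^-1."""
        return self.k3_sum / (1.0 + self.K3)

    def r_max(self, mode: str) -> float:
        """Rate cap for a run mode, ``'iso'`` or ``'shortening'``."""
        if mode == "iso":
            return self.r_max_iso
        if mode == "shortening":
            return self.r_max_shortening
        raise ValueError(f"unknown cap mode {mode!r} (expected 'iso' or 'shortening')")

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ParameterError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})
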