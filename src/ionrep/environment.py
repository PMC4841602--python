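"""Ionic environment and reversal-potential rules.

A single :class:`IonEnvironment` carries the intra/extracellular
concentrations of the four ions the model cares about plus the absolute
temperature.  Reversal rules are either a single-ion Nernst potential, a
fixed value, or a Goldman–Hodgkin–Katz (GHK) potential over a permeability
set that may include the divalent Ca2+ (solved from zero net GHK flux, so
the monovalent-only case reduces exactly to the familiar closed form).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .constants import BODY_TEMPERATURE, thermal_voltage


@dataclass(frozen=True)
class IonEnvironment:
    """Intra/extracellular ion concentrations (mM; Ca_i in nM) and T (K)."""

    na_i: float = 10.0
    na_o: float = 140.0
    k_i: float = 140.0
    k_o: float = 5.4
    ca_i: float = 100.0  # nM
    ca_o: float = 2.5
    # chloride follows the recording solutions (KCl-based internal solution),
    # putting E_Cl near 0 mV as in the whole-cell configuration modelled
    cl_i: float = 140.0
    cl_o: float = 142.7
    temperature: float = BODY_TEMPERATURE

    def __post_init__(self):
        for name in ("na_i", "na_o", "k_i", "k_o", "ca_i", "ca_o", "cl_i", "cl_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"concentration {name} must be positive")
        if not (273.0 <= self.temperature <= 320.0):
            raise ValueError("temperature outside [273, 320] K")

    @property
    def ca_i_mm(self) -> float:
        return self.ca_i * 1e-6

    def with_ca_i(self, ca_i_nm: float) -> "IonEnvironment":
        return replace(self, ca_i=ca_i_nm)

    def nernst(self, ion: str) -> float:
        """Nernst potential of ``ion`` in mV."""
        vt = thermal_voltage(self.temperature)
        if ion == "K":
            return vt * np.log(self.k_o / self.k_i)
        if ion == "Na":
            return vt * np.log(self.na_o / self.na_i)
        if ion == "Ca":
            return vt / 2.0 * np.log(self.ca_o / self.ca_i_mm)
        if ion == "Cl":
            return -vt * np.log(self.cl_o / self.cl_i)
        raise ValueError(f"unknown ion {ion!r}")

    def ghk_reversal(self, p_na: float = 0.0, p_k: float = 0.0,
                     p_ca: float = 0.0, p_cl: float = 0.0) -> float:
        """GHK reversal potential (mV) for the given relative permeabilities.

        Solved as the voltage at which the summed GHK flux over all permeant
        ions vanishes, which handles the divalent Ca2+ exactly.
        """
        if min(p_na, p_k, p_ca, p_cl) < 0:
            raise ValueError("permeabilities must be non-negative")
        if p_na + p_k + p_ca + p_cl == 0:
            raise ValueError("at least one permeability must be positive")
        vt = thermal_voltage(self.temperature)

        def flux(v: float) -> float:
            # GHK current for ion of valence z: z^2 u (ci - co e^{-z u}) / (1 - e^{-z u}),
            # u = V/vt; the singularity at u -> 0 is removable.
            u = v / vt
            total = 0.0
            for p, z, ci, co in (
                (p_na, 1, self.na_i, self.na_o),
                (p_k, 1, self.k_i, self.k_o),
                (p_cl, -1, self.cl_i, self.cl_o),
                (p_ca, 2, self.ca_i_mm, self.ca_o),
            ):
                if p == 0.0:
                    continue
                zu = z * u
                if abs(zu) < 1e-9:
                    drift = ci - co + (ci + co) * zu / 2.0
                    total += p * z * drift
                else:
                    e = np.exp(-zu)
                    total += p * z * zu * (ci - co * e) / (1.0 - e)
            return total

        return brentq(flux, -500.0, 500.0, xtol=1e-10)


#: Default environment used for all simulations (see docs/methods.md).
DEFAULT_ENVIRONMENT = IonEnvironment()
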