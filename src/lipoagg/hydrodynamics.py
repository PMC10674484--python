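"""Hydrodynamic size from steady-state fluorescence anisotropy.

For a fluorophore rigidly attached to a globular particle, the steady-state
anisotropy ``r``, the limit anisotropy ``r0`` and the fluorescence lifetime
``tau`` determine the rotational correlation time through the Perrin equation
for a spherical rotor::

    r0 / r = 1 + tau / sigma

The Stokes-Einstein-Debye relation then converts ``sigma`` into a
per-molecule hydrodynamic volume,

    Vh = sigma * R * T / (eta * N_A)

with solvent viscosity ``eta`` and temperature ``T``; the Avogadro division
turns the molar volume of the molar-form SED equation into the volume of a
single particle.  A sphere of that volume defines the hydrodynamic radius.

All public functions take explicit units: viscosity in cP, temperature in K,
times in ns, volumes in nm^3 per molecule, radii in Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

GAS_CONSTANT = 8.314        # J mol^-1 K^-1
AVOGADRO = 6.022e23         # mol^-1

__all__ = [
    "HydroConditions",
    "HydroResult",
    "anisotropy_from_intensities",
    "rotational_correlation_time",
    "hydrodynamic_volume",
    "radius_from_volume",
    "volume_from_radius",
    "hydro_chain",
    "hydro_table",
]


@dataclass(frozen=True)
class HydroConditions:
    """Solvent and photophysical conditions for the anisotropy chain.

    Parameters
    ----------
    viscosity_cP : float
        Solvent viscosity in centipoise (water at 298 K: 0.89 cP).
    temperature_K : float
        Absolute temperature.
    r0 : float
        Limit (fundamental) anisotropy of the fluorophore in the absence of
        rotational diffusion; 0.260 is the literature value for tryptophan
        excited at 295 nm.
    """

    viscosity_cP: float = 0.89
    temperature_K: float = 298.0
    r0: float = 0.260
    gas_constant: float = field(default=GAS_CONSTANT, repr=False)
    avogadro: float = field(default=AVOGADRO, repr=False)

    def __post_init__(self) -> None:
        if self.viscosity_cP <= 0:
            raise ValueError(f"viscosity_cP must be > 0, got {self.viscosity_cP}")
        if self.temperature_K <= 0:
            raise ValueError(f"temperature_K must be > 0, got {self.temperature_K}")
        if not 0 < self.r0 <= 0.4:
            raise ValueError(f"r0 must lie in (0, 0.4], got {self.r0}")


@dataclass(frozen=True)
class HydroResult:
    """Full output of the anisotropy -> hydrodynamic size chain."""

    r: float
    tau_ns: float
    sigma_ns: float
    Vh_nm3: float
    Rh_A: float
    Vh_err_nm3: Optional[float] = None
    Rh_err_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma_ns <= 0:
            raise ValueError("sigma must be positive")
        implied = volume_from_radius(self.Rh_A)
        if not math.isclose(implied, self.Vh_nm3, rel_tol=1e-9):
            raise ValueError("Vh and Rh are inconsistent with the sphere relation")


def anisotropy_from_intensities(Ivv: float, Ivh: float, g_factor: float = 1.0) -> float:
    """Steady-state anisotropy r = (Ivv - g*Ivh) / (Ivv + 2*g*Ivh).

    ``Ivv`` and ``Ivh`` are the emission intensities with excitation/emission
    polarizers vertical/vertical and vertical/horizontal; ``g_factor``
    corrects for the detection-path polarization bias (1 = no correction).
    """
    if Ivv < 0 or Ivh < 0:
        raise ValueError("intensities must be non-negative")
    if g_factor <= 0:
        raise ValueError(f"g_factor must be > 0, got {g_factor}")
    denom = Ivv + 2.0 * g_factor * Ivh
    if denom == 0:
        raise ValueError("both intensities are zero; anisotropy undefined")
    return (Ivv - g_factor * Ivh) / denom


def rotational_correlation_time(r: float, tau_ns: float, cond: HydroConditions) -> float:
    """Perrin spherical-rotor inversion: sigma = tau / (r0/r - 1), in ns."""
    if tau_ns <= 0:
        raise ValueError(f"tau must be > 0, got {tau_ns}")
    if r <= 0:
        raise ValueError(f"anisotropy must be > 0, got {r}")
    if r >= cond.r0:
        raise ValueError(
            f"anisotropy at or above limit value (r={r}, r0={cond.r0}): "
            "rotational correlation time undefined"
        )
    return tau_ns / (cond.r0 / r - 1.0)


def hydrodynamic_volume(sigma_ns: float, cond: HydroConditions) -> float:
    """Stokes-Einstein-Debye volume per molecule, in nm^3.

    Vh = sigma * R * T / (eta * N_A) with cP -> Pa s, ns -> s and
    m^3 -> nm^3 conversions handled internally.
    """
    if sigma_ns <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma_ns}")
    sigma_s = sigma_ns * 1e-9
    eta_Pas = cond.viscosity_cP * 1e-3
    vh_m3 = sigma_s * cond.gas_constant * cond.temperature_K / (eta_Pas * cond.avogadro)
    return vh_m3 * 1e27


def radius_from_volume(Vh_nm3: float) -> float:
    """Radius (Angstrom) of the sphere with volume ``Vh_nm3`` (nm^3)."""
    if Vh_nm3 <= 0:
        raise ValueError(f"volume must be > 0, got {Vh_nm3}")
    return 10.0 * (3.0 * Vh_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def volume_from_radius(Rh_A: float) -> float:
    """Volume (nm^3) of the sphere with radius ``Rh_A`` (Angstrom)."""
    if Rh_A <= 0:
        raise ValueError(f"radius must be > 0, got {Rh_A}")
    return (4.0 / 3.0) * math.pi * (Rh_A / 10.0) ** 3


def hydro_chain(
    r: float,
    tau_ns: float,
    cond: HydroConditions,
    r_err: Optional[float] = None,
) -> HydroResult:
    """Compose Perrin + SED + sphere inversion into one result.

    When ``r_err`` (the standard uncertainty on the anisotropy) is given,
    first-order (delta-method) uncertainties on Vh and Rh are propagated:
    d(sigma)/d(r) = tau * r0 / (r0 - r)^2, Vh is linear in sigma, and
    Rh scales as Vh^(1/3).
    """
    sigma = rotational_correlation_time(r, tau_ns, cond)
    vh = hydrodynamic_volume(sigma, cond)
    rh = radius_from_volume(vh)
    vh_err = rh_err = None
    if r_err is not None:
        dsigma_dr = tau_ns * cond.r0 / (cond.r0 - r) ** 2
        sigma_err = dsigma_dr * r_err
        vh_err = vh * sigma_err / sigma
        rh_err = rh * vh_err / (3.0 * vh)
    return HydroResult(r=r, tau_ns=tau_ns, sigma_ns=sigma, Vh_nm3=vh, Rh_A=rh,
                       Vh_err_nm3=vh_err, Rh_err_A=rh_err)


def hydro_table(table: pd.DataFrame, cond: HydroConditions) -> pd.DataFrame:
    """Apply the chain to a (concentration_uM, tau_ns, r) table.

    Returns a copy extended with sigma_ns, Vh_nm3 and Rh_A columns, one row
    per input row; an ``r_err`` column, if present, adds Vh_err_nm3/Rh_err_A.
    """
    required = {"tau_ns", "r"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    out = table.copy()
    results = [
        hydro_chain(row.r, row.tau_ns, cond,
                    r_err=getattr(row, "r_err", None))
        for row in table.itertuples()
    ]
    out["sigma_ns"] = [h.sigma_ns for h in results]
    out["Vh_nm3"] = [h.Vh_nm3 for h in results]
    out["Rh_A"] = [h.Rh_A for h in results]
    if "r_err" in table.columns:
        out["Vh_err_nm3"] = [h.Vh_err_nm3 for h in results]
        out["Rh_err_A"] = [h.Rh_err_A for h in results]
    return out
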