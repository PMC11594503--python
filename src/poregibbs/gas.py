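"""Headspace-equilibration gas conversions.

Converts headspace mixing ratios (ppm by volume) measured after vial
equilibration into porewater concentrations of H2 (nM), CH4 (mM), and DIC
(mM).  Hydrogen uses an equilibrium-saturation correlation (concentration of
dissolved H2 in equilibrium with 1 atm pure H2 as a function of temperature
and salinity); methane uses ideal-gas moles in the vial headspace normalized
to the porewater volume of the sediment plug; DIC reverses a dilution chain
and an extraction efficiency before the same ideal-gas step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import RangeError

__all__ = [
    "HeadspaceMeasurement",
    "h2_saturation_concentration",
    "h2_headspace_to_aqueous",
    "h2_aqueous_to_headspace",
    "ch4_aqueous_from_headspace",
    "ch4_headspace_from_aqueous",
    "dic_from_headspace",
    "undiluted_mixing_ratio",
    "R_L_ATM",
]

#: Gas constant, L atm mol-1 K-1.
R_L_ATM = 0.082057366080960

# Saturation correlation C(T,S) = C25 * exp(VANT_HOFF*(1/T - 1/298.15) - KS*S)
# in μM under 1 atm pure H2.  The van't Hoff slope is the standard Henry-law
# temperature dependence for H2; the 25 °C freshwater prefactor and the
# Setchenow salting-out coefficient are solved exactly from two seawater
# saturation anchors (671.8 μM at 24 °C/35 ‰; 704.9 μM at 28.5 °C/18.9 ‰),
# giving a freshwater 25 °C value of 785.5 μM (standard compilations: ~780).
H2_VANT_HOFF_K = 530.0
H2_C25_FRESH_UM = 785.5439794535548
H2_SETCHENOW_PER_PERMIL = 0.0046399436736952

_T_VALID_C = (-2.0, 40.0)
_S_VALID = (0.0, 40.0)


def h2_saturation_concentration(temperature: float, salinity: float) -> float:
    """Aqueous H2 saturation under 1 atm pure H2, in μM.

    Decreases with both temperature and salinity over the validity range
    (-2 to 40 °C, 0 to 40 ‰).
    """
    if not _T_VALID_C[0] < temperature < _T_VALID_C[1]:
        raise RangeError(f"temperature {temperature} °C outside ({_T_VALID_C[0]}, {_T_VALID_C[1]})")
    if not _S_VALID[0] <= salinity <= _S_VALID[1]:
        raise RangeError(f"salinity {salinity} ‰ outside {_S_VALID}")
    T = temperature + 273.15
    return H2_C25_FRESH_UM * math.exp(
        H2_VANT_HOFF_K * (1.0 / T - 1.0 / 298.15) - H2_SETCHENOW_PER_PERMIL * salinity
    )


def h2_headspace_to_aqueous(mixing_ratio_ppm: float, temperature: float, salinity: float) -> float:
    """Convert a headspace H2 mixing ratio (ppm) to aqueous H2 in nM.

    The headspace mixing ratio is read as the H2 partial pressure in
    fractions of 1 atm, so the aqueous concentration is that fraction of the
    1 atm saturation value: ppm * 1e-6 * C_sat(T, S), returned in nM.
    """
    if mixing_ratio_ppm < 0:
        raise RangeError("mixing ratio must be >= 0")
    sat_um = h2_saturation_concentration(temperature, salinity)
    return mixing_ratio_ppm * 1e-6 * sat_um * 1e3


def h2_aqueous_to_headspace(concentration_nm: float, temperature: float, salinity: float) -> float:
    """Inverse of :func:`h2_headspace_to_aqueous` (nM -> equivalent ppm)."""
    sat_um = h2_saturation_concentration(temperature, salinity)
    return concentration_nm / (sat_um * 1e3) * 1e6


@dataclass(frozen=True)
class HeadspaceMeasurement:
    """One equilibrated headspace measurement and its vial geometry.

    ``dilution_chain`` is an ordered list of (aliquot_mL, total_mL) steps
    applied to the headspace before analysis; the undiluted mixing ratio is
    the measured one multiplied by prod(total/aliquot).
    """

    analyte: Literal["H2", "CH4", "CO2"]
    mixing_ratio_ppm: float
    headspace_volume_ml: float
    sediment_volume_ml: float = 0.0
    porosity: float = 1.0
    temperature: float = 25.0
    dilution_chain: Sequence[tuple[float, float]] = field(default_factory=tuple)
    extraction_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.mixing_ratio_ppm < 0:
            raise RangeError("mixing ratio must be >= 0")
        if self.headspace_volume_ml <= 0:
            raise RangeError("headspace volume must be > 0")
        if not 0 < self.porosity <= 1:
            raise RangeError(f"porosity {self.porosity} outside (0, 1]")
        if not 0 < self.extraction_efficiency <= 1:
            raise RangeError("extraction efficiency must be in (0, 1]")
        for aliquot, total in self.dilution_chain:
            if not 0 < aliquot <= total:
                raise RangeError(f"invalid dilution step ({aliquot}, {total})")


def undiluted_mixing_ratio(measurement: HeadspaceMeasurement) -> float:
    """Undo the dilution chain: measured ppm * prod(total / aliquot)."""
    factor = 1.0
    for aliquot, total in measurement.dilution_chain:
        factor *= total / aliquot
    return measurement.mixing_ratio_ppm * factor


def _headspace_moles(ppm: float, headspace_volume_ml: float, temperature: float) -> float:
    # ideal gas: n = p V / (R T) with p = ppm * 1e-6 atm
    return ppm * 1e-6 * headspace_volume_ml * 1e-3 / (R_L_ATM * (temperature + 273.15))


def ch4_aqueous_from_headspace(measurement: HeadspaceMeasurement) -> float:
    """Aqueous CH4 (mM) from a killed-slurry headspace measurement.

    Ideal-gas moles in the vial headspace divided by the porewater volume of
    the sediment plug (porosity * sediment volume).  Any dissolved residual
    CH4 remaining in the slurry at equilibration is neglected.
    """
    if measurement.analyte != "CH4":
        raise ValueError(f"expected a CH4 measurement, got {measurement.analyte}")
    if measurement.sediment_volume_ml <= 0:
        raise RangeError("sediment volume must be > 0")
    ppm = undiluted_mixing_ratio(measurement)
    moles = _headspace_moles(ppm, measurement.headspace_volume_ml, measurement.temperature)
    porewater_l = measurement.porosity * measurement.sediment_volume_ml * 1e-3
    if porewater_l <= 0:
        raise RangeError("degenerate porewater volume")
    return moles / porewater_l * 1e3  # mol/L -> mM


def ch4_headspace_from_aqueous(
    concentration_mm: float,
    headspace_volume_ml: float,
    sediment_volume_ml: float,
    porosity: float,
    temperature: float,
) -> float:
    """Inverse of :func:`ch4_aqueous_from_headspace` (mM -> headspace ppm)."""
    porewater_l = porosity * sediment_volume_ml * 1e-3
    moles = concentration_mm * 1e-3 * porewater_l
    return moles * R_L_ATM * (temperature + 273.15) / (headspace_volume_ml * 1e-3) * 1e6


def dic_from_headspace(
    measurement: HeadspaceMeasurement,
    porewater_mass_g: float,
    porewater_density_g_per_ml: float = 1.025,
) -> float:
    """Porewater DIC (mM) from an acidified-sample CO2 headspace measurement.

    The measured mixing ratio is first corrected back through the dilution
    chain, converted to moles over the vial headspace, divided by the
    extraction efficiency (fraction of sample CO2 driven into the
    headspace), and normalized by the porewater volume implied by its mass
    and density.
    """
    if measurement.analyte != "CO2":
        raise ValueError(f"expected a CO2 measurement, got {measurement.analyte}")
    if porewater_mass_g <= 0:
        raise RangeError("porewater mass must be > 0")
    ppm = undiluted_mixing_ratio(measurement)
    moles = _headspace_moles(ppm, measurement.headspace_volume_ml, measurement.temperature)
    moles /= measurement.extraction_efficiency
    porewater_l = porewater_mass_g / porewater_density_g_per_ml * 1e-3
    return moles / porewater_l * 1e3
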