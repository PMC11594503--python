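"""Aqueous thermodynamics for porewater catabolic reactions.

Standard-state Gibbs energies at in-situ temperature, extended Debye-Hückel
(B-dot) activity coefficients, carbonate-system speciation, and the Gibbs
energy of reaction

    dG_r = dG°_r + R T ln Q_r,   Q_r = prod_i a_i^nu_i,

evaluated per mole of reaction turnover.  The two built-in reactions are
hydrogenotrophic methanogenesis (HCO3- + 4 H2 + H+ -> CH4 + 3 H2O), whose
reverse is sulfate-coupled anaerobic methane oxidation, and hydrogenotrophic
sulfate reduction (SO4-- + 4 H2 + H+ -> HS- + 4 H2O).

Standard-state data are a bundled SUPCRT92-consistent table of dG°_f and S°
at 25 °C / 1 atm for the nine species involved; temperature correction uses
a constant reaction entropy, which is accurate to well under 1 kJ/mol over
the 0-40 °C range this package targets.  Pressure is treated as 1 atm
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import MissingSpeciesError, RangeError

__all__ = [
    "SpeciesProperties",
    "Reaction",
    "SiteConditions",
    "species_table",
    "METHANOGENESIS",
    "SULFATE_REDUCTION",
    "STANDARD_DG_ANCHORS",
    "HCO3_ION_SIZE_ANGSTROM",
    "standard_gibbs_reaction",
    "activity_coefficient",
    "carbonate_speciation",
    "seawater_carbonate_constants",
    "freshwater_carbonate_constants",
    "gibbs_energy",
    "R_KJ",
]

#: Gas constant, kJ mol-1 K-1.
R_KJ = 8.31446261815324e-3

T_REF_K = 298.15
TEMPERATURE_RANGE_C = (-2.0, 40.0)
SALINITY_RANGE = (0.0, 40.0)

#: Ion-size parameter for HCO3- (Å), calibrated once so that the monovalent
#: B-dot activity coefficient at I = 0.7 M, 24 °C equals 0.661.
HCO3_ION_SIZE_ANGSTROM = 3.787

#: Standard-state anchors for hydrogenotrophic methanogenesis reported for
#: the two study sites (kJ/mol at 1 atm).  The 24 °C value is reproduced by
#: :func:`standard_gibbs_reaction` from the bundled table; the 28.5 °C value
#: is not consistent with any constant-entropy extrapolation of the 24 °C
#: one and is therefore shipped only as a usable override constant.
STANDARD_DG_ANCHORS = {
    ("methanogenesis", 24.0): -229.59,
    ("methanogenesis", 28.5): -238.98,
}


@dataclass(frozen=True)
class SpeciesProperties:
    """Standard-state constants for one aqueous species.

    Parameters
    ----------
    name : str
        Species identifier as used in reaction stoichiometries.
    charge : int
        Formal charge z.
    dG_formation_ref : float
        Standard Gibbs energy of formation at 25 °C, 1 atm (kJ/mol).
    S_ref : float
        Standard molal entropy at 25 °C (J mol-1 K-1).
    ion_size : float or None
        Extended Debye-Hückel å parameter (Å); ``None`` for neutral species.
    elements : mapping
        Element counts (C, H, O, S) used for balance checks.
    """

    name: str
    charge: int
    dG_formation_ref: float
    S_ref: float
    ion_size: float | None
    elements: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge not in (-2, -1, 0, 1):
            raise ValueError(f"unsupported charge {self.charge} for {self.name}")
        if self.charge != 0 and (self.ion_size is None or self.ion_size <= 0):
            raise ValueError(f"charged species {self.name} requires ion_size > 0")


def _load_species() -> dict[str, SpeciesProperties]:
    with resources.files("poregibbs.data").joinpath("species.csv").open() as fh:
        raw = pd.read_csv(fh)
    out: dict[str, SpeciesProperties] = {}
    for row in raw.itertuples(index=False):
        if row.name in out:
            raise ValueError(f"duplicate species {row.name} in bundled table")
        out[row.name] = SpeciesProperties(
            name=row.name,
            charge=int(row.charge),
            dG_formation_ref=float(row.dG_f_kJ_mol),
            S_ref=float(row.S_J_mol_K),
            ion_size=None if pd.isna(row.ion_size_A) else float(row.ion_size_A),
            elements={"C": int(row.C), "H": int(row.H), "O": int(row.O), "S": int(row.S_atoms)},
        )
    return out


_SPECIES: dict[str, SpeciesProperties] | None = None


def species_table() -> dict[str, SpeciesProperties]:
    """Return the bundled nine-species property table (cached)."""
    global _SPECIES
    if _SPECIES is None:
        _SPECIES = _load_species()
    return _SPECIES


@dataclass(frozen=True)
class Reaction:
    """A named stoichiometric map, products positive and reactants negative.

    Charge and C/H/O/S element balance are verified at construction against
    the bundled species table.
    """

    name: str
    stoichiometry: Mapping[str, float]

    def __post_init__(self) -> None:
        table = species_table()
        if not self.stoichiometry or all(v == 0 for v in self.stoichiometry.values()):
            raise ValueError(f"reaction {self.name} has empty stoichiometry")
        unknown = [s for s in self.stoichiometry if s not in table]
        if unknown:
            raise MissingSpeciesError(f"unknown species in {self.name}: {unknown}")
        charge = sum(nu * table[s].charge for s, nu in self.stoichiometry.items())
        if abs(charge) > 1e-9:
            raise ValueError(f"reaction {self.name} is not charge balanced ({charge:+g})")
        for el in ("C", "H", "O", "S"):
            bal = sum(nu * table[s].elements.get(el, 0) for s, nu in self.stoichiometry.items())
            if abs(bal) > 1e-9:
                raise ValueError(f"reaction {self.name} does not balance {el} ({bal:+g})")

    def reversed(self) -> "Reaction":
        return Reaction(
            name=f"{self.name}_reversed",
            stoichiometry={s: -nu for s, nu in self.stoichiometry.items()},
        )


#: HCO3- + 4 H2(aq) + H+ -> CH4(aq) + 3 H2O
METHANOGENESIS = Reaction(
    "methanogenesis",
    {"HCO3-": -1, "H2(aq)": -4, "H+": -1, "CH4(aq)": 1, "H2O": 3},
)

#: SO4-- + 4 H2(aq) + H+ -> HS- + 4 H2O
SULFATE_REDUCTION = Reaction(
    "sulfate_reduction",
    {"SO4--": -1, "H2(aq)": -4, "H+": -1, "HS-": 1, "H2O": 4},
)

BUILTIN_REACTIONS = {r.name: r for r in (METHANOGENESIS, SULFATE_REDUCTION)}


@dataclass(frozen=True)
class SiteConditions:
    """In-situ conditions and energetic thresholds for one site."""

    temperature: float  # °C
    salinity: float  # ‰
    pressure: float = 1.0  # atm (informational; no pressure correction applied)
    pH: float = 7.0
    ionic_strength: float = 0.7  # mol/L
    dG_min_methanogenesis: float = -10.0  # kJ/mol; 0 disables the threshold
    dG_min_sulfate_reduction: float = -19.1  # kJ/mol

    def __post_init__(self) -> None:
        lo, hi = TEMPERATURE_RANGE_C
        if not lo < self.temperature < hi:
            raise RangeError(f"temperature {self.temperature} °C outside ({lo}, {hi})")
        if not SALINITY_RANGE[0] <= self.salinity <= SALINITY_RANGE[1]:
            raise RangeError(f"salinity {self.salinity} ‰ outside {SALINITY_RANGE}")
        if self.ionic_strength <= 0:
            raise RangeError("ionic_strength must be > 0")
        if not 0 < self.pH < 14:
            raise RangeError(f"pH {self.pH} outside (0, 14)")


def _check_temperature(temperature: float) -> None:
    lo, hi = TEMPERATURE_RANGE_C
    if not lo < temperature < hi:
        raise RangeError(f"temperature {temperature} °C outside ({lo}, {hi})")


def standard_gibbs_reaction(reaction: Reaction, temperature: float) -> float:
    """Standard-state Gibbs energy of reaction at ``temperature`` (kJ/mol).

    Computed as sum(nu_i dG°_f,i) at 25 °C corrected by the constant reaction
    entropy: dG°_r(T) = dG°_r(Tref) - dS°_r (T - Tref).
    """
    _check_temperature(temperature)
    table = species_table()
    missing = [s for s in reaction.stoichiometry if s not in table]
    if missing:
        raise MissingSpeciesError(f"no thermodynamic data for {missing}")
    dG_ref = sum(nu * table[s].dG_formation_ref for s, nu in reaction.stoichiometry.items())
    dS = sum(nu * table[s].S_ref for s, nu in reaction.stoichiometry.items())  # J/K
    return dG_ref - dS * 1e-3 * (temperature + 273.15 - T_REF_K)


# Debye-Hückel limiting-law parameters for water, 0-40 °C.
_DH_T = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0])
_DH_A = np.array([0.4913, 0.4943, 0.4976, 0.5012, 0.5050, 0.5092, 0.5135, 0.5182, 0.5231])
_DH_B = np.array([0.3247, 0.3254, 0.3261, 0.3268, 0.3276, 0.3283, 0.3291, 0.3299, 0.3307])
B_DOT = 0.041

_DEFAULT_ION_SIZE = {0: None, 1: HCO3_ION_SIZE_ANGSTROM, 2: 4.0}


def activity_coefficient(
    charge: int,
    ionic_strength: float,
    temperature: float,
    ion_size: float | None = None,
) -> float:
    """Extended Debye-Hückel (B-dot) activity coefficient.

    log10 gamma = -A z^2 sqrt(I) / (1 + B å sqrt(I)) + Bdot I for charged
    species; neutral species are assigned gamma = 1 (dissolved CH4 and H2 are
    treated as ideal).  ``ion_size`` defaults to the calibrated HCO3- value
    for |z| = 1 and 4.0 Å for |z| = 2.
    """
    if ionic_strength < 0:
        raise RangeError("ionic strength must be >= 0")
    _check_temperature(temperature)
    if charge == 0:
        return 1.0
    if ion_size is None:
        ion_size = _DEFAULT_ION_SIZE[abs(charge)]
    A = float(np.interp(temperature, _DH_T, _DH_A))
    B = float(np.interp(temperature, _DH_T, _DH_B))
    sqrt_i = math.sqrt(ionic_strength)
    log_g = -A * charge * charge * sqrt_i / (1.0 + B * ion_size * sqrt_i) + B_DOT * ionic_strength
    return 10.0**log_g


def seawater_carbonate_constants(temperature: float, salinity: float) -> tuple[float, float]:
    """(pK1, pK2) of the seawater carbonate system (total-proton scale).

    Lueker, Dickson & Keeling (2000)-form fit; nominal validity S 19-43,
    T 2-35 °C, used here as the seawater branch and extrapolated smoothly
    into brackish salinities.
    """
    T = temperature + 273.15
    pK1 = (
        3633.86 / T - 61.2172 + 9.6777 * math.log(T)
        - 0.011555 * salinity + 0.0001152 * salinity**2
    )
    pK2 = (
        471.78 / T + 25.929 - 3.16967 * math.log(T)
        - 0.01781 * salinity + 0.0001122 * salinity**2
    )
    return pK1, pK2


def freshwater_carbonate_constants(temperature: float, salinity: float = 0.0) -> tuple[float, float]:
    """(pK1, pK2) for fresh water (Plummer & Busenberg 1982-form fits)."""
    T = temperature + 273.15
    log10T = math.log10(T)
    logK1 = -356.3094 - 0.06091964 * T + 21834.37 / T + 126.8339 * log10T - 1684915.0 / T**2
    logK2 = -107.8871 - 0.03252849 * T + 5151.79 / T + 38.92561 * log10T - 563713.9 / T**2
    return -logK1, -logK2


def carbonate_speciation(
    pH: float,
    temperature: float,
    salinity: float,
    constants: Callable[[float, float], tuple[float, float]] | tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """Fractions (f_CO2, f_HCO3, f_CO3) of dissolved inorganic carbon.

    ``constants`` may be a (pK1, pK2) pair or a callable ``(T, S) -> (pK1,
    pK2)``; by default the seawater parameterization is used for S > 0.5 ‰
    and the freshwater one below.
    """
    if not 0 < pH < 14:
        raise RangeError(f"pH {pH} outside (0, 14)")
    if not SALINITY_RANGE[0] <= salinity <= SALINITY_RANGE[1]:
        raise RangeError(f"salinity {salinity} ‰ outside {SALINITY_RANGE}")
    _check_temperature(temperature)
    if constants is None:
        constants = seawater_carbonate_constants if salinity > 0.5 else freshwater_carbonate_constants
    pK1, pK2 = constants(temperature, salinity) if callable(constants) else constants
    f_hco3 = 1.0 / (1.0 + 10.0 ** (pK1 - pH) + 10.0 ** (pH - pK2))
    f_co2 = f_hco3 * 10.0 ** (pK1 - pH)
    f_co3 = f_hco3 * 10.0 ** (pH - pK2)
    total = f_co2 + f_hco3 + f_co3
    return f_co2 / total, f_hco3 / total, f_co3 / total


def gibbs_energy(
    reaction: Reaction,
    dG_standard: float,
    activities: Mapping[str, float],
    temperature: float,
) -> float:
    """In-situ Gibbs energy of reaction, dG_r = dG°_r + R T ln Q_r (kJ/mol).

    Water activity defaults to 1 if absent from ``activities``; every other
    reaction species must have a strictly positive activity.
    """
    _check_temperature(temperature)
    ln_q = 0.0
    for species, nu in reaction.stoichiometry.items():
        if species == "H2O" and species not in activities:
            a = 1.0
        else:
            a = activities.get(species)
            if a is None:
                raise MissingSpeciesError(f"no activity supplied for {species}")
            if a <= 0:
                raise RangeError(f"non-positive activity for {species}: {a}")
        ln_q += nu * math.log(a)
    return dG_standard + R_KJ * (temperature + 273.15) * ln_q
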