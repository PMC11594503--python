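"""Proton-motive-force energetics and ATP-yield arithmetic.

Quantifies how far a small catabolic energy budget can go when it is spent
on pumping protons across an energy-transducing membrane: the energetic
cost of moving one mole of protons against the electrochemical gradient,
the moles of protons a given budget can translocate, and the equivalent
ATP yield at a given phosphorylation cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import RangeError
from .thermo import R_KJ

__all__ = [
    "FARADAY_KJ_PER_V_MOL",
    "AVOGADRO",
    "MembraneState",
    "pmf_energy_per_proton",
    "protons_translocatable",
    "atp_yield",
]

#: Faraday constant expressed in kJ V-1 mol-1.
FARADAY_KJ_PER_V_MOL = 96.48533212
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class MembraneState:
    """Membrane potential, pH gradient, temperature, and ATP cost.

    ``delta_psi`` in mV, ``delta_pH`` dimensionless (inside minus outside;
    negative when the outside is more acidic), ``dG_ATP`` in kJ per mol ATP.
    """

    delta_psi_mv: float = 120.0
    delta_ph: float = -0.5
    temperature: float = 25.0
    dG_ATP: float = 60.0

    def __post_init__(self) -> None:
        if self.dG_ATP <= 0:
            raise RangeError("dG_ATP must be > 0")
        if abs(self.delta_psi_mv) >= 500:
            raise RangeError("|delta_psi| must be < 500 mV")


def pmf_energy_per_proton(state: MembraneState) -> float:
    """Energetic cost of translocating one mole of protons (kJ/mol H+).

    Both gradient components are taken as magnitudes of a gradient that
    resists proton export:

        dG_pmf = F |dPsi| + 2.303 R T |dpH|

    which gives 14.43 kJ/mol H+ for 120 mV and 0.5 pH units at 25 °C.
    Positive whenever either gradient component is nonzero.
    """
    T = state.temperature + 273.15
    electrical = FARADAY_KJ_PER_V_MOL * abs(state.delta_psi_mv) * 1e-3
    chemical = 2.303 * R_KJ * T * abs(state.delta_ph)
    return electrical + chemical


def protons_translocatable(
    energy_budget: float,
    state: MembraneState,
    convention: Literal["magnitude", "literal"] = "magnitude",
) -> tuple[float, float]:
    """Moles of protons a reaction energy budget can translocate.

    Returns ``(mol H+ per mol reaction, protons per mol reaction)``; the
    proton count is the mole number times Avogadro's constant.

    Under the default ``magnitude`` convention the budget is divided by the
    per-proton cost F |dPsi| + 2.303 R T |dpH| (0.693 mol for 10 kJ under
    the 120 mV / -0.5 pH / 25 °C state).  The ``literal`` convention solves
    budget = n F dPsi - 2.303 R T dpH for n, i.e. treats the pH term as a
    per-reaction rather than per-proton quantity — the other reading
    admitted by the sign/grouping ambiguity of the defining expression
    (0.617 mol for the same inputs).
    """
    if energy_budget <= 0:
        raise RangeError("energy budget must be > 0")
    T = state.temperature + 273.15
    if convention == "magnitude":
        per_proton = pmf_energy_per_proton(state)
        if per_proton <= 0:
            raise ZeroDivisionError("per-proton energy is not positive")
        n = energy_budget / per_proton
    elif convention == "literal":
        electrical = FARADAY_KJ_PER_V_MOL * state.delta_psi_mv * 1e-3
        if electrical == 0:
            raise ZeroDivisionError("per-proton electrical energy is zero")
        n = (energy_budget + 2.303 * R_KJ * T * state.delta_ph) / electrical
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return n, n * AVOGADRO


def atp_yield(energy_budget: float, dG_ATP: float) -> float:
    """Mol ATP per mol reaction: energy budget / phosphorylation cost."""
    if dG_ATP <= 0:
        raise RangeError("dG_ATP must be > 0")
    if energy_budget < 0:
        raise RangeError("energy budget must be >= 0")
    return energy_budget / dG_ATP
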