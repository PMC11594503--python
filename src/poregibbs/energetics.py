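"""Per-depth Gibbs-energy profiles and exergonic-direction classification.

For each depth of a core this stage assembles species activities from the
measured concentrations (hydrogen in nM, methane in mM, DIC split into a
bicarbonate activity through carbonate speciation, sulfate and sulfide in
mM; the proton activity from the site pH; water at unit activity), then
evaluates dG_r = dG°_r + R T ln Q_r for the requested reaction.  Positive
values for the methanogenesis reaction mean its reverse — sulfate-coupled
anaerobic methane oxidation — is the exergonic direction.

Gap handling follows the measurement convention for DIC: a missing DIC
value is filled with the mean of the depths immediately above and below;
depths whose gaps cannot be filled are omitted and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .profiles import CoreDataset, DepthProfile
from .thermo import (
    METHANOGENESIS,
    Reaction,
    activity_coefficient,
    carbonate_speciation,
    gibbs_energy,
    species_table,
    standard_gibbs_reaction,
)

__all__ = ["EnergeticsResult", "depth_profile_gibbs", "classify_direction"]

# which measured profile feeds which reaction species, and its unit scale
# to mol/L
_SPECIES_SOURCES = {
    "H2(aq)": ("h2_nM", 1e-9),
    "CH4(aq)": ("ch4_mM", 1e-3),
    "HCO3-": ("dic_mM", 1e-3),
    "SO4--": ("so4_mM", 1e-3),
    "HS-": ("sulfide_mM", 1e-3),
}


@dataclass(frozen=True)
class EnergeticsResult:
    depth_cm: float
    reaction: str
    dG_kJ_mol: float
    direction: str
    activities: Mapping[str, float]
    gap_filled: tuple[str, ...] = ()


def classify_direction(dG_r: float, dG_min: float = 0.0) -> str:
    """Classify the exergonic direction of a reaction against a threshold.

    With ``dG_min = 0`` classification is by sign alone; with a negative
    ``dG_min``, magnitudes smaller than |dG_min| are reported as
    sub-threshold in the corresponding direction.  Exactly zero is
    ``equilibrium``.
    """
    if dG_min > 0:
        raise ValueError("dG_min must be <= 0")
    if dG_r == 0:
        return "equilibrium"
    if dG_r < 0:
        return "forward_exergonic" if dG_r <= dG_min else "sub_threshold_forward"
    return "reverse_exergonic" if dG_r >= -dG_min else "sub_threshold_reverse"


def _fill_gaps(depths: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill isolated NaNs with the mean of the adjacent depths."""
    filled = values.copy()
    flags = np.zeros(len(values), dtype=bool)
    for i in range(len(values)):
        if np.isnan(values[i]) and 0 < i < len(values) - 1:
            above, below = values[i - 1], values[i + 1]
            if not (np.isnan(above) or np.isnan(below)):
                filled[i] = 0.5 * (above + below)
                flags[i] = True
    return filled, flags


def _aligned_values(
    profile: DepthProfile,
    grid: np.ndarray,
    tolerance: float,
    reduce: str,
) -> np.ndarray:
    """Nearest-depth match of a profile onto ``grid`` within ``tolerance``."""
    prof = profile.reduce_replicates(reduce) if "replicate" in profile.data.columns else profile
    depths, values = prof.depths, prof.values
    out = np.full(len(grid), np.nan)
    if len(depths) == 0:
        return out
    idx = np.searchsorted(depths, grid)
    for k, z in enumerate(grid):
        candidates = [j for j in (idx[k] - 1, idx[k]) if 0 <= j < len(depths)]
        j = min(candidates, key=lambda j: abs(depths[j] - z))
        if abs(depths[j] - z) <= tolerance:
            out[k] = values[j]
    return out


def depth_profile_gibbs(
    core: CoreDataset,
    reaction: Reaction = METHANOGENESIS,
    dG_standard: float | None = None,
    dG_min: float | None = None,
    replicate_reduce: str = "mean",
    alignment_tolerance: float | None = None,
) -> list[EnergeticsResult]:
    """Gibbs-energy profile of ``reaction`` over the depths of a core.

    The hydrogen profile defines the output depth grid (replicate
    triplicates reduced by ``replicate_reduce``); other variables are
    matched by nearest depth within ``alignment_tolerance`` (default: half
    the coarsest grid spacing).  ``dG_standard`` overrides the table-derived
    standard-state value, e.g. with a site-reported anchor.  ``dG_min``
    defaults to the site's methanogenesis or sulfate-reduction threshold
    depending on the reaction; pass 0 to classify by sign alone.

    Depths with non-positive concentrations are skipped with a warning;
    depths with unfillable DIC gaps are omitted.
    """
    site = core.site
    needed = [s for s in reaction.stoichiometry if s in _SPECIES_SOURCES]
    for s in needed:
        var = _SPECIES_SOURCES[s][0]
        if var not in core.profiles:
            raise ConfigurationError(f"reaction {reaction.name} requires profile '{var}'")
    if "h2_nM" not in core.profiles:
        raise ConfigurationError("energetics requires a hydrogen profile")
    h2 = core.profiles["h2_nM"].reduce_replicates(replicate_reduce)
    grid = h2.depths

    if alignment_tolerance is None:
        spacings = []
        for s in needed:
            d = core.profiles[_SPECIES_SOURCES[s][0]].reduce_replicates(replicate_reduce).depths
            if len(d) > 1:
                spacings.append(np.median(np.diff(d)))
        alignment_tolerance = max(spacings) / 2.0 if spacings else 0.0

    aligned: dict[str, np.ndarray] = {}
    gap_flags: dict[str, np.ndarray] = {}
    for s in needed:
        var, _scale = _SPECIES_SOURCES[s]
        vals = _aligned_values(core.profiles[var], grid, alignment_tolerance, replicate_reduce)
        if var == "dic_mM":
            vals, flags = _fill_gaps(grid, vals)
            gap_flags[s] = flags
        aligned[s] = vals

    if dG_standard is None:
        dG_standard = standard_gibbs_reaction(reaction, site.temperature)
    if dG_min is None:
        dG_min = (
            site.dG_min_methanogenesis
            if reaction.name.startswith("methanogenesis")
            else site.dG_min_sulfate_reduction
        )

    table = species_table()
    _, f_hco3, _ = carbonate_speciation(site.pH, site.temperature, site.salinity)
    gammas = {
        s: activity_coefficient(
            table[s].charge, site.ionic_strength, site.temperature, table[s].ion_size
        )
        for s in needed
    }

    results: list[EnergeticsResult] = []
    for k, depth in enumerate(grid):
        if any(np.isnan(aligned[s][k]) for s in needed):
            continue  # unfillable gap: depth omitted
        activities = {"H+": 10.0 ** (-site.pH), "H2O": 1.0}
        bad = False
        for s in needed:
            conc = aligned[s][k] * _SPECIES_SOURCES[s][1]
            if s == "HCO3-":
                conc *= f_hco3  # bicarbonate share of measured DIC
            if conc <= 0:
                warnings.warn(
                    f"non-positive concentration for {s} at {depth} cm; depth skipped",
                    stacklevel=2,
                )
                bad = True
                break
            activities[s] = conc * gammas[s]
        if bad:
            continue
        dg = gibbs_energy(reaction, dG_standard, activities, site.temperature)
        filled = tuple(s for s in needed if gap_flags.get(s) is not None and gap_flags[s][k])
        results.append(
            EnergeticsResult(
                depth_cm=float(depth),
                reaction=reaction.name,
                dG_kJ_mol=dg,
                direction=classify_direction(dg, dG_min),
                activities=activities,
                gap_filled=filled,
            )
        )
    return results
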