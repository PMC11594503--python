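"""Seeded synthetic-core generator with known ground truth.

Generates downcore porewater datasets that emulate the two canonical
end-member settings of coastal anoxic sediments:

* an organic-rich bight-type site ("organic_rich_CLB_like"): sulfate held
  near-constant through a bioirrigated upper layer, then declining to
  depletion; DIC rising at roughly twice the sulfate drawdown (organoclastic
  sulfate reduction); methane rising linearly with no net removal; hydrogen
  elevated and variable near the surface, lower below;
* an organic-poor estuary-type site ("organic_poor_WOR_like"): sulfate
  declining from the surface; DIC rising at roughly 1:1 with sulfate
  drawdown (methane-fueled sulfate reduction); a concave-up methane profile
  shaped by anaerobic methane oxidation; hydrogen tightly controlled and
  nearly invariant in the upper zone, released to higher, more variable
  values at depth.

Every generated core is paired with an immutable :class:`GroundTruth`
recording the parameters the analysis stages are expected to recover.
DIC is generated from the *realized* (noisy) sulfate drawdown, so in the
noiseless limit dDIC(z) = slope x |dSO4(z)| holds exactly at every depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import CoreDataset, DepthProfile, water_content_from_porosity
from .thermo import SiteConditions

__all__ = [
    "HydrogenZone",
    "SyntheticTemplate",
    "GroundTruth",
    "generate_core",
    "template_library",
]


@dataclass(frozen=True)
class HydrogenZone:
    """One depth zone of the hydrogen profile, [top_cm, bottom_cm)."""

    top_cm: float
    bottom_cm: float
    mean_nM: float
    variance_nM2: float
    distribution: str = "lognormal"  # or "truncated_normal"

    def __post_init__(self) -> None:
        if self.bottom_cm <= self.top_cm:
            raise ValueError("zone bottom must exceed top")
        if self.variance_nM2 < 0:
            raise ValueError("zone variance must be >= 0")
        if self.mean_nM <= 0:
            raise ValueError("zone mean must be > 0")
        if self.distribution not in ("lognormal", "truncated_normal"):
            raise ValueError(f"unknown hydrogen distribution {self.distribution}")


@dataclass(frozen=True)
class SyntheticTemplate:
    """Parametric description of one synthetic site.

    Depth samples are section midpoints on a regular grid.  Sulfate is
    constant at ``so4_surface_mM`` down to ``so4_plateau_cm`` (the
    bioirrigated layer; 0 for none), declines linearly to zero at
    ``so4_depletion_cm`` and stays at zero below.  DIC is
    ``dic_reference_mM`` plus ``dic_slope`` times the realized sulfate
    drawdown plus Gaussian noise.  Methane is either ``linear_no_AOM``
    (linear rise from zero to ``ch4_deep_mM`` at the bottom of the grid) or
    ``concave_up_AOM`` (exponential tail ``ch4_deep_mM * exp((z -
    z_depletion)/lambda)`` above the depletion depth, linear rise below);
    both are capped at ``ch4_saturation_mM``.  Hydrogen is drawn per zone
    from a moment-matched strictly-positive distribution, with optional
    replicate measurements jittered by a relative measurement error.
    """

    name: str
    top_cm: float = 0.0
    bottom_cm: float = 62.0
    spacing_cm: float = 1.0
    # sulfate
    so4_surface_mM: float = 24.0
    so4_plateau_cm: float = 0.0
    so4_depletion_cm: float = 35.0
    so4_noise_mM: float = 0.3
    # DIC
    dic_reference_mM: float = 2.0
    dic_slope: float = 1.0
    dic_noise_mM: float = 0.5
    # methane
    ch4_shape: str = "linear_no_AOM"  # or "concave_up_AOM"
    ch4_deep_mM: float = 1.0
    ch4_saturation_mM: float = 1.5
    ch4_aom_lambda_cm: float = 8.0
    ch4_deep_slope_mM_cm: float = 0.025
    ch4_noise_rel: float = 0.05
    # hydrogen
    hydrogen_zones: Sequence[HydrogenZone] = ()
    h2_replicates: int = 3
    h2_replicate_max_depth_cm: float | None = None
    h2_measurement_rel_sd: float = 0.02
    # sulfide
    sulfide_peak_mM: float = 5.0
    sulfide_peak_cm: float = 30.0
    sulfide_noise_mM: float = 0.1
    # porosity
    porosity_surface: float = 0.85
    porosity_deep: float = 0.70
    porosity_outlier_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bottom_cm <= self.top_cm or self.spacing_cm <= 0:
            raise ValueError("invalid depth grid")
        if not self.top_cm <= self.so4_depletion_cm <= self.bottom_cm:
            raise ValueError("sulfate depletion depth must lie within the grid")
        if self.so4_plateau_cm >= self.so4_depletion_cm:
            raise ValueError("bioirrigation plateau must be shallower than depletion")
        if self.ch4_shape not in ("linear_no_AOM", "concave_up_AOM"):
            raise ValueError(f"unknown methane shape {self.ch4_shape}")
        if self.ch4_shape == "linear_no_AOM" and self.ch4_saturation_mM < self.ch4_deep_mM:
            raise ValueError("saturation cap must be >= deep methane value")
        zones = sorted(self.hydrogen_zones, key=lambda z: z.top_cm)
        if not zones:
            raise ValueError("template needs at least one hydrogen zone")
        if zones[0].top_cm > self.top_cm or zones[-1].bottom_cm < self.bottom_cm:
            raise ValueError("hydrogen zones must cover the depth grid")
        for a, b in zip(zones, zones[1:]):
            if b.top_cm != a.bottom_cm:
                raise ValueError("hydrogen zones must tile the grid without gaps/overlap")
        object.__setattr__(self, "hydrogen_zones", tuple(zones))

    def depth_grid(self) -> np.ndarray:
        edges = np.arange(self.top_cm, self.bottom_cm + 1e-9, self.spacing_cm)
        return edges[:-1] + self.spacing_cm / 2.0


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters the analysis stages should recover."""

    template: str
    seed: int
    dic_so4_slope: float
    so4_depletion_cm: float
    ch4_shape: str
    h2_zone_means_nM: tuple[float, ...]
    h2_zone_variances_nM2: tuple[float, ...]
    h2_zone_bounds_cm: tuple[tuple[float, float], ...]


def _lognormal_params(mean: float, variance: float) -> tuple[float, float]:
    # moment matching: mean = exp(mu + s^2/2), var = mean^2 (exp(s^2) - 1)
    s2 = np.log1p(variance / mean**2)
    mu = np.log(mean) - s2 / 2.0
    return mu, np.sqrt(s2)


def _draw_zone(rng: np.random.Generator, zone: HydrogenZone, n: int) -> np.ndarray:
    if zone.variance_nM2 == 0:
        return np.full(n, zone.mean_nM)
    if zone.distribution == "lognormal":
        mu, s = _lognormal_params(zone.mean_nM, zone.variance_nM2)
        return rng.lognormal(mu, s, n)
    sd = np.sqrt(zone.variance_nM2)
    draws = rng.normal(zone.mean_nM, sd, n)
    while np.any(draws <= 0):  # resample the non-positive tail
        bad = draws <= 0
        draws[bad] = rng.normal(zone.mean_nM, sd, bad.sum())
    return draws


def generate_core(
    template: SyntheticTemplate,
    seed: int | None = None,
    site: SiteConditions | None = None,
) -> tuple[CoreDataset, GroundTruth]:
    """Generate one core and its ground truth; identical seeds reproduce
    bit-identical output."""
    if seed is None:
        seed = template.seed
    if site is None:
        site = _SITE_PRESETS.get(template.name, SiteConditions(temperature=24.0, salinity=35.0, pH=7.2))
    rng = np.random.default_rng(seed)
    z = template.depth_grid()
    nz = len(z)

    # sulfate: plateau, linear decline, floor at zero
    decline = (template.so4_depletion_cm - z) / (
        template.so4_depletion_cm - template.so4_plateau_cm
    )
    so4_true = template.so4_surface_mM * np.clip(decline, 0.0, None)
    so4_true[z <= template.so4_plateau_cm] = template.so4_surface_mM
    so4 = np.clip(so4_true + rng.normal(0.0, template.so4_noise_mM, nz), 0.0, None)

    # DIC follows the realized sulfate drawdown
    drawdown = template.so4_surface_mM - so4
    dic = (
        template.dic_reference_mM
        + template.dic_slope * drawdown
        + rng.normal(0.0, template.dic_noise_mM, nz)
    )

    # methane
    if template.ch4_shape == "linear_no_AOM":
        ch4_true = template.ch4_deep_mM * (z - template.top_cm) / (
            template.bottom_cm - template.top_cm
        )
    else:
        above = template.ch4_deep_mM * np.exp(
            (z - template.so4_depletion_cm) / template.ch4_aom_lambda_cm
        )
        below = template.ch4_deep_mM + template.ch4_deep_slope_mM_cm * (
            z - template.so4_depletion_cm
        )
        ch4_true = np.where(z <= template.so4_depletion_cm, above, below)
    ch4_true = np.clip(ch4_true, 0.0, template.ch4_saturation_mM)
    ch4 = np.clip(
        ch4_true * rng.lognormal(0.0, template.ch4_noise_rel, nz),
        0.0,
        template.ch4_saturation_mM,
    )

    # hydrogen: one true value per depth from its zone, optional replicates
    h2_true = np.empty(nz)
    for zone in template.hydrogen_zones:
        mask = (z >= zone.top_cm) & (z < zone.bottom_cm)
        h2_true[mask] = _draw_zone(rng, zone, int(mask.sum()))
    depths_rep, values_rep, rep_ids = [], [], []
    for i, depth in enumerate(z):
        nrep = template.h2_replicates
        if (
            template.h2_replicate_max_depth_cm is not None
            and depth > template.h2_replicate_max_depth_cm
        ):
            nrep = 1
        jitter = rng.normal(0.0, template.h2_measurement_rel_sd, nrep) if nrep > 1 else np.zeros(1)
        for r in range(nrep):
            depths_rep.append(depth)
            values_rep.append(max(h2_true[i] * (1.0 + jitter[r]), 1e-4))
            rep_ids.append(r)

    # sulfide: rise to a peak, flat below
    sulfide_true = template.sulfide_peak_mM * np.clip(z / template.sulfide_peak_cm, 0.0, 1.0)
    sulfide = np.clip(sulfide_true + rng.normal(0.0, template.sulfide_noise_mM, nz), 1e-3, None)

    # porosity: linear trend with Bernoulli-injected high spikes
    porosity = template.porosity_surface + (template.porosity_deep - template.porosity_surface) * (
        z - template.top_cm
    ) / (template.bottom_cm - template.top_cm)
    porosity += rng.normal(0.0, 0.01, nz)
    spikes = rng.random(nz) < template.porosity_outlier_rate
    porosity[spikes] = rng.uniform(0.92, 0.99, spikes.sum())
    porosity = np.clip(porosity, 0.05, 0.999)

    profiles = {
        "so4_mM": DepthProfile.from_arrays("so4_mM", z, so4),
        "dic_mM": DepthProfile.from_arrays("dic_mM", z, dic),
        "ch4_mM": DepthProfile.from_arrays("ch4_mM", z, ch4),
        "h2_nM": DepthProfile.from_arrays("h2_nM", depths_rep, values_rep, replicate=rep_ids),
        "sulfide_mM": DepthProfile.from_arrays("sulfide_mM", z, sulfide),
        "porosity": DepthProfile.from_arrays("porosity", z, porosity),
        "water_content": DepthProfile.from_arrays(
            "water_content", z, water_content_from_porosity(porosity)
        ),
    }
    core = CoreDataset(site=site, profiles=profiles, provenance=f"{template.name} seed={seed}")
    truth = GroundTruth(
        template=template.name,
        seed=seed,
        dic_so4_slope=template.dic_slope,
        so4_depletion_cm=template.so4_depletion_cm,
        ch4_shape=template.ch4_shape,
        h2_zone_means_nM=tuple(zn.mean_nM for zn in template.hydrogen_zones),
        h2_zone_variances_nM2=tuple(zn.variance_nM2 for zn in template.hydrogen_zones),
        h2_zone_bounds_cm=tuple((zn.top_cm, zn.bottom_cm) for zn in template.hydrogen_zones),
    )
    return core, truth


# Site presets: the organic-rich site uses the bight's measured 24 °C / 35 ‰
# / pH 7.2; the organic-poor estuarine site uses 28.5 °C / 18.9 ‰ with the
# same sediment pH (the only sediment pH measured in either setting).
_SITE_PRESETS = {
    "organic_rich_CLB_like": SiteConditions(temperature=24.0, salinity=35.0, pH=7.2),
    "organic_poor_WOR_like": SiteConditions(temperature=28.5, salinity=18.9, pH=7.2),
}


def template_library() -> dict[str, SyntheticTemplate]:
    """Immutable presets for the two study-site archetypes.

    Numeric defaults follow the reported site statistics: sulfate 24 mM
    declining to depletion near 35 cm (organic-rich) or 14 mM declining from
    the surface to ~30 cm (organic-poor); DIC:|dSO4| ground-truth slopes
    2.38 and 0.629; hydrogen zone moments (organic-poor: mean 0.465 nM /
    variance 0.00081 nM^2 above 15 cm, 1.49 nM / 0.194 nM^2 below 30 cm;
    organic-rich: 0.876 nM / 0.2285 nM^2 above 10 cm, 0.410 nM below);
    2 cm vs 1 cm section spacing; porosity 0.85 -> 0.70.
    """
    organic_rich = SyntheticTemplate(
        name="organic_rich_CLB_like",
        spacing_cm=2.0,
        so4_surface_mM=24.0,
        so4_plateau_cm=12.0,
        so4_depletion_cm=35.0,
        so4_noise_mM=0.3,
        dic_reference_mM=40.0,
        dic_slope=2.38,
        dic_noise_mM=1.5,
        ch4_shape="linear_no_AOM",
        ch4_deep_mM=1.4,
        ch4_saturation_mM=1.5,
        hydrogen_zones=(
            HydrogenZone(0.0, 10.0, 0.876, 0.2285),
            HydrogenZone(10.0, 62.0, 0.410, 0.04),
        ),
        sulfide_peak_mM=6.0,
        seed=0,
    )
    organic_poor = SyntheticTemplate(
        name="organic_poor_WOR_like",
        spacing_cm=1.0,
        so4_surface_mM=14.0,
        so4_plateau_cm=0.0,
        so4_depletion_cm=30.0,
        so4_noise_mM=0.3,
        dic_reference_mM=2.0,
        dic_slope=0.629,
        dic_noise_mM=0.35,
        ch4_shape="concave_up_AOM",
        ch4_deep_mM=0.1,
        ch4_saturation_mM=1.5,
        ch4_aom_lambda_cm=8.0,
        ch4_deep_slope_mM_cm=0.025,
        hydrogen_zones=(
            HydrogenZone(0.0, 15.0, 0.465, 0.00081),
            HydrogenZone(15.0, 30.0, 1.0, 0.203),
            HydrogenZone(30.0, 62.0, 1.49, 0.1936),
        ),
        h2_replicate_max_depth_cm=47.0,
        sulfide_peak_mM=2.0,
        seed=0,
    )
    return {t.name: t for t in (organic_rich, organic_poor)}


def get_template(name: str) -> SyntheticTemplate:
    """Look up a preset template by name; unknown names raise KeyError."""
    lib = template_library()
    if name not in lib:
        raise KeyError(f"unknown template {name!r}; available: {sorted(lib)}")
    return lib[name]
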