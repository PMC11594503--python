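"""Downcore profile data model, porosity, outlier cleaning, and CSV I/O.

Profiles are depth-ordered measurements in cm below seafloor (cmbsf), with
optional replicate identifiers when the same horizon was measured more than
once.  A :class:`CoreDataset` bundles the profiles of one core with its
:class:`~poregibbs.thermo.SiteConditions`.  The on-disk format is a wide CSV
(``depth_cm`` plus one column per variable, optional ``replicate``) with the
site metadata in a YAML sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InsufficientDataError, ParseError, RangeError
from .thermo import SiteConditions

__all__ = [
    "UNITS",
    "DepthProfile",
    "CoreDataset",
    "OutlierReplacement",
    "porosity_from_water_content",
    "water_content_from_porosity",
    "clean_porosity_outliers",
    "read_core_csv",
    "write_core_csv",
    "read_site_yaml",
    "write_site_yaml",
]

#: Registered variable -> unit map for core CSV columns.
UNITS = {
    "so4_mM": "mM",
    "dic_mM": "mM",
    "ch4_mM": "mM",
    "h2_nM": "nM",
    "sulfide_mM": "mM",
    "water_content": "fraction",
    "porosity": "fraction",
}


@dataclass(frozen=True)
class DepthProfile:
    """One measured variable versus depth.

    ``data`` has columns ``depth_cm``, ``value`` and optionally
    ``replicate``; rows are kept sorted by depth (stable, so replicate order
    at one depth is preserved).
    """

    variable: str
    data: pd.DataFrame
    units: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if not {"depth_cm", "value"}.issubset(df.columns):
            raise ParseError(f"profile {self.variable} needs depth_cm and value columns")
        if (df["depth_cm"] < 0).any():
            raise RangeError(f"profile {self.variable} has negative depths")
        df = df.sort_values("depth_cm", kind="stable").reset_index(drop=True)
        object.__setattr__(self, "data", df)
        if not self.units:
            object.__setattr__(self, "units", UNITS.get(self.variable, ""))

    @classmethod
    def from_arrays(
        cls,
        variable: str,
        depths_cm: Iterable[float],
        values: Iterable[float],
        replicate: Iterable | None = None,
        units: str = "",
    ) -> "DepthProfile":
        df = pd.DataFrame({"depth_cm": list(depths_cm), "value": list(values)})
        if replicate is not None:
            df["replicate"] = list(replicate)
        return cls(variable, df, units)

    @property
    def depths(self) -> np.ndarray:
        return self.data["depth_cm"].to_numpy(float)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(float)

    def reduce_replicates(self, how: str = "mean") -> "DepthProfile":
        """Collapse replicate rows to one value per depth (mean or median)."""
        if how not in ("mean", "median"):
            raise ValueError("replicate reduction must be 'mean' or 'median'")
        grouped = getattr(self.data.groupby("depth_cm")["value"], how)().reset_index()
        return DepthProfile(self.variable, grouped, self.units)


@dataclass
class CoreDataset:
    """All measured profiles of one core plus its site conditions."""

    site: SiteConditions
    profiles: dict[str, DepthProfile] = field(default_factory=dict)
    provenance: str = ""

    def __getitem__(self, variable: str) -> DepthProfile:
        try:
            return self.profiles[variable]
        except KeyError:
            raise ConfigurationError(f"core has no '{variable}' profile") from None


def porosity_from_water_content(
    w,
    rho_solid: float = 2.5,
    rho_porewater: float = 1.025,
):
    """Porosity from wet-sediment water-content fraction.

    phi = w rho_sm / (rho_sm w + (1 - w) rho_pw), with the solid-matter and
    porewater densities defaulting to 2.5 and 1.025 g/cm^3.  Accepts scalars
    or arrays; strictly increasing in w, with phi(0) = 0 and phi(1) = 1.
    """
    w = np.asarray(w, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise RangeError("water content must lie in [0, 1]")
    phi = w * rho_solid / (rho_solid * w + (1.0 - w) * rho_porewater)
    return float(phi) if phi.ndim == 0 else phi


def water_content_from_porosity(
    phi,
    rho_solid: float = 2.5,
    rho_porewater: float = 1.025,
):
    """Inverse of :func:`porosity_from_water_content`."""
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise RangeError("porosity must lie in [0, 1]")
    w = phi * rho_porewater / (rho_solid * (1.0 - phi) + phi * rho_porewater)
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class OutlierReplacement:
    depth_cm: float
    old_value: float
    new_value: float
    rule: str  # "iqr" or "3sd"


def _quartiles(window: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(window, [0.25, 0.75])
    return float(q1), float(q3)


def clean_porosity_outliers(
    profile: DepthProfile,
    shallow_window: tuple[float, float] = (0.0, 33.0),
    deep_window: tuple[float, float] = (33.0, 51.0),
    local_n: int = 5,
    global_quartiles: bool = False,
) -> tuple[DepthProfile, list[OutlierReplacement]]:
    """Replace porosity outliers using two depth-dependent rules.

    Shallow rule (depths in ``shallow_window``): a value outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] — quartiles over a centered ``local_n``-point
    moving window (or over the whole shallow window when
    ``global_quartiles``) — is replaced by the mean of its three nearest
    non-outlying values.  Deep rule (``deep_window``): a value strictly more
    than 3 standard deviations from the mean of the surrounding depths
    (the rest of the local window) is replaced by that mean.  Boundary cases
    use strict inequalities, so a value exactly on a fence is retained.

    Returns the cleaned profile and the list of replacements made.
    """
    depths = profile.depths
    values = profile.values.copy()
    n = len(values)
    half = local_n // 2

    shallow_idx = [i for i in range(n) if shallow_window[0] <= depths[i] < shallow_window[1]]
    deep_idx = [i for i in range(n) if deep_window[0] <= depths[i] < deep_window[1]]
    if shallow_idx and len(shallow_idx) < local_n:
        raise InsufficientDataError(
            f"shallow window has {len(shallow_idx)} points; need >= {local_n}"
        )

    report: list[OutlierReplacement] = []
    flagged: list[int] = []
    shallow_vals = values[shallow_idx] if shallow_idx else np.empty(0)
    for i in shallow_idx:
        if global_quartiles:
            window = shallow_vals
        else:
            lo = max(0, min(i - half, n - local_n))
            window = values[lo : lo + local_n]
        q1, q3 = _quartiles(window)
        iqr = q3 - q1
        if values[i] > q3 + 1.5 * iqr or values[i] < q1 - 1.5 * iqr:
            flagged.append(i)
    for i in flagged:
        neighbors = sorted(
            (j for j in range(n) if j != i and j not in flagged),
            key=lambda j: (abs(depths[j] - depths[i]), j),
        )[:3]
        new = float(np.mean(values[neighbors]))
        report.append(OutlierReplacement(float(depths[i]), float(values[i]), new, "iqr"))
    for rep, i in zip(report, flagged):
        values[i] = rep.new_value

    for i in deep_idx:
        lo = max(0, min(i - half, n - local_n))
        surrounding = [j for j in range(lo, min(lo + local_n, n)) if j != i]
        mean = float(np.mean(values[surrounding]))
        sd = float(np.std(values[surrounding], ddof=1))
        if sd > 0 and abs(values[i] - mean) > 3.0 * sd:
            report.append(OutlierReplacement(float(depths[i]), float(values[i]), mean, "3sd"))
            values[i] = mean

    cleaned = DepthProfile(
        profile.variable,
        profile.data.assign(value=values),
        profile.units,
    )
    return cleaned, report


def read_site_yaml(path: str | Path) -> SiteConditions:
    """Read site conditions from a YAML config, validating required fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    required = {
        "temperature_C": "temperature",
        "salinity_permil": "salinity",
        "pH": "pH",
        "ionic_strength_M": "ionic_strength",
    }
    kwargs = {}
    for key, attr in required.items():
        if key not in raw:
            raise ConfigurationError(f"site config missing required field '{key}'")
        kwargs[attr] = float(raw[key])
    for key, attr in {
        "pressure_atm": "pressure",
        "dg_min_methanogenesis_kJ": "dG_min_methanogenesis",
        "dg_min_sulfate_reduction_kJ": "dG_min_sulfate_reduction",
    }.items():
        if key in raw:
            kwargs[attr] = float(raw[key])
    return SiteConditions(**kwargs)


def write_site_yaml(site: SiteConditions, path: str | Path) -> None:
    doc = {
        "temperature_C": site.temperature,
        "salinity_permil": site.salinity,
        "pressure_atm": site.pressure,
        "pH": site.pH,
        "ionic_strength_M": site.ionic_strength,
        "dg_min_methanogenesis_kJ": site.dG_min_methanogenesis,
        "dg_min_sulfate_reduction_kJ": site.dG_min_sulfate_reduction,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_core_csv(path: str | Path, site: SiteConditions | str | Path) -> CoreDataset:
    """Read a wide core CSV; ``site`` is a SiteConditions or a YAML path.

    Unknown columns raise a parse error; non-numeric cells report the line
    number of the offending row.
    """
    if not isinstance(site, SiteConditions):
        site = read_site_yaml(site)
    df = pd.read_csv(path)
    if "depth_cm" not in df.columns:
        raise ParseError(f"{path}: missing required column depth_cm")
    unknown = [c for c in df.columns if c not in UNITS and c not in ("depth_cm", "replicate")]
    if unknown:
        raise ParseError(f"{path}: unknown columns {unknown}")
    for col in df.columns:
        if col == "replicate":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise ParseError(f"{path}: non-numeric value in column {col} at line {line}")
        df[col] = coerced
    profiles: dict[str, DepthProfile] = {}
    for col in df.columns:
        if col in ("depth_cm", "replicate"):
            continue
        sub = df[["depth_cm", col]].dropna().rename(columns={col: "value"})
        if "replicate" in df.columns:
            sub["replicate"] = df.loc[sub.index, "replicate"]
        if len(sub):
            profiles[col] = DepthProfile(col, sub.reset_index(drop=True))
    return CoreDataset(site=site, profiles=profiles, provenance=str(path))


def write_core_csv(
    dataset: CoreDataset,
    path: str | Path,
    site_path: str | Path | None = None,
) -> None:
    """Write a CoreDataset as a wide CSV (plus optional site YAML sidecar)."""
    frames = []
    for name, prof in dataset.profiles.items():
        df = prof.data.rename(columns={"value": name})
        if "replicate" not in df.columns:
            df["replicate"] = 0
        frames.append(df.set_index(["depth_cm", "replicate"]))
    wide = pd.concat(frames, axis=1).sort_index().reset_index()
    if (wide["replicate"] == 0).all():
        wide = wide.drop(columns="replicate")
    wide.to_csv(path, index=False)
    if site_path is not None:
        write_site_yaml(dataset.site, site_path)
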