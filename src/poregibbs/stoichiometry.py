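"""dDIC : |dSO4| stoichiometry and sulfate-reduction pathway classification.

In the sulfate-reducing zone, organoclastic sulfate reduction of average
marine organic matter produces about two moles of dissolved inorganic
carbon per mole of sulfate consumed, while sulfate reduction coupled to
anaerobic methane oxidation produces one.  Regressing the DIC increase
against the sulfate drawdown (both relative to a reference horizon) over a
stated depth window therefore diagnoses which pathway dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ConfigurationError, InsufficientDataError
from .profiles import DepthProfile

__all__ = [
    "StoichiometryResult",
    "delta_vs_reference",
    "fit_dic_so4_slope",
    "classify_pathway",
]


@dataclass(frozen=True)
class StoichiometryResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]  # 95% confidence interval
    n: int
    window_cm: tuple[float, float]
    classification: str


def delta_vs_reference(profile: DepthProfile, reference: float | tuple[str, float]) -> DepthProfile:
    """Profile of changes relative to a reference horizon or value.

    ``reference`` is either ``("depth", z_cm)`` — the profile value at that
    exact depth (replicates averaged) — or a plain number, e.g. an overlying
    water-column concentration.  The result at the reference depth is zero.
    """
    prof = profile.reduce_replicates() if "replicate" in profile.data.columns else profile
    if isinstance(reference, tuple):
        kind, z = reference
        if kind != "depth":
            raise ValueError("reference tuple must be ('depth', z_cm)")
        match = np.isclose(prof.depths, z)
        if not match.any():
            raise ConfigurationError(f"reference depth {z} cm not present in profile")
        ref_value = float(prof.values[match].mean())
    else:
        ref_value = float(reference)
    return DepthProfile.from_arrays(
        f"delta_{profile.variable}", prof.depths, prof.values - ref_value, units=profile.units
    )


def fit_dic_so4_slope(
    d_dic: DepthProfile,
    d_so4: DepthProfile,
    window_cm: tuple[float, float],
    method: str = "ols",
    zero_intercept: bool = False,
    match_tolerance: float | None = None,
    bands: tuple[float, ...] = (1.5,),
) -> StoichiometryResult:
    """Fit the dDIC : |dSO4| slope over a depth window.

    Depth pairs are matched by nearest depth within ``match_tolerance``
    (default half the coarser grid spacing) and restricted to
    ``window_cm`` (inclusive).  ``method`` is ``"ols"`` (ordinary least
    squares of dDIC on |dSO4|) or ``"rma"`` (reduced major axis, for when
    both variables carry comparable error).  Requires at least three pairs.
    """
    lo, hi = window_cm
    dic_d, dic_v = d_dic.depths, d_dic.values
    so4_d, so4_v = d_so4.depths, np.abs(d_so4.values)
    if match_tolerance is None:
        sp = [np.median(np.diff(d)) for d in (dic_d, so4_d) if len(d) > 1]
        match_tolerance = max(sp) / 2.0 if sp else 0.0
    idx = np.searchsorted(so4_d, dic_d)
    xs, ys = [], []
    for k, z in enumerate(dic_d):
        if not lo <= z <= hi:
            continue
        candidates = [j for j in (idx[k] - 1, idx[k]) if 0 <= j < len(so4_d)]
        if not candidates:
            continue
        j = min(candidates, key=lambda j: abs(so4_d[j] - z))
        if abs(so4_d[j] - z) <= match_tolerance:
            xs.append(so4_v[j])
            ys.append(dic_v[k])
    x, y = np.asarray(xs), np.asarray(ys)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"only {n} depth pairs in window {window_cm}; need >= 3")

    if method == "ols":
        design = x[:, None] if zero_intercept else sm.add_constant(x)
        fit = sm.OLS(y, design).fit()
        slope = float(fit.params[-1])
        intercept = 0.0 if zero_intercept else float(fit.params[0])
        ci = fit.conf_int(alpha=0.05)
        slope_ci = (float(ci[-1, 0]), float(ci[-1, 1]))
    elif method == "rma":
        sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
        if sx == 0:
            raise InsufficientDataError("zero sulfate variance in window")
        r = np.corrcoef(x, y)[0, 1]
        slope = float(np.sign(r) * sy / sx)
        intercept = float(np.mean(y) - slope * np.mean(x))
        # large-sample RMA slope CI via the standard error of the ratio
        se = abs(slope) * np.sqrt((1 - r**2) / max(n - 2, 1))
        from scipy import stats

        tcrit = stats.t.ppf(0.975, max(n - 2, 1))
        slope_ci = (slope - tcrit * se, slope + tcrit * se)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    return StoichiometryResult(
        slope=slope,
        intercept=intercept,
        slope_ci=slope_ci,
        n=n,
        window_cm=window_cm,
        classification=classify_pathway(slope, bands),
    )


def classify_pathway(slope: float, bands: tuple[float, ...] = (1.5,)) -> str:
    """Classify a dDIC:|dSO4| slope.

    With the default single cut at 1.5 (midway between the 1:1 methane-
    oxidation and 2:1 organoclastic stoichiometries): slope < 1.5 is
    ``AOM-dominated``, slope >= 1.5 is ``OSR-dominated``.  A two-value
    ``bands = (low, high)`` enables a ``mixed`` class between them.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if len(bands) == 1:
        return "AOM-dominated" if slope < bands[0] else "OSR-dominated"
    lo, hi = bands
    if slope < lo:
        return "AOM-dominated"
    if slope >= hi:
        return "OSR-dominated"
    return "mixed"
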