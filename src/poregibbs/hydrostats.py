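"""Zone-wise hydrogen statistics and the two-zone Welch comparison.

Dissolved hydrogen is the shared currency of fermenter-respirer syntrophy:
a zone where hydrogen is low and nearly invariant indicates tight
syntrophic control by sulfate reducers, while a high-variance zone
indicates that control has been released.  This module summarizes a
hydrogen profile over depth zones and compares two zones with Welch's
unequal-variance t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .profiles import DepthProfile

__all__ = ["ZoneStats", "zone_statistics", "welch_t_test", "zone_values"]


@dataclass(frozen=True)
class ZoneStats:
    """Summary moments of one depth zone; variance uses the n-1 denominator
    and is reported in nM^2."""

    label: str
    top_cm: float
    bottom_cm: float
    n: int
    mean: float | None
    variance: float | None
    min: float | None
    max: float | None


def zone_values(
    profile: DepthProfile,
    top_cm: float,
    bottom_cm: float,
    replicates: str = "mean",
) -> np.ndarray:
    """Sample values in [top_cm, bottom_cm).

    ``replicates`` is ``"mean"``/``"median"`` (one value per depth) or
    ``"independent"`` (every replicate kept as its own observation).
    """
    if replicates in ("mean", "median"):
        prof = (
            profile.reduce_replicates(replicates)
            if "replicate" in profile.data.columns
            else profile
        )
    elif replicates == "independent":
        prof = profile
    else:
        raise ValueError(f"unknown replicate handling {replicates!r}")
    mask = (prof.depths >= top_cm) & (prof.depths < bottom_cm)
    return prof.values[mask]


def zone_statistics(
    profile: DepthProfile,
    boundaries: Sequence[float],
    replicates: str = "mean",
) -> list[ZoneStats]:
    """Per-zone n, mean, sample variance, min, max.

    ``boundaries`` are strictly increasing depths; zones are the half-open
    intervals [b_i, b_{i+1}).  Empty zones report n = 0 with missing
    moments.
    """
    bounds = list(boundaries)
    if len(bounds) < 2 or any(b <= a for a, b in zip(bounds, bounds[1:])):
        raise ValueError("zone boundaries must be strictly increasing")
    out = []
    for top, bottom in zip(bounds, bounds[1:]):
        vals = zone_values(profile, top, bottom, replicates)
        n = len(vals)
        out.append(
            ZoneStats(
                label=f"{top:g}-{bottom:g} cm",
                top_cm=top,
                bottom_cm=bottom,
                n=n,
                mean=float(np.mean(vals)) if n else None,
                variance=float(np.var(vals, ddof=1)) if n > 1 else None,
                min=float(np.min(vals)) if n else None,
                max=float(np.max(vals)) if n else None,
            )
        )
    return out


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p).

    The degrees of freedom use the Welch-Satterthwaite approximation, so
    they are generally non-integer.  Swapping the samples negates t and
    preserves df and p.  Each sample needs n >= 2 and nonzero variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise InsufficientDataError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
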