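"""Model-independent dissolution statistics.

Implements the three classical profile summaries used to compare
formulations without assuming a release mechanism:

* similarity factor ``f2`` — a logarithmic transform of the mean squared
  point-wise difference between a reference and a test profile; 100 means
  identity and values below 50 conventionally flag dissimilar profiles,

      f2 = 50 * log10( 100 / sqrt(1 + (1/n) * sum_t (R_t - T_t)^2 ) )

* dissolution efficiency ``DE%`` — area under the cumulative dissolution
  curve up to ``t_end`` as a percentage of the rectangle corresponding to
  instantaneous 100% dissolution over the same window,

* mean dissolution time ``MDT`` — the increment-weighted mean of interval
  midpoints of the cumulative curve; small values indicate fast release.

Plus the 2-decimal fold-change convention used in formulation reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .profiles import DissolutionProfile

__all__ = [
    "similarity_factor",
    "dissolution_efficiency",
    "mean_dissolution_time",
    "fold_change",
    "monotonize",
    "DissolutionSummary",
    "summarize_profiles",
]


def similarity_factor(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    include_t0: bool = False,
    fda_truncation: bool = False,
) -> float:
    """Similarity factor f2 between two profiles on a common time grid.

    The t = 0 point is excluded by default (both curves are 0 there by
    definition, which would only inflate the score).  With
    ``fda_truncation=True``, sampling points after the first at which both
    profiles exceed 85% dissolved are dropped (at most one such point kept),
    following the regulatory convention; default uses all shared points.

    Identical profiles return exactly 100; any growing point-wise divergence
    strictly decreases the score.
    """
    if reference.times.shape != test.times.shape or not np.array_equal(
        reference.times, test.times
    ):
        raise ValueError(
            "profiles are not on a common time grid; use align_profiles first"
        )
    t = reference.times
    r = reference.dissolved
    s = test.dissolved
    mask = np.ones_like(t, dtype=bool)
    if not include_t0:
        mask &= t > 0
    if fda_truncation:
        both85 = (r > 85.0) & (s > 85.0)
        idx = np.flatnonzero(both85 & mask)
        if idx.size > 1:
            mask[idx[1:]] = False
    if mask.sum() < 3:
        raise ValueError("need at least 3 usable points for f2")
    msd = float(np.mean((r[mask] - s[mask]) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def dissolution_efficiency(profile: DissolutionProfile, t_end: float) -> float:
    """Dissolution efficiency DE% over [0, t_end] (minutes).

    The integral is the trapezoidal rule over the sampling points, with the
    profile anchored at (0, 0) if t = 0 is absent (the dose is undissolved at
    test start) and ``t_end`` inserted by linear interpolation if unsampled.
    No extrapolation: ``t_end`` beyond the last sample is an error.
    """
    p = profile.anchored()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if t_end > p.times[-1]:
        raise ValueError(
            f"t_end={t_end} beyond last sampling time {p.times[-1]}; no extrapolation"
        )
    t, y = p.times, p.dissolved
    if t_end not in t:
        y_end = float(np.interp(t_end, t, y))
        keep = t < t_end
        t = np.append(t[keep], t_end)
        y = np.append(y[keep], y_end)
    else:
        keep = t <= t_end
        t, y = t[keep], y[keep]
    area = float(np.trapezoid(y, t))
    return 100.0 * area / (100.0 * t_end)


def mean_dissolution_time(profile: DissolutionProfile) -> float:
    """Mean dissolution time (minutes): sum_j t*_j dM_j / sum_j dM_j.

    ``t*_j`` is the midpoint of sampling interval j and ``dM_j`` the percent
    dissolved in that interval.  The profile is anchored at (0, 0) with a
    warning if t = 0 is absent.  Negative increments from noisy cumulative
    data are used as-is (the literal formula) with a warning; see
    :func:`monotonize` for the optional pre-pass.
    """
    if not profile.has_t0:
        warnings.warn(
            f"{profile.label}: profile not anchored at t=0; inserting (0, 0)",
            stacklevel=2,
        )
    p = profile.anchored()
    dm = np.diff(p.dissolved)
    if np.any(dm < 0):
        warnings.warn(
            f"{p.label}: cumulative curve decreases; negative increments used as-is",
            stacklevel=2,
        )
    total = float(dm.sum())
    if total <= 0:
        raise ValueError(f"{p.label}: no dissolution observed")
    midpoints = 0.5 * (p.times[:-1] + p.times[1:])
    return float(np.sum(midpoints * dm) / total)


def monotonize(profile: DissolutionProfile) -> DissolutionProfile:
    """Running-maximum pre-pass removing noisy decreases in a cumulative curve."""
    return replace(profile, dissolved=np.maximum.accumulate(profile.dissolved))


def fold_change(test_value: float, reference_value: float, rounded: bool = True) -> float:
    """test/reference ratio; half-even rounded to 2 decimals for reporting."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    ratio = test_value / reference_value
    return round(ratio, 2) if rounded else ratio


@dataclass(frozen=True)
class DissolutionSummary:
    """Report row for one formulation: DE15, DE60, MDT and f2 vs reference."""

    label: str
    de15: float
    de60: float
    mdt: float
    f2_vs_reference: float | None


def summarize_profiles(
    profiles: list[DissolutionProfile],
    reference_label: str | None = None,
    de_times: tuple[float, float] = (15.0, 60.0),
) -> pd.DataFrame:
    """Tabulate DE%, MDT and (optionally) f2 vs a reference for many profiles."""
    ref = None
    if reference_label is not None:
        by_label = {p.label: p for p in profiles}
        if reference_label not in by_label:
            raise ValueError(f"reference label {reference_label!r} not among profiles")
        ref = by_label[reference_label]
    rows = []
    for p in profiles:
        f2 = None
        if ref is not None and p.label != ref.label:
            f2 = round(similarity_factor(ref, p), 2)
        rows.append(
            {
                "label": p.label,
                f"de{de_times[0]:g}": round(dissolution_efficiency(p, de_times[0]), 2),
                f"de{de_times[1]:g}": round(dissolution_efficiency(p, de_times[1]), 2),
                "mdt_min": round(mean_dissolution_time(p), 2),
                "f2": f2,
            }
        )
    return pd.DataFrame(rows)
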