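"""Degree of relative crystallinity (DRC) from powder XRD patterns.

DRC = I_sample / I_reference: the ratio of baseline-corrected peak heights
at a characteristic diffraction angle (for the drug studied here, the
strong reflection near 2θ = 4°).  A ratio near 0 indicates amorphization of
the sample relative to the crystalline reference.

Peak height is measured as the maximum of (intensity − linear baseline)
within a closed window around the nominal angle, where the baseline is the
straight line through the window's endpoint samples; raw (uncorrected)
heights are available behind ``baseline="none"`` since published ratios do
not always state their baseline handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DiffractionPattern", "read_pattern", "peak_height", "relative_crystallinity"]

DEFAULT_WINDOW_DEG = 1.0  # full width, i.e. +/- 0.5 degrees


@dataclass(frozen=True)
class DiffractionPattern:
    label: str
    two_theta: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        tt = np.asarray(self.two_theta, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "two_theta", tt)
        object.__setattr__(self, "intensity", it)
        if tt.shape != it.shape or tt.ndim != 1:
            raise ValueError("two_theta and intensity must be equal-length 1-D")
        if not np.all(np.diff(tt) > 0):
            raise ValueError("two_theta must be strictly increasing")
        if np.any((tt <= 0) | (tt >= 90)):
            raise ValueError("two_theta must lie in (0, 90) degrees")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")


def read_pattern(path: str | Path, label: str | None = None) -> DiffractionPattern:
    """Two-column CSV reader (``two_theta,intensity``)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (two_theta, intensity)")
    return DiffractionPattern(
        label=label or path.stem,
        two_theta=df.iloc[:, 0].to_numpy(dtype=float),
        intensity=df.iloc[:, 1].to_numpy(dtype=float),
    )


def peak_height(
    pattern: DiffractionPattern,
    angle: float,
    window: float = DEFAULT_WINDOW_DEG,
    baseline: str = "linear",
) -> float:
    """Baseline-corrected peak height (counts) in [angle - w/2, angle + w/2].

    The window is closed, so an apex exactly on the edge is still captured.
    ``baseline="linear"`` subtracts the straight line through the window's
    endpoint samples; ``"none"`` uses raw intensities.  The result is
    floored at 0.
    """
    lo, hi = angle - window / 2.0, angle + window / 2.0
    if lo < pattern.two_theta[0] or hi > pattern.two_theta[-1]:
        raise ValueError(
            f"window [{lo:g}, {hi:g}]° outside pattern range "
            f"[{pattern.two_theta[0]:g}, {pattern.two_theta[-1]:g}]°"
        )
    mask = (pattern.two_theta >= lo) & (pattern.two_theta <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 samples inside the window")
    tt = pattern.two_theta[mask]
    it = pattern.intensity[mask]
    if baseline == "linear":
        slope = (it[-1] - it[0]) / (tt[-1] - tt[0])
        base = it[0] + slope * (tt - tt[0])
        corrected = it - base
    elif baseline == "none":
        corrected = it
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(max(corrected.max(), 0.0))


def relative_crystallinity(
    sample: DiffractionPattern,
    reference: DiffractionPattern,
    angle: float,
    window: float = DEFAULT_WINDOW_DEG,
    baseline: str = "linear",
    rounded: bool = True,
) -> float:
    """DRC = sample peak height / reference peak height at one angle."""
    h_ref = peak_height(reference, angle, window, baseline)
    if h_ref <= 0:
        raise ValueError(f"reference peak absent at {angle}°")
    h_sample = peak_height(sample, angle, window, baseline)
    drc = h_sample / h_ref
    return round(drc, 2) if rounded else drc
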