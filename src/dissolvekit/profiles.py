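"""Data model and I/O for cumulative dissolution time courses.

A :class:`DissolutionProfile` is the pipeline's atomic input: mean cumulative
percent of dose dissolved at a strictly increasing grid of sampling times
(minutes), optionally with per-time replicate standard deviations.  Values
above 100% are retained (assay variability in real data produces them) but
trigger a warning.

CSV layout: one ``time_min`` column plus one column per labelled profile,
with optional paired ``<label>_sd`` columns::

    time_min,plain,SD18,SD18_sd
    0,0,0,0
    5,6.1,88.2,1.3
    ...
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DissolutionProfile",
    "XYSeries",
    "read_profiles",
    "write_profiles",
    "align_profiles",
]

TIME_COLUMN = "time_min"


@dataclass(frozen=True)
class XYSeries:
    """Generic paired series (XRD angle/intensity, time/concentration)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be equal-length 1-D sequences")
        if self.x.size >= 2 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative percent-dissolved time course for one formulation.

    Parameters
    ----------
    label : str
        Identifier of the formulation (e.g. ``"plain"``, ``"SD18"``).
    times : array-like
        Sampling times in minutes, strictly increasing, all >= 0.
    dissolved : array-like
        Mean cumulative percent of dose dissolved at each time.  Values
        above 100% are permitted but flagged with a warning.
    sd : array-like, optional
        Replicate standard deviation at each time, percent.
    n_replicates : int, optional
        Number of replicate vessels behind the means.
    """

    label: str
    times: np.ndarray
    dissolved: np.ndarray
    sd: np.ndarray | None = None
    n_replicates: int | None = field(default=None)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.dissolved, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dissolved", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError(f"{self.label}: times and dissolved must be equal-length 1-D")
        if t.size < 2:
            raise ValueError(f"{self.label}: need at least 2 sampling points")
        if np.any(t < 0):
            raise ValueError(f"{self.label}: negative sampling times")
        if not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2  # 1-based offending row
            raise ValueError(f"{self.label}: times not strictly increasing at row {bad}")
        if np.any(~np.isfinite(y)) or np.any(~np.isfinite(t)):
            raise ValueError(f"{self.label}: non-finite values")
        if np.any(y < 0):
            raise ValueError(f"{self.label}: negative dissolved values")
        if np.any(y > 100.0):
            warnings.warn(
                f"{self.label}: dissolved exceeds 100% (max {y.max():.2f}%); retained",
                stacklevel=2,
            )
        if self.sd is not None:
            s = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", s)
            if s.shape != t.shape:
                raise ValueError(f"{self.label}: sd length mismatch")
        if self.n_replicates is not None and self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")

    @property
    def has_t0(self) -> bool:
        return self.times[0] == 0.0

    def anchored(self) -> "DissolutionProfile":
        """Return a copy with a (0, 0) point prepended if t = 0 is absent."""
        if self.has_t0:
            return self
        sd = None if self.sd is None else np.insert(self.sd, 0, 0.0)
        return replace(
            self,
            times=np.insert(self.times, 0, 0.0),
            dissolved=np.insert(self.dissolved, 0, 0.0),
            sd=sd,
        )


def read_profiles(path: str | Path) -> list[DissolutionProfile]:
    """Read all profiles from a CSV file (``time_min`` + labelled columns).

    Columns named ``<label>_sd`` are attached as replicate SDs of ``<label>``.
    Missing cells or a non-monotone time column are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if TIME_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing required column '{TIME_COLUMN}'")
    if df.isna().any().any():
        cells = [
            f"({row + 2}, {col})"
            for col in df.columns
            for row in df.index[df[col].isna()]
        ]
        raise ValueError(f"{path}: missing values at cells {', '.join(cells)}")
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2  # 1-based offending data row
        raise ValueError(f"{path}: time column not strictly increasing at row {bad}")
    labels = [c for c in df.columns if c != TIME_COLUMN and not c.endswith("_sd")]
    if not labels:
        raise ValueError(f"{path}: no profile columns found")
    out = []
    for lab in labels:
        sd_col = f"{lab}_sd"
        sd = df[sd_col].to_numpy(dtype=float) if sd_col in df.columns else None
        out.append(
            DissolutionProfile(label=lab, times=t, dissolved=df[lab].to_numpy(dtype=float), sd=sd)
        )
    return out


def write_profiles(profiles: Sequence[DissolutionProfile], path: str | Path) -> None:
    """Write profiles sharing a common time grid to CSV (inverse of read)."""
    if not profiles:
        raise ValueError("no profiles to write")
    t0 = profiles[0].times
    for p in profiles[1:]:
        if not np.array_equal(p.times, t0):
            raise ValueError("write_profiles requires a shared time grid")
    data: dict[str, np.ndarray] = {TIME_COLUMN: t0}
    for p in profiles:
        data[p.label] = p.dissolved
        if p.sd is not None:
            data[f"{p.label}_sd"] = p.sd
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def align_profiles(
    a: DissolutionProfile,
    b: DissolutionProfile,
    mode: str = "intersection",
) -> tuple[DissolutionProfile, DissolutionProfile, int]:
    """Put two profiles on a common time grid.

    ``mode="intersection"`` (default) keeps only shared sampling times, as
    point-wise profile comparison presumes common sampling; the number of
    dropped points (summed over both inputs) is returned.
    ``mode="interpolate"`` linearly interpolates ``b`` onto ``a``'s grid.
    """
    if mode == "interpolate":
        lo, hi = b.times[0], b.times[-1]
        keep = (a.times >= lo) & (a.times <= hi)
        if keep.sum() < 3:
            raise ValueError("fewer than 3 of a's times lie inside b's range")
        t = a.times[keep]
        ya = a.dissolved[keep]
        yb = np.interp(t, b.times, b.dissolved)
        dropped = int((~keep).sum())
        return (
            replace(a, times=t, dissolved=ya, sd=None),
            replace(b, times=t, dissolved=yb, sd=None),
            dropped,
        )
    if mode != "intersection":
        raise ValueError(f"unknown alignment mode {mode!r}")
    # exact float match is intended: grids come from the same CSV conventions
    shared = np.intersect1d(a.times, b.times)
    if shared.size < 3:
        raise ValueError(
            f"only {shared.size} shared time points between {a.label!r} and "
            f"{b.label!r}; consider align_profiles(..., mode='interpolate')"
        )
    ia = np.isin(a.times, shared)
    ib = np.isin(b.times, shared)
    dropped = int((~ia).sum() + (~ib).sum())
    sub = lambda p, m: replace(  # noqa: E731
        p, times=p.times[m], dissolved=p.dissolved[m], sd=None if p.sd is None else p.sd[m]
    )
    return sub(a, ia), sub(b, ib), dropped
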