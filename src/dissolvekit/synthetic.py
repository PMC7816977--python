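"""Seeded generators for every input the pipeline consumes.

Dissolution profiles with known kinetics, factorial-design datasets with
known coefficients, and powder-XRD patterns with known peak heights — all
pure functions of their spec (including the seed), so every downstream stage
is testable without external data.

The default sampling grid (0, 5, 10, 15, 30, 45, 60 min) mirrors a typical
one-hour paddle-apparatus schedule for immediate-release solids; the default
noise level emulates replicate-mean scatter of a triplicate UV assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import DesignTable, POLYMER_LEVELS, RATIO_LEVELS, encode_design
from .profiles import DissolutionProfile
from .xrd import DiffractionPattern

__all__ = [
    "ProfileSpec",
    "gen_dissolution_profile",
    "gen_doe_dataset",
    "gen_xrd_pattern",
    "DEFAULT_GRID_MIN",
]

DEFAULT_GRID_MIN = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for a synthetic cumulative release curve.

    model: one of ``first_order`` (k in 1/min), ``weibull`` (tau in min,
    beta dimensionless), ``zero_order`` (slope in %/min), ``higuchi``
    (k in %/min^0.5).  ``plateau`` caps the ideal curve; Gaussian i.i.d.
    noise (SD in %) is added per point and floored at 0 but not capped at
    100, matching observed >100% assay values in real data.
    """

    model: str
    k: float | None = None
    tau: float | None = None
    beta: float | None = None
    slope: float | None = None
    plateau: float = 100.0
    times: tuple[float, ...] = DEFAULT_GRID_MIN
    noise_sd: float = 0.0
    seed: int = 0
    label: str = field(default="synthetic")


def _ideal_curve(spec: ProfileSpec, t: np.ndarray) -> np.ndarray:
    if spec.model == "first_order":
        if spec.k is None or spec.k <= 0:
            raise ValueError("first_order requires k > 0")
        return spec.plateau * (1.0 - np.exp(-spec.k * t))
    if spec.model == "weibull":
        if not (spec.tau and spec.beta) or spec.tau <= 0 or spec.beta <= 0:
            raise ValueError("weibull requires tau > 0 and beta > 0")
        return spec.plateau * (1.0 - np.exp(-((t / spec.tau) ** spec.beta)))
    if spec.model == "zero_order":
        if spec.slope is None or spec.slope <= 0:
            raise ValueError("zero_order requires slope > 0")
        return np.minimum(spec.slope * t, spec.plateau)
    if spec.model == "higuchi":
        if spec.k is None or spec.k <= 0:
            raise ValueError("higuchi requires k > 0")
        return np.minimum(spec.k * np.sqrt(t), spec.plateau)
    raise ValueError(f"unknown profile model {spec.model!r}")


def gen_dissolution_profile(spec: ProfileSpec) -> DissolutionProfile:
    """Generate one profile; deterministic given the spec (incl. seed).

    The t = 0 point is exactly 0 before noise; noise is then added
    independently per post-zero point and floored at 0.
    """
    t = np.asarray(spec.times, dtype=float)
    y = _ideal_curve(spec, t)
    y = np.where(t == 0.0, 0.0, y)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=t.size)
        noise[t == 0.0] = 0.0
        y = np.maximum(y + noise, 0.0)
    return DissolutionProfile(label=spec.label, times=t, dissolved=y)


def gen_doe_dataset(
    true_coefficients: np.ndarray,
    model_order: str = "quadratic",
    noise_sd: float = 1.0,
    seed: int = 0,
    response: str = "y",
    replicate_map: dict[tuple[float, str], int] | None = None,
) -> tuple[DesignTable, np.ndarray]:
    """Design table with one response generated from known coded coefficients.

    By default the run layout mirrors an 18-run two-factor design: all 12
    ratio × polymer combinations plus 6 duplicated settings, so the
    lack-of-fit test has positive pure-error degrees of freedom.  Returns
    the table and the generating coefficient vector (for recovery tests).
    """
    if replicate_map is None:
        replicate_map = {
            (1, POLYMER_LEVELS[0]): 2,
            (2, POLYMER_LEVELS[0]): 2,
            (1, POLYMER_LEVELS[1]): 2,
            (2, POLYMER_LEVELS[1]): 2,
            (2, POLYMER_LEVELS[2]): 2,
            (2, POLYMER_LEVELS[3]): 2,
        }
    rows = []
    for ratio in RATIO_LEVELS:
        for polymer in POLYMER_LEVELS:
            for _ in range(replicate_map.get((ratio, polymer), 1)):
                rows.append({"ratio_parts": ratio, "polymer": polymer})
    runs = pd.DataFrame(rows)
    runs.insert(0, "run", [f"R{i + 1}" for i in range(len(runs))])
    table = DesignTable(runs=runs, responses=[])
    X, _ = encode_design(table, model_order)
    beta = np.asarray(true_coefficients, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(
            f"{model_order} model needs {X.shape[1]} coefficients, got {beta.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    y = X @ beta + rng.normal(0.0, noise_sd, size=X.shape[0])
    runs[response] = y
    return DesignTable(runs=runs, responses=[response]), beta


def gen_xrd_pattern(
    peaks: list[tuple[float, float, float]],
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    two_theta: np.ndarray | None = None,
    label: str = "synthetic",
) -> DiffractionPattern:
    """Sum-of-Gaussians powder pattern on a constant baseline.

    ``peaks`` is a list of (center angle deg, amplitude counts, sigma deg).
    Default grid spans 2–40° 2-theta at 0.02° steps.
    """
    if two_theta is None:
        two_theta = np.arange(2.0, 40.0, 0.02)
    tt = np.asarray(two_theta, dtype=float)
    intensity = np.full_like(tt, float(baseline))
    for center, amplitude, sigma in peaks:
        if not (tt[0] <= center <= tt[-1]):
            raise ValueError(f"peak at {center}° outside the angular range")
        intensity += amplitude * np.exp(-0.5 * ((tt - center) / sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.maximum(intensity + rng.normal(0.0, noise_sd, tt.size), 0.0)
    return DiffractionPattern(label=label, two_theta=tt, intensity=intensity)
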