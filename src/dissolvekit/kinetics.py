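"""Release-kinetics model fitting and mechanism selection.

Three classical release laws are fitted to a cumulative dissolution profile
(percent dissolved Q versus time t in minutes):

* zero order:   Q(t) = K0 * t                 (K0 in %/min)
* first order:  log10(C) = log10(C0) - K*t/2.303, with C = 100 - Q the
                percent remaining             (K in 1/min)
* Higuchi:      Q(t) = K * sqrt(t)            (K in %/min^1/2)

Zero order and Higuchi are intercept-free least squares in the original
percent-dissolved space (the standard release-equation forms).  The first
order model is a linear fit in log-remaining space with a free intercept.

R² is evaluated for all three models in the *original* percent-dissolved
space against the mean-centered total sum of squares, so the models compete
on a common scale; badly mis-specified intercept-free fits can therefore
yield strongly negative R².  The mechanism is chosen by highest R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import DissolutionProfile

__all__ = ["KineticFit", "KineticSelection", "fit_kinetic_model", "select_best_model"]

MODELS = ("zero_order", "first_order", "higuchi")

# percent-remaining floor below which points are unusable for the log fit
FIRST_ORDER_EPSILON = 0.5

LN10 = np.log(10.0)


@dataclass(frozen=True)
class KineticFit:
    model: str
    K: float
    r_squared: float
    n_used: int


@dataclass(frozen=True)
class KineticSelection:
    fits: dict[str, KineticFit]
    chosen: str
    rationale: str = "highest R²"

    @property
    def best(self) -> KineticFit:
        return self.fits[self.chosen]


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_kinetic_model(
    profile: DissolutionProfile,
    model: str,
    epsilon: float = FIRST_ORDER_EPSILON,
    r2_space: str = "observed",
) -> KineticFit:
    """Fit one release law; K and R² (observed-space unless ``r2_space='linearized'``).

    First order drops points with percent remaining <= ``epsilon`` (profiles
    that exceed 100% dissolved make the log argument non-positive) with a
    warning.  Fewer than 3 usable points after exclusions is an error.
    """
    t = profile.times
    q = profile.dissolved
    if model == "zero_order":
        if t.size < 3:
            raise ValueError("need >= 3 points for zero-order fit")
        k = float(np.sum(t * q) / np.sum(t * t))
        pred = k * t
        lin_r2 = _r_squared(q, pred)
        obs_r2 = lin_r2
    elif model == "higuchi":
        if t.size < 3:
            raise ValueError("need >= 3 points for Higuchi fit")
        s = np.sqrt(t)
        k = float(np.sum(s * q) / np.sum(s * s))
        pred = k * s
        lin_r2 = _r_squared(q, pred)
        obs_r2 = lin_r2
    elif model == "first_order":
        remaining = 100.0 - q
        mask = remaining > epsilon
        if mask.sum() < t.size:
            warnings.warn(
                f"{profile.label}: {int((~mask).sum())} point(s) with "
                f"<= {epsilon}% remaining excluded from the first-order fit",
                stacklevel=2,
            )
        if mask.sum() < 3:
            raise ValueError(
                f"fewer than 3 usable points after excluding percent remaining <= {epsilon}"
            )
        logc = np.log10(remaining[mask])
        # variance-weighted: sd(log10 C) ~ sd(C)/(C ln10), so weight by C to
        # keep near-complete points (tiny remaining, huge log noise) from
        # dominating the regression; exact on noiseless data
        slope, intercept = np.polyfit(t[mask], logc, 1, w=remaining[mask])
        k = float(-slope * LN10)  # the conventional 2.303 factor
        pred = 100.0 - 10.0 ** (intercept + slope * t)
        obs_r2 = _r_squared(q, pred)
        lin_r2 = _r_squared(logc, intercept + slope * t[mask])
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    r2 = obs_r2 if r2_space == "observed" else lin_r2
    return KineticFit(model=model, K=k, r_squared=float(r2), n_used=int(t.size))


def select_best_model(profile: DissolutionProfile, **kwargs) -> KineticSelection:
    """Fit all three release laws and select the mechanism by highest R².

    Ties break deterministically in the order zero order → first order →
    Higuchi.
    """
    fits = {m: fit_kinetic_model(profile, m, **kwargs) for m in MODELS}
    chosen = max(MODELS, key=lambda m: (fits[m].r_squared, -MODELS.index(m)))
    return KineticSelection(fits=fits, chosen=chosen)
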