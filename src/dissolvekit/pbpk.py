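"""Mechanistic oral-absorption PBPK simulation with virtual populations.

The model is a transparent compartmental-absorption-and-transit (CAT-style)
oral PBPK: the dose enters the stomach as solid, dissolves at a first-order
rate (taken from the formulation's in-vitro curve via its best first-order
fit, minute-for-minute, or given directly), and both solid and dissolved
material move by first-order gastric emptying into a chain of intestinal
transit compartments.  Dissolved intestinal drug is absorbed at ``ka`` with
pre-systemic survival ``F``; whatever exits the last transit compartment
reaches the colon and is not absorbed (conservative for a low-solubility,
high-permeability acid).  Disposition is one-compartment with
``V = vss * body_weight`` and first-order clearance.

Virtual populations follow a trial-structured design (``n_trials`` trials of
``n_subjects`` each) with log-normal inter-individual variability on
clearance, absorption rate and volume; per-subject random streams derive
from (seed, trial, subject) so any subject is reproducible in isolation.

Compound identity parameters (MW, pKa, logP, B/P, fu) are carried in
:class:`CompoundParams` and echoed in reports for provenance, but the
minimal model's equations use only Vss, CL, body weight and the absorption/
transit constants — they would parameterize a fuller mechanistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import fit_kinetic_model
from .profiles import DissolutionProfile, XYSeries

__all__ = [
    "CompoundParams",
    "FormulationInput",
    "SubjectPhysiology",
    "PopulationSpec",
    "PKParams",
    "PKSummary",
    "SubjectResult",
    "SimResult",
    "diacerein",
    "draw_subject",
    "auc_to_inf",
    "simulate_subject",
    "simulate_population",
    "pk_params",
    "relative_bioavailability",
    "simulated_observed_ratio",
]

LN2 = np.log(2.0)

# fasted-state GI physiology (standard transit-model literature values)
GASTRIC_HALF_LIFE_H = 0.25
SMALL_INTESTINE_TRANSIT_H = 3.32
N_TRANSIT_DEFAULT = 7


@dataclass(frozen=True)
class CompoundParams:
    """Physicochemical and disposition parameters of the compound."""

    molecular_weight: float  # g/mol
    pka: float  # monoprotic acid
    log_p: float
    blood_plasma_ratio: float
    fu: float  # fraction unbound in plasma
    vss: float  # L/kg
    cl: float  # L/h

    def __post_init__(self) -> None:
        for name in ("molecular_weight", "pka", "log_p", "blood_plasma_ratio", "fu", "vss", "cl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fu > 1.0:
            raise ValueError("fu is a fraction and cannot exceed 1")


def diacerein() -> CompoundParams:
    """Literature parameter set for diacerein (anti-osteoarthritic BCS II acid)."""
    return CompoundParams(
        molecular_weight=368.29,
        pka=3.37,
        log_p=2.14,
        blood_plasma_ratio=0.604,
        fu=0.010,
        vss=0.23,
        cl=1.5,
    )


@dataclass(frozen=True)
class FormulationInput:
    """In-vivo release input: an in-vitro profile or a first-order rate.

    Profile mode requires coverage to at least 60 min; the profile's best
    first-order fit provides the in-vivo dissolution rate constant,
    minute-for-minute.
    """

    label: str
    profile: DissolutionProfile | None = None
    k_diss_per_min: float | None = None

    def __post_init__(self) -> None:
        if (self.profile is None) == (self.k_diss_per_min is None):
            raise ValueError("provide exactly one of profile or k_diss_per_min")
        if self.k_diss_per_min is not None and self.k_diss_per_min <= 0:
            raise ValueError("dissolution rate constant must be positive")
        if self.profile is not None and self.profile.times[-1] < 60.0:
            raise ValueError("profile mode requires coverage to >= 60 min")

    @property
    def dissolution_rate_per_h(self) -> float:
        if self.k_diss_per_min is not None:
            return 60.0 * self.k_diss_per_min
        fit = fit_kinetic_model(self.profile, "first_order")
        if fit.K <= 0:
            raise ValueError(f"{self.label}: non-positive first-order rate from profile")
        return 60.0 * fit.K


@dataclass(frozen=True)
class SubjectPhysiology:
    """One virtual subject's GI and disposition scalers."""

    body_weight: float = 81.0  # kg
    gastric_emptying_rate: float = LN2 / GASTRIC_HALF_LIFE_H  # 1/h
    intestinal_transit_rate: float = N_TRANSIT_DEFAULT / SMALL_INTESTINE_TRANSIT_H  # 1/h each
    n_transit: int = N_TRANSIT_DEFAULT
    ka: float = 1.2  # 1/h
    F: float = 0.45  # pre-systemic survival
    cl_multiplier: float = 1.0
    v_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "body_weight",
            "gastric_emptying_rate",
            "intestinal_transit_rate",
            "ka",
            "F",
            "cl_multiplier",
            "v_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.F > 1.0:
            raise ValueError("F is a fraction and cannot exceed 1")
        if self.n_transit < 1:
            raise ValueError("need at least one transit compartment")


@dataclass(frozen=True)
class PopulationSpec:
    """Trial-structured virtual population (default 10 trials x 10 subjects).

    ``group`` selects the physiology template: ``healthy_adult`` (age 40-55,
    weight ~ N(81, 10) kg) or ``geriatric`` (age 65-75, weight ~ N(75, 10) kg,
    clearance scaled by 0.75 for reduced renal function and hepatic mass).
    """

    group: str = "healthy_adult"
    n_trials: int = 10
    n_subjects: int = 10
    dose_mg: float = 50.0
    seed: int = 0
    cv_cl: float = 0.30
    cv_ka: float = 0.30
    cv_v: float = 0.20
    geriatric_cl_scale: float = 0.75
    weight_mean: float | None = None  # kg; defaults by group
    weight_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.group not in ("healthy_adult", "geriatric"):
            raise ValueError("group must be 'healthy_adult' or 'geriatric'")
        if self.n_trials < 1 or self.n_subjects < 1:
            raise ValueError("n_trials and n_subjects must be >= 1")
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")

    @property
    def resolved_weight_mean(self) -> float:
        if self.weight_mean is not None:
            return self.weight_mean
        return 75.0 if self.group == "geriatric" else 81.0


@dataclass(frozen=True)
class PKParams:
    """Noncompartmental parameters of a single plasma curve."""

    cmax: float  # ug/mL
    tmax: float  # h
    auc_0_24: float  # ug/mL * h


@dataclass(frozen=True)
class PKSummary:
    """Across-population summary: mean +/- SD for Cmax and AUC, median Tmax."""

    cmax_mean: float
    cmax_sd: float
    tmax_median: float
    auc_mean: float
    auc_sd: float
    n: int


@dataclass(frozen=True)
class SubjectResult:
    curve: XYSeries  # h vs ug/mL
    pk: PKParams
    physiology: SubjectPhysiology
    mass_balance_error: float  # max |total - dose| / dose over the grid


@dataclass(frozen=True)
class SimResult:
    label: str
    group: str
    subjects: list[SubjectResult]
    summary: PKSummary


def simulate_subject(
    compound: CompoundParams,
    formulation: FormulationInput,
    subject: SubjectPhysiology | None = None,
    dose_mg: float = 50.0,
    grid_h: float = 0.05,
    t_end_h: float = 24.0,
    rtol: float = 1e-8,
) -> SubjectResult:
    """Integrate the oral mass-balance ODEs for one subject.

    State layout (amounts, mg): stomach solid, stomach dissolved, n transit
    solids, n transit dissolved, central amount, then three bookkeeping
    accumulators (eliminated, colon arrival, pre-systemic loss) that make
    total mass conservation checkable at every grid time.
    """
    if subject is None:
        subject = SubjectPhysiology()
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if grid_h > 0.1:
        raise ValueError("grid step must be <= 0.1 h")
    kd = formulation.dissolution_rate_per_h
    kge = subject.gastric_emptying_rate
    kt = subject.intestinal_transit_rate
    ka = subject.ka
    F = subject.F
    n = subject.n_transit
    V = compound.vss * subject.body_weight * subject.v_multiplier  # L
    CL = compound.cl * subject.cl_multiplier  # L/h
    ke = CL / V

    i_sol = slice(2, 2 + n)
    i_dis = slice(2 + n, 2 + 2 * n)
    i_cen, i_elim, i_colon, i_loss = 2 + 2 * n, 3 + 2 * n, 4 + 2 * n, 5 + 2 * n
    n_states = 6 + 2 * n

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n_states)
        st_sol, st_dis = y[0], y[1]
        sol = y[i_sol]
        dis = y[i_dis]
        dy[0] = -(kd + kge) * st_sol
        dy[1] = kd * st_sol - kge * st_dis
        in_sol = np.empty(n)
        in_sol[0] = kge * st_sol
        in_sol[1:] = kt * sol[:-1]
        in_dis = np.empty(n)
        in_dis[0] = kge * st_dis
        in_dis[1:] = kt * dis[:-1]
        dy[i_sol] = in_sol - (kd + kt) * sol
        dy[i_dis] = in_dis + kd * sol - (kt + ka) * dis
        absorbed_flux = ka * dis.sum()
        dy[i_cen] = F * absorbed_flux - ke * y[i_cen]
        dy[i_elim] = ke * y[i_cen]
        dy[i_colon] = kt * (sol[-1] + dis[-1])
        dy[i_loss] = (1.0 - F) * absorbed_flux
        return dy

    y0 = np.zeros(n_states)
    y0[0] = dose_mg
    t_eval = np.arange(0.0, t_end_h + 0.5 * grid_h, grid_h)
    sol = solve_ivp(
        rhs,
        (0.0, t_end_h),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-10 * dose_mg,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"ODE integration failed ({sol.message}); kd={kd:g}/h, ka={ka:g}/h, "
            f"kge={kge:g}/h, kt={kt:g}/h, V={V:g} L, CL={CL:g} L/h"
        )
    total = sol.y.sum(axis=0)
    mb_err = float(np.max(np.abs(total - dose_mg)) / dose_mg)
    conc = sol.y[i_cen] / V  # mg/L == ug/mL
    curve = XYSeries(x=sol.t, y=conc)
    return SubjectResult(
        curve=curve, pk=pk_params(curve), physiology=subject, mass_balance_error=mb_err
    )


def pk_params(curve: XYSeries) -> PKParams:
    """Cmax, earliest Tmax, and linear-trapezoid AUC over the curve's span."""
    if curve.x.size == 0:
        raise ValueError("empty plasma curve")
    i = int(np.argmax(curve.y))
    auc = float(np.trapezoid(curve.y, curve.x))
    return PKParams(cmax=float(curve.y[i]), tmax=float(curve.x[i]), auc_0_24=auc)


def auc_to_inf(curve: XYSeries, ke: float) -> float:
    """Trapezoid AUC plus the standard log-linear tail C_last / ke."""
    if ke <= 0:
        raise ValueError("elimination rate must be positive")
    return float(np.trapezoid(curve.y, curve.x) + curve.y[-1] / ke)


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 log-normal deviate with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def draw_subject(spec: PopulationSpec, trial: int, subject: int) -> SubjectPhysiology:
    """Deterministic per-subject physiology from (seed, trial, subject)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, trial, subject]))
    weight = max(float(rng.normal(spec.resolved_weight_mean, spec.weight_sd)), 40.0)
    cl_mult = _lognormal_multiplier(rng, spec.cv_cl)
    if spec.group == "geriatric":
        cl_mult *= spec.geriatric_cl_scale
    base = SubjectPhysiology()
    return replace(
        base,
        body_weight=weight,
        ka=base.ka * _lognormal_multiplier(rng, spec.cv_ka),
        cl_multiplier=cl_mult,
        v_multiplier=_lognormal_multiplier(rng, spec.cv_v),
    )


def simulate_population(
    compound: CompoundParams,
    formulation: FormulationInput,
    spec: PopulationSpec,
    grid_h: float = 0.05,
) -> SimResult:
    """Simulate all trials x subjects; deterministic given spec.seed."""
    subjects: list[SubjectResult] = []
    for trial in range(spec.n_trials):
        for subj in range(spec.n_subjects):
            phys = draw_subject(spec, trial, subj)
            subjects.append(
                simulate_subject(compound, formulation, phys, spec.dose_mg, grid_h=grid_h)
            )
    cmax = np.array([s.pk.cmax for s in subjects])
    tmax = np.array([s.pk.tmax for s in subjects])
    auc = np.array([s.pk.auc_0_24 for s in subjects])
    summary = PKSummary(
        cmax_mean=float(cmax.mean()),
        cmax_sd=float(cmax.std(ddof=1)) if cmax.size > 1 else 0.0,
        tmax_median=float(np.median(tmax)),
        auc_mean=float(auc.mean()),
        auc_sd=float(auc.std(ddof=1)) if auc.size > 1 else 0.0,
        n=len(subjects),
    )
    return SimResult(label=formulation.label, group=spec.group, subjects=subjects, summary=summary)


def relative_bioavailability(
    test_auc: float, reference_auc: float, rounded: bool = True
) -> float:
    """100 x test AUC / reference AUC, percent (half-even, 2 decimals)."""
    if reference_auc <= 0:
        raise ValueError("reference AUC must be positive")
    pct = 100.0 * test_auc / reference_auc
    return round(pct, 2) if rounded else pct


def simulated_observed_ratio(simulated: float, observed: float, rounded: bool = True) -> float:
    """Model-validation ratio simulated/observed (half-even, 2 decimals)."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    ratio = simulated / observed
    return round(ratio, 2) if rounded else ratio
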