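"""Factorial-design response modeling and desirability optimization.

The design under study crosses a numeric drug:polymer ratio factor (polymer
parts per drug part: 1, 2, 4) with a 4-level categorical polymer-type factor.
Responses (drug content, dissolution efficiencies, mean dissolution time)
are fitted by ordinary least squares on a coded model matrix:

* the numeric factor is affinely mapped onto [-1, +1] over its level range,
* the categorical factor uses sum-to-zero contrasts (intercept = grand mean),
* ``2FI`` adds ratio × polymer interaction columns, ``quadratic`` adds the
  squared ratio term.

ANOVA splits the residual into lack-of-fit and pure error using replicate
groups (runs with identical factor settings).  PRESS uses the hat-matrix
shortcut e_i/(1-h_ii); predicted R² = 1 - PRESS/SStot; adequate precision is
the Design-Expert-style signal-to-noise (max fitted - min fitted) /
sqrt(p*MSE/n).

Multi-response optimization follows Derringer–Suich: per-response linear
desirability ramps over the observed response range, combined by geometric
mean and maximized over the exhaustive grid of candidate factor settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RATIO_LEVELS",
    "POLYMER_LEVELS",
    "RESPONSE_GOALS",
    "DesignTable",
    "ResponseModel",
    "OptimizationResult",
    "load_design",
    "table2_design",
    "encode_design",
    "fit_response_model",
    "desirability_optimize",
]

RATIO_LEVELS: tuple[int, ...] = (1, 2, 4)
POLYMER_LEVELS: tuple[str, ...] = ("PVP K25", "PVP K90", "PEG 4000", "PEG 8000")

# report-table responses and their optimization goals: maximize drug content
# and both dissolution efficiencies, minimize mean dissolution time
RESPONSE_GOALS: dict[str, str] = {
    "dc": "maximize",
    "de15": "maximize",
    "de60": "maximize",
    "mdt": "minimize",
}

MODEL_ORDERS = ("linear", "2FI", "quadratic")


@dataclass(frozen=True)
class DesignTable:
    """Runs of a two-factor formulation design plus measured responses.

    ``runs`` columns: ``run``, ``ratio_parts`` (numeric), ``polymer``
    (categorical), then one column per response.
    """

    runs: pd.DataFrame
    responses: list[str]

    def __post_init__(self) -> None:
        for col in ("run", "ratio_parts", "polymer"):
            if col not in self.runs.columns:
                raise ValueError(f"design table missing column {col!r}")
        bad_polymer = set(self.runs["polymer"]) - set(POLYMER_LEVELS)
        if bad_polymer:
            raise ValueError(f"unknown polymer level(s): {sorted(bad_polymer)}")
        bad_ratio = set(self.runs["ratio_parts"]) - set(RATIO_LEVELS)
        if bad_ratio:
            raise ValueError(f"unknown ratio level(s): {sorted(bad_ratio)}")
        for r in self.responses:
            if r not in self.runs.columns:
                raise ValueError(f"response column {r!r} missing")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def replicate_groups(self) -> list[np.ndarray]:
        """Indices of runs sharing identical factor settings (size >= 2)."""
        groups = self.runs.groupby(["ratio_parts", "polymer"]).indices
        return [np.asarray(ix) for ix in groups.values() if len(ix) >= 2]


def load_design(path: str | Path, responses: list[str] | None = None) -> DesignTable:
    """Read a design CSV (``run,ratio_parts,polymer,<responses...>``)."""
    df = pd.read_csv(path)
    if responses is None:
        responses = [c for c in df.columns if c not in ("run", "ratio_parts", "polymer")]
    return DesignTable(runs=df, responses=responses)


def table2_design() -> DesignTable:
    """The packaged 18-run solid-dispersion design with measured responses."""
    with resources.as_file(
        resources.files("dissolvekit.data").joinpath("sd_design_18run.csv")
    ) as p:
        return load_design(p, responses=list(RESPONSE_GOALS))


def _code_ratio(x: np.ndarray) -> np.ndarray:
    lo, hi = min(RATIO_LEVELS), max(RATIO_LEVELS)
    return (2.0 * np.asarray(x, dtype=float) - (lo + hi)) / (hi - lo)


def _polymer_contrasts(polymer: pd.Series) -> np.ndarray:
    """Sum-to-zero contrast columns (k-1 of them) for the polymer factor."""
    n = len(polymer)
    k = len(POLYMER_LEVELS)
    cols = np.zeros((n, k - 1))
    idx = polymer.map({lev: i for i, lev in enumerate(POLYMER_LEVELS)}).to_numpy()
    for j in range(k - 1):
        cols[idx == j, j] = 1.0
        cols[idx == k - 1, j] = -1.0
    return cols


def _encode_rows(
    ratio_parts: np.ndarray, polymer: pd.Series, model_order: str
) -> tuple[np.ndarray, list[str]]:
    a = _code_ratio(np.asarray(ratio_parts))
    b = _polymer_contrasts(polymer)
    cols = [np.ones(a.size), a] + [b[:, j] for j in range(b.shape[1])]
    names = ["intercept", "A"] + [f"B{j + 1}" for j in range(b.shape[1])]
    if model_order in ("2FI", "quadratic"):
        for j in range(b.shape[1]):
            cols.append(a * b[:, j])
            names.append(f"A:B{j + 1}")
    if model_order == "quadratic":
        cols.append(a**2)
        names.append("A^2")
    return np.column_stack(cols), names


def encode_design(table: DesignTable, model_order: str) -> tuple[np.ndarray, list[str]]:
    """Coded model matrix (with intercept) and its column names."""
    if model_order not in MODEL_ORDERS:
        raise ValueError(f"model_order must be one of {MODEL_ORDERS}")
    if model_order == "quadratic" and len(set(table.runs["ratio_parts"])) < 3:
        raise ValueError("quadratic model needs >= 3 numeric factor levels")
    return _encode_rows(
        table.runs["ratio_parts"].to_numpy(), table.runs["polymer"], model_order
    )


@dataclass(frozen=True)
class ResponseModel:
    """OLS response surface with the fit statistics of a DoE report."""

    response: str
    model_order: str
    coefficients: dict[str, float]
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adequate_precision: float
    model_f: float
    model_p: float
    lof_f: float | None
    lof_p: float | None
    pure_error_df: int
    _table: DesignTable = field(repr=False, compare=False)

    def predict(self, ratio_parts: float, polymer: str) -> float:
        X, _ = _encode_rows(
            np.array([ratio_parts]), pd.Series([polymer]), self.model_order
        )
        beta = np.array(list(self.coefficients.values()))
        return float((X @ beta)[0])


def fit_response_model(
    table: DesignTable, response: str, model_order: str = "quadratic"
) -> ResponseModel:
    """Fit one response on the coded design and compute its report statistics."""
    if response not in table.runs.columns:
        raise ValueError(f"unknown response {response!r}")
    X, names = encode_design(table, model_order)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"{n} runs cannot support a {p}-term model")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"singular coded matrix: {p - rank} aliased column(s) among {names}")
    y = table.runs[response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    fitted = fit.fittedvalues
    h = fit.get_influence().hat_matrix_diag

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    ss_model = ss_tot - ss_res
    df_model, df_res = p - 1, n - p
    mse = ss_res / df_res if df_res > 0 else np.nan
    model_f = (ss_model / df_model) / mse if df_res > 0 else np.inf
    model_p = float(stats.f.sf(model_f, df_model, df_res)) if df_res > 0 else 0.0

    # lack-of-fit: pure error from replicate groups
    ss_pe, df_pe = 0.0, 0
    for ix in table.replicate_groups():
        yg = y[ix]
        ss_pe += float(np.sum((yg - yg.mean()) ** 2))
        df_pe += len(ix) - 1
    lof_f = lof_p = None
    if df_pe > 0 and df_res - df_pe > 0:
        ss_lof = max(ss_res - ss_pe, 0.0)
        df_lof = df_res - df_pe
        if ss_pe > 0:
            lof_f = (ss_lof / df_lof) / (ss_pe / df_pe)
            lof_p = float(stats.f.sf(lof_f, df_lof, df_pe))

    press = float(np.sum((resid / (1.0 - h)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / (n - 1)) if df_res > 0 else np.nan
    pred_r2 = 1.0 - press / ss_tot if ss_tot > 0 else np.nan
    adequate_precision = (
        float((fitted.max() - fitted.min()) / np.sqrt(p * mse / n)) if mse > 0 else np.inf
    )
    return ResponseModel(
        response=response,
        model_order=model_order,
        coefficients=dict(zip(names, fit.params)),
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        adequate_precision=adequate_precision,
        model_f=float(model_f),
        model_p=model_p,
        lof_f=lof_f,
        lof_p=lof_p,
        pure_error_df=df_pe,
        _table=table,
    )


@dataclass(frozen=True)
class OptimizationResult:
    ratio_parts: float
    polymer: str
    predictions: dict[str, float]
    desirabilities: dict[str, float]
    overall_desirability: float


def desirability_optimize(
    models: dict[str, ResponseModel],
    goals: dict[str, str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> OptimizationResult:
    """Derringer–Suich optimum over the exhaustive factor-level grid.

    Per-response desirability is a linear ramp between bounds L and T
    (default: the observed response min/max in the fitted design):
    maximize → (y-L)/(T-L), minimize → (T-y)/(T-L), clipped to [0, 1].
    The overall desirability is the geometric mean (importance weights 1);
    it is 0 iff any single desirability is 0.  Ties break by candidate
    order (ratio levels outer, polymer levels inner).
    """
    if goals is None:
        goals = {r: RESPONSE_GOALS[r] for r in models}
    if set(goals) != set(models):
        raise ValueError("goals and models must cover the same responses")
    table = next(iter(models.values()))._table
    resolved_bounds: dict[str, tuple[float, float]] = {}
    for r in models:
        if bounds and r in bounds:
            lo, hi = bounds[r]
        else:
            y = table.runs[r].to_numpy(dtype=float)
            lo, hi = float(y.min()), float(y.max())
        if lo == hi:
            raise ValueError(f"degenerate desirability bounds for {r!r} (L == T)")
        resolved_bounds[r] = (lo, hi)

    best: OptimizationResult | None = None
    for ratio in RATIO_LEVELS:
        for polymer in POLYMER_LEVELS:
            preds, ds = {}, {}
            for r in sorted(models):  # response order must not matter
                yhat = models[r].predict(ratio, polymer)
                lo, hi = resolved_bounds[r]
                d = (yhat - lo) / (hi - lo) if goals[r] == "maximize" else (hi - yhat) / (hi - lo)
                preds[r] = yhat
                ds[r] = float(np.clip(d, 0.0, 1.0))
            dv = np.array(list(ds.values()))
            overall = 0.0 if np.any(dv == 0.0) else float(np.exp(np.mean(np.log(dv))))
            cand = OptimizationResult(
                ratio_parts=float(ratio),
                polymer=polymer,
                predictions=preds,
                desirabilities=ds,
                overall_desirability=overall,
            )
            if best is None or cand.overall_desirability > best.overall_desirability:
                best = cand
    assert best is not None
    return best
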