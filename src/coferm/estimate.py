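"""Two-stage kinetic parameter estimation and analytic threshold helpers.

Stage one linearises the Monod equation as a double-reciprocal
(Lineweaver-Burk) plot of log-phase growth rates to initialise ``mu_m`` and
``Ks``.  Stage two refines the remaining parameters by least squares: the
model trajectories are interpolated to the data sampling times and the
residuals over biomass, sugars and ethanol are pooled, unweighted, in g/L.
Refinement uses a derivative-based trust-region least-squares scheme (via
lmfit) with optional seeded multi-start to guard against local minima.

The module also carries the sensitivity comparison of substrate-inhibition
model variants and the back-of-envelope thresholds relating critical
ethanol concentrations to the sugar loads that would reach them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd

from .kinetics import (
    StrainKinetics,
    Trajectory,
    YPS_THEORETICAL_MAX,
)
from .simulate import SimOptions, simulate_monoculture

__all__ = [
    "GrowthPoint",
    "FitResult",
    "EstimationError",
    "lineweaver_burk",
    "residuals",
    "pooled_rmse",
    "truncate_at_plateau",
    "fit_parameters",
    "compare_variants",
    "inhibition_thresholds",
    "theoretical_yield_fraction",
    "GLUCOSE_EQUIVALENT_YIELD",
]

#: Theoretical ethanol yield on a glucose-equivalent basis (g/g); the
#: reference for "percent of theoretical yield" statements.
GLUCOSE_EQUIVALENT_YIELD = 0.511


class EstimationError(ValueError):
    """Raised when an estimator receives degenerate input."""


@dataclass(frozen=True)
class GrowthPoint:
    """One log-phase observation: initial sugar S (g/L), growth rate mu (/h)."""

    S: float
    mu: float

    def __post_init__(self) -> None:
        if self.S <= 0 or self.mu <= 0:
            raise ValueError("GrowthPoint requires S > 0 and mu > 0")


def lineweaver_burk(points: Sequence[GrowthPoint]) -> Tuple[float, float]:
    """Estimate (mu_m, Ks) from growth points by double-reciprocal regression.

    Ordinary least squares of 1/mu on 1/S; mu_m = 1/intercept and
    Ks = slope/intercept.  With exactly two points this is the exact
    two-point solve.
    """
    if len(points) < 2:
        raise EstimationError("need at least two growth points")
    S = np.array([p.S for p in points])
    mu = np.array([p.mu for p in points])
    if len(np.unique(S)) < 2:
        raise EstimationError("growth points must span at least two distinct "
                              "substrate concentrations")
    slope, intercept = np.polyfit(1.0 / S, 1.0 / mu, 1)
    if intercept <= 0:
        raise EstimationError(
            f"nonpositive double-reciprocal intercept ({intercept:.4g}); "
            "data inconsistent with Monod saturation")
    mu_m = 1.0 / intercept
    Ks = slope / intercept
    return float(mu_m), float(Ks)


_OBS_COLUMNS = ("biomass_gdcw_L", "cellobiose_g_L", "xylose_g_L",
                "ethanol_g_L")


def _active_columns(data: Trajectory, model: Trajectory) -> List[str]:
    """Biomass and ethanol always; a sugar only if either series carries it."""
    cols = ["biomass_gdcw_L", "ethanol_g_L"]
    for sugar in ("cellobiose_g_L", "xylose_g_L"):
        if np.any(data.column(sugar) > 0) or np.any(model.column(sugar) > 0):
            cols.append(sugar)
    return cols


def residuals(model_traj: Trajectory, data: Trajectory) -> np.ndarray:
    """Pooled residual vector (g/L): model interpolated to the data times.

    Residuals are stacked over biomass, sugar(s) and ethanol, unweighted.
    A sugar column that is identically zero in both series (the unused
    sugar of a monoculture) is excluded from the pool.
    """
    if len(data) == 0:
        raise EstimationError("empty data trajectory")
    t_data = data.t
    t_model = model_traj.t
    if t_data[0] < t_model[0] - 1e-9 or t_data[-1] > t_model[-1] + 1e-9:
        raise EstimationError("data times fall outside the model trajectory")
    res = []
    for col in _active_columns(data, model_traj):
        predicted = np.interp(t_data, t_model, model_traj.column(col))
        res.append(predicted - data.column(col))
    return np.concatenate(res)


def pooled_rmse(residual_vector: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(residual_vector))))


def truncate_at_plateau(traj: Trajectory, sugar_column: str = "xylose_g_L",
                        delta: float = 0.1) -> Trajectory:
    """Drop samples after the sugar levels off.

    The plateau is the first point where the concentration change over two
    consecutive samples stays below ``delta`` g/L; later samples are
    excluded (the xylose model does not describe the post-plateau phase,
    where ethanol re-assimilation takes over).
    """
    S = traj.column(sugar_column)
    if len(S) < 3:
        return traj
    dS = np.abs(np.diff(S))
    flat = (dS[:-1] < delta) & (dS[1:] < delta)
    idx = np.argmax(flat)
    if not flat[idx]:
        return traj
    cut = idx + 1  # keep samples up to and including the plateau onset
    return Trajectory(traj.data.iloc[: cut + 1].reset_index(drop=True),
                      provenance=traj.provenance, replicate=traj.replicate)


@dataclass
class FitResult:
    """Estimated kinetics with least-squares diagnostics."""

    kinetics: StrainKinetics
    free: Tuple[str, ...]
    fixed: Dict[str, Optional[float]]
    rss: float
    rmse: float
    rmse_per_variable: Dict[str, float]
    n_obs: int
    n_eval: int
    converged: bool
    bound_hits: Dict[str, bool] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("RSS must be >= 0")


_DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "mu_m": (1e-4, 2.0),
    "Ks": (1e-3, 500.0),
    "Ki": (1.0, 5000.0),
    "Pm": (1.0, 500.0),
    "beta": (0.05, 10.0),
    "m": (0.0, 1.0),
    "Yps": (0.01, YPS_THEORETICAL_MAX),
    "Yxs": (0.01, 2.0),
    "b1": (0.1, 10.0),
    "b2": (0.1, 10.0),
    "vm": (1e-4, 5.0),
    "Ksp": (1e-3, 500.0),
    "Kip": (1.0, 5000.0),
    "Pmp": (1.0, 500.0),
    "gamma": (0.05, 10.0),
    "a_s0": (0.0, 0.1),
}

#: Fallback starting values for constants absent from the starting kinetics
#: (used when a variant re-introduces a structurally omitted term).
_DEFAULT_STARTS = {"Ki": 200.0, "Kip": 100.0}

_FIT_OPTS = SimOptions(rtol=1e-7, atol=1e-9)


def _initial_conditions(traj: Trajectory) -> Tuple[float, float, float]:
    """(S0, X0, P0) read off the first sample; the nonzero sugar is used."""
    S_c = float(traj.column("cellobiose_g_L")[0])
    S_x = float(traj.column("xylose_g_L")[0])
    S0 = S_c if S_c >= S_x else S_x
    return S0, float(traj.column("biomass_gdcw_L")[0]), \
        float(traj.column("ethanol_g_L")[0])


def _simulate_for(k: StrainKinetics, S0: float, X0: float, P0: float,
                  t_end: float, sugar: str) -> Trajectory:
    opts = SimOptions(rtol=_FIT_OPTS.rtol, atol=_FIT_OPTS.atol,
                      t_end=max(t_end, _FIT_OPTS.grid_dt))
    return simulate_monoculture(k, S0, X0, P0, opts=opts, sugar=sugar)


def _pooled_residuals(k: StrainKinetics, data: Sequence[Trajectory],
                      conds: Sequence[Tuple[float, float, float]],
                      sugar: str) -> np.ndarray:
    parts = []
    for traj, (S0, X0, P0) in zip(data, conds):
        model = _simulate_for(k, S0, X0, P0, float(traj.t[-1]), sugar)
        parts.append(residuals(model, traj))
    return np.concatenate(parts)


def fit_parameters(data: Sequence[Trajectory], k0: StrainKinetics,
                   free: Iterable[str],
                   bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
                   initial_conditions: Optional[Sequence[Tuple[float, float, float]]] = None,
                   sugar: str = "auto",
                   multi_start: int = 1, seed: int = 0) -> FitResult:
    """Least-squares refinement of the free parameters from the k0 start.

    Parameters not in ``free`` stay fixed (the growth constants from the
    double-reciprocal plot, the literature yield and the experimental
    critical ethanol concentrations are typically fixed).  ``bounds``
    overrides the built-in per-parameter intervals.  ``multi_start`` > 1
    restarts the optimiser from seeded log-uniform perturbations of k0 and
    keeps the best optimum.  ``initial_conditions`` supplies the true
    (S0, X0, P0) design values per trajectory; by default they are read off
    each trajectory's first (possibly noisy) sample.
    """
    data = list(data)
    if not data:
        raise EstimationError("no data trajectories given")
    free = tuple(dict.fromkeys(free))
    valid = set(StrainKinetics.field_names())
    unknown = set(free) - valid
    if unknown:
        raise EstimationError(f"unknown free parameters: {sorted(unknown)}")
    if sugar == "auto":
        sugar = "xylose" if k0.name.upper().startswith("SR") else "cellobiose"
    conds = ([_initial_conditions(traj) for traj in data]
             if initial_conditions is None else list(initial_conditions))
    if len(conds) != len(data):
        raise EstimationError("one (S0, X0, P0) tuple per trajectory required")

    bounds = dict(bounds or {})

    def make_params(start: StrainKinetics) -> lmfit.Parameters:
        params = lmfit.Parameters()
        for name in free:
            value = getattr(start, name)
            if value is None:
                value = _DEFAULT_STARTS.get(name, 1.0)
            lo, hi = bounds.get(name, _DEFAULT_BOUNDS[name])
            params.add(name, value=float(np.clip(value, lo, hi)),
                       min=lo, max=hi)
        return params

    def build(params: lmfit.Parameters) -> StrainKinetics:
        return k0.with_updates(**{name: params[name].value for name in free})

    def objective(params: lmfit.Parameters) -> np.ndarray:
        return _pooled_residuals(build(params), data, conds, sugar)

    rng = np.random.default_rng(seed)
    best = None
    n_eval = 0
    for attempt in range(max(1, multi_start)):
        start = k0
        if attempt > 0:
            jitter = {}
            for name in free:
                value = getattr(k0, name)
                if value is None:
                    value = _DEFAULT_STARTS.get(name, 1.0)
                jitter[name] = value * float(np.exp(rng.uniform(-0.7, 0.7)))
            start = k0.with_updates(**{n: v for n, v in jitter.items()
                                       if getattr(k0, n) is not None})
        try:
            result = lmfit.minimize(objective, make_params(start),
                                    method="least_squares",
                                    xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception:
            continue
        n_eval += result.nfev
        if best is None or result.chisqr < best.chisqr:
            best = result

    if best is None:
        raise EstimationError("least-squares refinement failed to start")

    k_fit = build(best.params)
    res_vec = _pooled_residuals(k_fit, data, conds, sugar)
    rss = float(np.sum(np.square(res_vec)))
    per_var: Dict[str, float] = {}
    for col in _active_columns(data[0], _simulate_for(
            k_fit, *conds[0], float(data[0].t[-1]), sugar)):
        parts = []
        for traj, (S0, X0, P0) in zip(data, conds):
            model = _simulate_for(k_fit, S0, X0, P0, float(traj.t[-1]), sugar)
            predicted = np.interp(traj.t, model.t, model.column(col))
            parts.append(predicted - traj.column(col))
        per_var[col] = pooled_rmse(np.concatenate(parts))
    bound_hits = {}
    for name in free:
        lo, hi = bounds.get(name, _DEFAULT_BOUNDS[name])
        value = best.params[name].value
        span = hi - lo
        bound_hits[name] = bool(value - lo < 1e-6 * span or
                                hi - value < 1e-6 * span)
    fixed = {name: getattr(k0, name) for name in StrainKinetics.field_names()
             if name not in free}
    return FitResult(
        kinetics=k_fit, free=free, fixed=fixed, rss=rss,
        rmse=pooled_rmse(res_vec), rmse_per_variable=per_var,
        n_obs=len(res_vec), n_eval=n_eval,
        converged=bool(best.success), bound_hits=bound_hits, seed=seed)


_VARIANTS = {
    "with Ki & Kip": {"Ki": True, "Kip": True},
    "without Ki": {"Ki": False, "Kip": True},
    "without Kip": {"Ki": True, "Kip": False},
    "without both": {"Ki": False, "Kip": False},
}

#: RMSE resolution (g/L) used when ranking model variants; ties at this
#: resolution are broken in favour of the variant with fewer free parameters.
_RMSE_RESOLUTION = 1e-4


def compare_variants(data: Sequence[Trajectory], k0: StrainKinetics,
                     variants: Optional[Sequence[str]] = None,
                     free_base: Sequence[str] = ("vm", "Ksp", "Pmp", "gamma"),
                     **fit_kwargs) -> pd.DataFrame:
    """Fit substrate-inhibition model variants and rank them by pooled RMSE.

    Each variant structurally includes or omits the growth (Ki) and
    production (Kip) substrate-inhibition constants; an included constant is
    fitted (with a generic start if k0 omits it).  Rows are sorted by RMSE
    at a fixed resolution, preferring fewer free parameters on ties, so
    that on data generated without substrate inhibition the leaner model
    family wins even though the richer families nest it.
    """
    if not list(data):
        raise EstimationError("no data trajectories given")
    names = list(variants) if variants is not None else list(_VARIANTS)
    unknown = set(names) - set(_VARIANTS)
    if unknown:
        raise EstimationError(f"unknown variants: {sorted(unknown)}")
    rows = []
    for name in names:
        structure = _VARIANTS[name]
        k_start = k0.with_updates(
            Ki=(k0.Ki or _DEFAULT_STARTS["Ki"]) if structure["Ki"] else None,
            Kip=(k0.Kip or _DEFAULT_STARTS["Kip"]) if structure["Kip"] else None,
        )
        free = list(free_base)
        if structure["Ki"]:
            free.append("Ki")
        if structure["Kip"]:
            free.append("Kip")
        fit = fit_parameters(data, k_start, free, **fit_kwargs)
        rows.append({"variant": name, "rmse": fit.rmse, "rss": fit.rss,
                     "n_free": len(free), "converged": fit.converged})
    table = pd.DataFrame(rows)
    table["_rank_rmse"] = (table["rmse"] / _RMSE_RESOLUTION).round()
    table = (table.sort_values(["_rank_rmse", "n_free"])
             .drop(columns="_rank_rmse").reset_index(drop=True))
    return table


def inhibition_thresholds(k: StrainKinetics, Pm_exp: float,
                          Yps_basis: float) -> Tuple[float, Optional[float]]:
    """Sugar loads whose full conversion reaches the critical ethanol levels.

    Complete conversion of an initial load S0 at yield ``Yps_basis``
    produces ``S0 * Yps_basis`` ethanol, so growth stops for loads above
    ``Pm_exp / Yps_basis`` and production above ``Pmp / Yps_basis``.
    ``Pm_exp`` is the experimentally observed growth-arrest ethanol
    concentration (which can differ from the fitted Pm).
    """
    if Pm_exp <= 0 or Yps_basis <= 0:
        raise ValueError("Pm_exp and Yps_basis must be > 0")
    S_growth = Pm_exp / Yps_basis
    S_production = k.Pmp / Yps_basis if k.Pmp is not None else None
    return S_growth, S_production


def theoretical_yield_fraction(Yps: float,
                               basis: float = GLUCOSE_EQUIVALENT_YIELD) -> float:
    """Ethanol yield as a percentage of a theoretical basis yield."""
    if Yps <= 0 or basis <= 0:
        raise ValueError("yields must be > 0")
    return 100.0 * Yps / basis
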