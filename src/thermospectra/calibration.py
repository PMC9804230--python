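"""Calibration of maximum recruitment and consumption to target data.

The maximum-recruitment caps are fitted by minimising the residual sum
of squares between log steady-state spawning stock biomass and log
targets (window averages at window-mean fishing mortality, reference
temperature), optimising in log10 parameter space with L-BFGS-B and
numerical gradients on the steady-state map.  The maximum-consumption
coefficient can afterwards be tuned by a stepwise multiplicative search
against weight-at-age targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import Model, ModelState, SpeciesParams, WeightGrid, maturity_ogive
from .dynamics_engine import SolverConfig, run_to_steady, ssb_of

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationTargets",
    "FitReport",
    "ssb",
    "calibrate_rmax",
    "tune_h_to_growth",
    "density_dependence_ratio",
]


@dataclass
class CalibrationTargets:
    """Window-averaged SSB targets with matching mean fishing mortality
    and optional weight-at-age growth targets."""

    ssb: dict[str, float]
    f_bar: dict[str, float]
    growth: pd.DataFrame | None = None  # columns: species, age, weight
    ssb_series: pd.DataFrame | None = None  # columns: species, year, ssb, f

    def __post_init__(self) -> None:
        if not self.ssb:
            raise ValueError("empty target set")
        if any(v <= 0 for v in self.ssb.values()):
            raise ValueError("SSB targets must be positive")

    @classmethod
    def from_series(cls, frame: pd.DataFrame, window: tuple[int, int] | None = None) -> "CalibrationTargets":
        """Window-average a (species, year, ssb, f) table."""
        df = frame.copy()
        if window is not None:
            df = df[(df["year"] >= window[0]) & (df["year"] <= window[1])]
        if df.empty:
            raise ValueError("calibration window is empty")
        agg = df.groupby("species").agg(ssb=("ssb", "mean"), f=("f", "mean"))
        return cls(
            ssb=agg["ssb"].to_dict(),
            f_bar=agg["f"].to_dict(),
            ssb_series=frame,
        )


@dataclass
class FitReport:
    rmax: dict[str, float]
    log10_rmax: np.ndarray
    objective: float
    n_eval: int
    converged: bool
    coexistence: bool
    message: str = ""

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.rmax),
                "rmax": list(self.rmax.values()),
                "log10_rmax": self.log10_rmax,
            }
        )


def ssb(state: ModelState, grid: WeightGrid, sp: SpeciesParams, species_index: int) -> float:
    """Spawning stock biomass: maturity-ogive-weighted biomass integral."""
    sl = grid.span(sp.name)
    w, dw = grid.w[sl], grid.dw[sl]
    return float(np.sum(maturity_ogive(w, sp) * state.N[species_index, sl] * w * dw))


def density_dependence_ratio(R_phy: float, R: float) -> float:
    """Ratio of physiological to realised recruitment (>= 1)."""
    if R <= 0:
        raise ValueError("realised recruitment must be positive")
    return R_phy / R


_LN_FLOOR = 1e-30  # SSB floor; an extinct species contributes a huge residual


def calibrate_rmax(
    model: Model,
    targets: CalibrationTargets,
    bounds: tuple[float, float] = (2.0, 14.0),
    solver: SolverConfig | None = None,
    T: float | None = None,
    maxiter: int = 60,
    eps: float = 1e-3,
) -> FitReport:
    """Fit per-species log10 maximum recruitment to log-SSB targets.

    Runs the model to steady state at the targets' mean fishing
    mortality for every candidate, warm-starting each run from the
    previous steady state.  Fails with a calibration report (not an
    exception) when no coexisting optimum is found.
    """
    if bounds[0] >= bounds[1]:
        raise ValueError("infeasible bounds: lower >= upper")
    solver = solver or SolverConfig(steady_tol=1e-5)
    names = [sp.name for sp in model.species]
    missing = [n for n in names if n not in targets.ssb]
    if missing:
        raise ValueError(f"targets missing species {missing}")
    F = np.array([targets.f_bar[n] for n in names])
    ln_targets = np.log(np.array([targets.ssb[n] for n in names]))
    if T is None:
        T = 283.15

    cache = {"state": model.initial_state(T=T), "n_eval": 0}

    def objective(x: np.ndarray) -> float:
        for sp, lx in zip(model.species, x):
            sp.Rmax = 10.0**lx
        cache["n_eval"] += 1
        try:
            state, _ = run_to_steady(cache["state"], model, solver, F=F, T=T)
        except (ZeroDivisionError, FloatingPointError):
            # infeasible region (e.g. resource collapse starves recruits)
            cache["state"] = model.initial_state(T=T)
            return 1e6 + float(np.sum(x**2))
        cache["state"] = state
        s = ssb_of(state, model)
        resid = np.log(np.maximum(s, _LN_FLOOR)) - ln_targets
        return float(np.sum(resid**2))

    x0 = np.log10(np.array([sp.Rmax for sp in model.species]))
    x0 = np.clip(x0, bounds[0], bounds[1])
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[bounds] * len(names),
        options={"maxiter": maxiter, "eps": eps, "ftol": 1e-12, "gtol": 1e-10},
    )
    # re-evaluate at the optimum so the model carries the fitted values
    final_obj = objective(res.x)
    final_ssb = ssb_of(cache["state"], model)
    coexist = bool(np.all(final_ssb > 0))
    if not coexist:
        logger.warning("calibration optimum loses species: SSB=%s", final_ssb)
    return FitReport(
        rmax={n: 10.0**lx for n, lx in zip(names, res.x)},
        log10_rmax=res.x.copy(),
        objective=final_obj,
        n_eval=cache["n_eval"],
        converged=bool(res.success),
        coexistence=coexist,
        message=str(res.message),
    )


def tune_h_to_growth(
    model: Model,
    growth_targets: pd.DataFrame,
    step_factor: float = 1.1,
    max_iterations: int = 12,
    solver: SolverConfig | None = None,
    T: float | None = None,
) -> dict[str, float]:
    """Stepwise multiplicative adjustment of the maximum-consumption
    coefficient against weight-at-age targets.

    Per species, a deterministic line search multiplies/divides h by
    ``step_factor`` while the squared log error of emergent weight-at-age
    improves.  Returns the adjusted h per species (model updated in
    place).  ``max_iterations == 0`` returns the initial values with a
    warning.
    """
    from .scenario_pipeline import size_at_age  # local import avoids a cycle

    solver = solver or SolverConfig()
    if max_iterations == 0:
        import warnings

        warnings.warn("max_iterations=0: returning initial h unchanged")
        return {sp.name: sp.h for sp in model.species}
    if T is None:
        T = 283.15

    def sse_for_species(i: int, state: ModelState) -> float:
        sp = model.species[i]
        tgt = growth_targets[growth_targets["species"] == sp.name]
        if tgt.empty:
            return 0.0
        ages = tgt["age"].to_numpy(dtype=float)
        w_tgt = tgt["weight"].to_numpy(dtype=float)
        w_mod = size_at_age(model, state, i, ages)
        good = w_tgt > 0
        return float(np.sum((np.log(np.maximum(w_mod[good], 1e-12)) - np.log(w_tgt[good])) ** 2))

    state, _ = run_to_steady(model.initial_state(T=T), model, solver, T=T)
    out = {}
    for i, sp in enumerate(model.species):
        best_h = sp.h
        best = sse_for_species(i, state)
        for direction in (step_factor, 1.0 / step_factor):
            h = best_h
            for _ in range(max_iterations):
                sp.h = h * direction
                trial_state, _ = run_to_steady(state, model, solver, T=T)
                val = sse_for_species(i, trial_state)
                if val < best - 1e-12:
                    best, h, state = val, sp.h, trial_state
                else:
                    break
            sp.h = h
            best_h = h
        out[sp.name] = best_h
    return out
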