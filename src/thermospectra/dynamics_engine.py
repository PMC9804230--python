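"""Time integration of the coupled size-spectrum and resource dynamics.

The fish spectra follow a transport equation in body weight with
food-dependent growth as the advection speed and total mortality as the
sink; it is discretized with a first-order upwind scheme, implicit in
weight (bidiagonal solve).  Resources follow semi-chemostat dynamics
with a semi-implicit exponential-decay update.  Recruitment enters as a
number flux through the egg-weight boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .model_core import Model, ModelState, Rates, WeightGrid, maturity_ogive
from .thermal import ThermalConfig, ActivationDraw, scale_physiology, scale_resource

__all__ = [
    "SolverConfig",
    "Forcing",
    "SimOutput",
    "step_fish",
    "step_resource",
    "project",
    "run_to_steady",
]


@dataclass
class SolverConfig:
    dt: float = 0.1
    t_max: float = 200.0
    scheme: str = "upwind-implicit"
    steady_tol: float = 1e-4
    steady_window: float = 10.0  # years over which SSB change is measured

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be > 0")


@dataclass
class Forcing:
    """Annual forcing: per-species F and temperature, held piecewise
    constant within years.  Years are relative model years starting at 0
    unless an explicit year index is given."""

    F: np.ndarray  # (n_years, n_species)
    T: np.ndarray  # (n_years,)
    year0: float = 0.0
    years: np.ndarray | None = None  # optional explicit year labels

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.T = np.asarray(self.T, dtype=float)
        if self.F.shape[0] != self.T.size:
            raise ValueError("F and T must cover the same years")
        if self.years is not None:
            self.years = np.asarray(self.years, dtype=float)
            if self.years.size != self.T.size:
                raise ValueError("years must match forcing length")
            if np.any(np.diff(self.years) <= 0):
                raise ValueError("forcing years must be strictly increasing")
            self.year0 = float(self.years[0])

    @classmethod
    def constant(cls, F: np.ndarray, T: float, n_years: int) -> "Forcing":
        F = np.asarray(F, dtype=float)
        return cls(F=np.tile(F, (n_years, 1)), T=np.full(n_years, T))

    def at(self, t: float) -> tuple[np.ndarray, float]:
        idx = int(np.clip(np.floor(t - self.year0 + 1e-9), 0, self.T.size - 1))
        return self.F[idx], float(self.T[idx])


@dataclass
class SimOutput:
    """Annual summaries plus the final state of a projection."""

    time: np.ndarray
    ssb: np.ndarray  # (n_t, S)
    yield_: np.ndarray  # (n_t, S)
    r_phy: np.ndarray  # (n_t, S)
    recruitment: np.ndarray  # (n_t, S)
    temperature: np.ndarray  # (n_t,)
    final_state: ModelState
    final_rates: Rates
    species: list[str]
    converged: bool | None = None
    spectra: np.ndarray | None = None  # optional (n_t, S, nw)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.time):
            for i, name in enumerate(self.species):
                rows.append(
                    {
                        "time": t,
                        "species": name,
                        "ssb": self.ssb[k, i],
                        "yield": self.yield_[k, i],
                        "r_phy": self.r_phy[k, i],
                        "recruitment": self.recruitment[k, i],
                        "temperature": self.temperature[k],
                    }
                )
        return pd.DataFrame(rows)

    def spectra_frame(self, grid: WeightGrid) -> pd.DataFrame:
        if self.spectra is None:
            raise ValueError("spectra were not recorded")
        n_t, S, nw = self.spectra.shape
        frames = []
        for k, t in enumerate(self.time):
            for i, name in enumerate(self.species):
                frames.append(
                    pd.DataFrame(
                        {
                            "time": t,
                            "species": name,
                            "w": grid.w,
                            "density": self.spectra[k, i],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Elementary steps
# ---------------------------------------------------------------------------


def _advance_species(
    N: np.ndarray, g: np.ndarray, mu: np.ndarray, R: float, dw: np.ndarray, dt: float
) -> np.ndarray:
    """One implicit upwind step for a single species on its own span.

    Boundary: the egg-weight density carries the recruitment number flux,
    N[0] = R / g[0].
    """
    n = N.size
    if g[0] <= 0.0:
        if R > 0.0:
            raise ZeroDivisionError(
                "zero growth at the egg weight with positive recruitment"
            )
        boundary = N[0] / (1.0 + dt * mu[0]) if g[0] == 0.0 else 0.0
    else:
        boundary = R / g[0]
    diag = 1.0 + dt * mu + dt * g / dw
    sub = -dt * g[:-1] / dw[1:]
    rhs = N.copy()
    # impose the boundary value via the first row
    ab = np.zeros((2, n))
    ab[0, :] = diag
    ab[0, 0] = 1.0
    ab[1, :-1] = sub
    ab[1, 0] = sub[0]
    rhs[0] = boundary
    out = solve_banded((1, 0), ab, rhs)
    return np.maximum(out, 0.0)


def step_fish(
    state: ModelState, rates: Rates, grid: WeightGrid, dt: float, model: Model
) -> ModelState:
    """Advance all fish spectra by one implicit upwind step."""
    N_new = state.N.copy()
    for i, sp in enumerate(model.species):
        sl = grid.span(sp.name)
        N_new[i, sl] = _advance_species(
            state.N[i, sl],
            rates.g[i, sl],
            rates.mu[i, sl],
            float(rates.R[i]),
            grid.dw[sl],
            dt,
        )
    return ModelState(N=N_new, NR=state.NR, t=state.t + dt, T=state.T)


def step_resource(
    state: ModelState,
    mu_pre_R: np.ndarray,
    model: Model,
    dt: float,
    resource_factors: tuple[float, float] = (1.0, 1.0),
) -> ModelState:
    """Semi-implicit semi-chemostat update of all resource spectra.

    ``resource_factors`` are the (r0, kappa) temperature multipliers.
    """
    fr, fk = resource_factors
    NR_new = state.NR.copy()
    for j, r in enumerate(model.resources):
        sl = model.grid.span(r.name)
        rate = fr * model._r_rate[j]
        cap = fk * model._r_cap[j]
        mu = mu_pre_R[j, sl]
        NR_new[j, sl] = (state.NR[j, sl] + dt * rate * cap) / (1.0 + dt * (rate + mu))
    NR_new = np.maximum(NR_new, 0.0)
    return ModelState(N=state.N, NR=NR_new, t=state.t, T=state.T)


# ---------------------------------------------------------------------------
# Summaries used while recording
# ---------------------------------------------------------------------------


def ssb_of(state: ModelState, model: Model) -> np.ndarray:
    """Per-species spawning stock biomass (ogive-weighted biomass)."""
    out = np.zeros(model.n_species)
    g = model.grid
    for i, sp in enumerate(model.species):
        sl = g.span(sp.name)
        ogive = maturity_ogive(g.w[sl], sp)
        out[i] = float(np.sum(ogive * state.N[i, sl] * g.w[sl] * g.dw[sl]))
    return out


def yield_of(state: ModelState, model: Model) -> np.ndarray:
    """Per-species instantaneous biomass yield F * biomass above wmat."""
    out = np.zeros(model.n_species)
    g = model.grid
    for i, sp in enumerate(model.species):
        sl = g.span(sp.name)
        ws = g.w[sl]
        mask = ws >= sp.wmat
        out[i] = sp.F * float(np.sum(state.N[i, sl][mask] * ws[mask] * g.dw[sl][mask]))
    return out


# ---------------------------------------------------------------------------
# Projection loops
# ---------------------------------------------------------------------------


def project(
    state: ModelState,
    model: Model,
    solver: SolverConfig,
    forcing: Forcing,
    thermal: ThermalConfig | None = None,
    draw: ActivationDraw | None = None,
    record_spectra: bool = False,
    record_every: float = 1.0,
) -> SimOutput:
    """Project the community forward under annual forcing.

    Each step evaluates rates, advances fish, then resources.  Annual
    forcings are held piecewise constant within years.  Summaries are
    recorded every ``record_every`` years (and at the final time).
    """
    thermal = thermal or ThermalConfig(scenario="none")
    n_steps = int(round(solver.t_max / solver.dt))
    state = state.copy()
    t0 = state.t

    times, ssbs, ylds, rphys, recs, temps = [], [], [], [], [], []
    spectra = [] if record_spectra else None
    S = model.n_species

    def record(st: ModelState, rt: Rates, F_now: np.ndarray) -> None:
        times.append(st.t)
        ssbs.append(ssb_of(st, model))
        ylds.append(yield_of(st, model))
        rphys.append(rt.R_phy.copy())
        recs.append(rt.R.copy())
        temps.append(st.T)
        if spectra is not None:
            spectra.append(st.N.copy())

    rt = None
    next_record = t0
    for k in range(n_steps):
        F_now, T_now = forcing.at(state.t - t0)
        state.T = T_now
        for i, sp in enumerate(model.species):
            sp.F = float(F_now[i])
        phys = scale_physiology(T_now, thermal, draw, n_species=S)
        res_f = scale_resource(T_now, thermal, draw)
        rt = model.rates(state, thermal_factors=phys)
        if state.t >= next_record - 1e-9:
            record(state, rt, F_now)
            next_record += record_every
        state = step_fish(state, rt, model.grid, solver.dt, model)
        state = step_resource(state, rt.mu_pre_R, model, solver.dt, res_f)
        if not np.all(np.isfinite(state.N)):
            raise FloatingPointError(f"non-finite fish density at t={state.t:.2f}")

    # final record with rates re-evaluated at the final state
    F_now, T_now = forcing.at(state.t - t0) if n_steps == 0 else forcing.at(
        state.t - t0 - 1e-9
    )
    state.T = T_now
    for i, sp in enumerate(model.species):
        sp.F = float(F_now[i])
    rt = model.rates(
        state, thermal_factors=scale_physiology(T_now, thermal, draw, n_species=S)
    )
    record(state, rt, F_now)

    return SimOutput(
        time=np.array(times),
        ssb=np.array(ssbs),
        yield_=np.array(ylds),
        r_phy=np.array(rphys),
        recruitment=np.array(recs),
        temperature=np.array(temps),
        final_state=state,
        final_rates=rt,
        species=[sp.name for sp in model.species],
        spectra=np.array(spectra) if spectra is not None else None,
    )


def run_to_steady(
    state: ModelState,
    model: Model,
    solver: SolverConfig,
    F: np.ndarray | None = None,
    T: float | None = None,
    thermal: ThermalConfig | None = None,
    draw: ActivationDraw | None = None,
) -> tuple[ModelState, bool]:
    """Project under constant forcing until steady or ``t_max``.

    Steadiness: the maximum relative SSB change across species over a
    trailing window shorter than ``solver.steady_tol``.  Returns the
    final state and a convergence flag.
    """
    thermal = thermal or ThermalConfig(scenario="none")
    if F is None:
        F = np.array([sp.F for sp in model.species], dtype=float)
    if T is None:
        T = state.T
    S = model.n_species
    state = state.copy()
    state.T = T
    for i, sp in enumerate(model.species):
        sp.F = float(F[i])
    phys = scale_physiology(T, thermal, draw, n_species=S)
    res_f = scale_resource(T, thermal, draw)

    dt = solver.dt
    n_steps = int(round(solver.t_max / dt))
    window_steps = max(1, int(round(solver.steady_window / dt)))
    check_every = max(1, int(round(1.0 / dt)))
    ssb_hist: list[np.ndarray] = [ssb_of(state, model)]
    converged = False
    for k in range(n_steps):
        rt = model.rates(state, thermal_factors=phys)
        state = step_fish(state, rt, model.grid, dt, model)
        state = step_resource(state, rt.mu_pre_R, model, dt, res_f)
        if (k + 1) % check_every == 0:
            ssb_hist.append(ssb_of(state, model))
            lag = window_steps // check_every
            if len(ssb_hist) > lag:
                new = ssb_hist[-1]
                old = ssb_hist[-1 - lag]
                denom = np.where(new > 0, new, 1.0)
                rel = np.max(np.abs(new - old) / denom)
                if rel < solver.steady_tol:
                    converged = True
                    break
    return state, converged
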