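"""Warming projections, constant temperature x fishing grids, FMSY search
and derived size/yield metrics.

Projections follow a fixed protocol: a burn-in under the first forcing
values, the historical fishing and temperature series, then
model-derived FMSY until the final year.  The baseline run is identical
except temperature is frozen at its value in the freeze year.  Constant
grids enumerate the full factorial of temperature and fishing
proportions and run each cell to steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import Model, ModelState, SpeciesParams
from .dynamics_engine import (
    Forcing,
    SimOutput,
    SolverConfig,
    project,
    run_to_steady,
    ssb_of,
    yield_of,
)
from .thermal import ActivationDraw, ThermalConfig, sample_activation_energies, scale_physiology

__all__ = [
    "ScenarioSpec",
    "GridSpec",
    "FmsyResult",
    "fmsy_search",
    "yield_per_species",
    "run_warming_projection",
    "run_constant_grid",
    "size_at_age",
    "mean_weight",
    "relative_metrics",
    "ensemble_quantiles",
    "fmsy_yield_slopes",
]


@dataclass
class ScenarioSpec:
    f_history: pd.DataFrame  # columns: year + one per species
    t_history: pd.DataFrame  # columns: year, T
    f_future: dict[str, float] | None = None  # FMSY per species; None = last F
    burn_in: float = 100.0
    horizon_end: int = 2050
    baseline_freeze_year: int = 1997
    n_draws: int = 200
    seed: int = 0
    thermal_scenario: str = "both"

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        years = self.t_history["year"].to_numpy()
        if not (years[0] <= self.baseline_freeze_year <= self.horizon_end):
            raise ValueError("baseline_freeze_year outside the horizon")
        if years[-1] < self.horizon_end:
            raise ValueError("temperature series does not reach the horizon end")


@dataclass
class GridSpec:
    """Full-factorial constant temperature x fishing proportions."""

    t_lo: float = 0.75
    t_hi: float = 1.25
    t_step: float = 0.01
    f_lo: float = 0.1
    f_hi: float = 2.0
    f_step: float = 0.05

    @property
    def T_props(self) -> np.ndarray:
        n = int(round((self.t_hi - self.t_lo) / self.t_step)) + 1
        return np.round(np.linspace(self.t_lo, self.t_hi, n), 10)

    @property
    def F_props(self) -> np.ndarray:
        n = int(round((self.f_hi - self.f_lo) / self.f_step)) + 1
        return np.round(np.linspace(self.f_lo, self.f_hi, n), 10)

    @property
    def n_cells(self) -> int:
        return self.T_props.size * self.F_props.size


@dataclass
class FmsyResult:
    fmsy: float
    max_yield: float
    f_grid: np.ndarray
    yields: np.ndarray
    on_boundary: bool


# ---------------------------------------------------------------------------
# Steady-state metrics
# ---------------------------------------------------------------------------


def yield_per_species(state: ModelState, model: Model) -> np.ndarray:
    """Instantaneous biomass yield per species, F times biomass above wmat."""
    return yield_of(state, model)


def mean_weight(state: ModelState, model: Model, species_index: int) -> float:
    """Mean individual weight over the species' size range."""
    sp = model.species[species_index]
    sl = model.grid.span(sp.name)
    w, dw = model.grid.w[sl], model.grid.dw[sl]
    N = state.N[species_index, sl]
    numbers = float(np.sum(N * dw))
    if numbers <= 0:
        return float("nan")
    return float(np.sum(N * w * dw)) / numbers


def size_at_age(
    model: Model,
    state: ModelState,
    species_index: int,
    ages: np.ndarray,
    thermal_factors: dict[str, np.ndarray] | None = None,
    da: float = 0.01,
    growth=None,
) -> np.ndarray:
    """Weight-at-age of a cohort growing through the growth field implied
    by ``state`` (quasi-steady conditions).

    Integrates dw/da = g(w) with RK4 on substeps of ``da`` years,
    interpolating g linearly in log weight.  ``growth`` overrides the
    growth-rate function (signature w -> g) for testing.
    """
    sp = model.species[species_index]
    sl = model.grid.span(sp.name)
    if growth is None:
        rates = model.rates(state, thermal_factors=thermal_factors)
        wg = model.grid.w[sl]
        gg = rates.g[species_index, sl]
        logw = np.log(wg)

        def g_of(w: float) -> float:
            if w <= wg[0]:
                return float(gg[0])
            if w >= wg[-1]:
                return float(gg[-1])
            return float(np.interp(np.log(w), logw, gg))

    else:
        g_of = growth

    ages = np.asarray(ages, dtype=float)
    order = np.argsort(ages)
    a_max = float(ages.max())
    n_sub = max(1, int(round(a_max / da)))
    h = a_max / n_sub if n_sub else da
    out = np.empty(ages.size)
    w = sp.w0
    a = 0.0
    targets = iter(sorted(zip(ages[order], order)))
    next_t = next(targets, None)
    # record any age-0 targets
    while next_t is not None and next_t[0] <= 0.0:
        out[next_t[1]] = w
        next_t = next(targets, None)
    for _ in range(n_sub):
        k1 = g_of(w)
        k2 = g_of(w + 0.5 * h * k1)
        k3 = g_of(w + 0.5 * h * k2)
        k4 = g_of(w + h * k3)
        w = min(sp.Wi, w + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4))
        a += h
        while next_t is not None and a >= next_t[0] - 1e-9:
            out[next_t[1]] = w
            next_t = next(targets, None)
    while next_t is not None:
        out[next_t[1]] = w
        next_t = next(targets, None)
    return out


def relative_metrics(
    output: pd.DataFrame | np.ndarray, baseline: pd.DataFrame | np.ndarray
) -> np.ndarray | pd.DataFrame:
    """Element-wise warming/baseline ratio; zero-baseline entries are NaN."""
    if isinstance(output, pd.DataFrame):
        num = output.to_numpy(dtype=float)
        den = baseline.to_numpy(dtype=float)
        ratio = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
        return pd.DataFrame(ratio, index=output.index, columns=output.columns)
    num = np.asarray(output, dtype=float)
    den = np.asarray(baseline, dtype=float)
    return np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)


def ensemble_quantiles(values: np.ndarray, qs=(2.5, 50.0, 97.5)) -> np.ndarray:
    """Percentiles across the draw axis (axis 0) of an ensemble array."""
    return np.nanpercentile(np.asarray(values, dtype=float), qs, axis=0)


def fmsy_yield_slopes(surface: pd.DataFrame) -> pd.DataFrame:
    """OLS slopes of per-temperature FMSY and maximum yield against T_prop.

    ``surface`` columns: species, T_prop, F (absolute), yield.  For each
    (species, T_prop) the F maximising yield defines FMSY(T) and the
    yield there; slopes are least squares over T_prop.
    """
    rows = []
    for name, df in surface.groupby("species"):
        per_t = df.loc[df.groupby("T_prop")["yield"].idxmax()]
        t = per_t["T_prop"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("need at least two temperatures for a slope")
        fmsy_slope = np.polyfit(t, per_t["F"].to_numpy(dtype=float), 1)[0]
        yield_slope = np.polyfit(t, per_t["yield"].to_numpy(dtype=float), 1)[0]
        rows.append({"species": name, "fmsy_slope": fmsy_slope, "yield_slope": yield_slope})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FMSY search
# ---------------------------------------------------------------------------


def fmsy_search(
    model: Model,
    species_index: int,
    F_others: np.ndarray,
    T: float = 283.15,
    thermal: ThermalConfig | None = None,
    draw: ActivationDraw | None = None,
    f_grid: np.ndarray | None = None,
    solver: SolverConfig | None = None,
    start_state: ModelState | None = None,
) -> FmsyResult:
    """Grid search for the fishing mortality maximising steady-state yield
    of one species, others held at fixed F.

    Runs are warm-started along the F grid so each re-steady is cheap.
    """
    if f_grid is None:
        f_grid = np.round(np.arange(0.0, 3.0 + 1e-9, 0.05), 10)
    solver = solver or SolverConfig()
    F = np.asarray(F_others, dtype=float).copy()
    state = start_state.copy() if start_state is not None else model.initial_state(T=T)
    yields = np.empty(f_grid.size)
    for k, f in enumerate(f_grid):
        F[species_index] = f
        state, _ = run_to_steady(state, model, solver, F=F, T=T, thermal=thermal, draw=draw)
        yields[k] = yield_of(state, model)[species_index]
    k_best = int(np.argmax(yields))
    return FmsyResult(
        fmsy=float(f_grid[k_best]),
        max_yield=float(yields[k_best]),
        f_grid=f_grid,
        yields=yields,
        on_boundary=k_best in (0, f_grid.size - 1),
    )


# ---------------------------------------------------------------------------
# Warming projections
# ---------------------------------------------------------------------------


def _build_forcings(
    spec: ScenarioSpec, species: list[str], Tref: float
) -> tuple[Forcing, Forcing, float]:
    """Warming and baseline forcing tables over burn-in + projection years."""
    t_hist = spec.t_history.sort_values("year")
    years = np.arange(int(t_hist["year"].iloc[0]), spec.horizon_end + 1)
    T = np.interp(years, t_hist["year"], t_hist["T"])

    f_hist = spec.f_history.sort_values("year")
    f_years = f_hist["year"].to_numpy()
    F = np.empty((years.size, len(species)))
    for i, name in enumerate(species):
        if name not in f_hist.columns:
            raise ValueError(f"fishing history missing species {name}")
        fy = f_hist[name].to_numpy(dtype=float)
        last_year = f_years[-1]
        future = spec.f_future[name] if spec.f_future else fy[-1]
        for k, y in enumerate(years):
            if y < f_years[0]:
                F[k, i] = fy[0]
            elif y <= last_year:
                F[k, i] = fy[np.searchsorted(f_years, y, side="right") - 1]
            else:
                F[k, i] = future

    T_base = T.copy()
    freeze_idx = int(np.searchsorted(years, spec.baseline_freeze_year))
    T_base[freeze_idx + 1 :] = T_base[freeze_idx]

    # prepend burn-in at the first forcing values
    nb = int(round(spec.burn_in))
    Fb = np.vstack([np.tile(F[0], (nb, 1)), F])
    Tw = np.concatenate([np.full(nb, T[0]), T])
    Tb = np.concatenate([np.full(nb, T_base[0]), T_base])
    horizon = float(Fb.shape[0])
    return Forcing(F=Fb, T=Tw), Forcing(F=Fb, T=Tb), horizon


@dataclass
class WarmingResult:
    warming: list[SimOutput]
    baseline: list[SimOutput]
    draws: list[ActivationDraw]
    species: list[str]

    def size_at_age_ratio(
        self, model: Model, ages: np.ndarray, thermal: ThermalConfig
    ) -> dict[str, np.ndarray]:
        """Per-species (n_draws, n_ages) warming/baseline weight-at-age
        ratios evaluated in the end-of-horizon growth field."""
        out = {}
        for i, name in enumerate(self.species):
            ratios = []
            for warm, base, draw in zip(self.warming, self.baseline, self.draws):
                fw = scale_physiology(warm.final_state.T, thermal, draw, len(self.species))
                fb = scale_physiology(base.final_state.T, thermal, draw, len(self.species))
                ww = size_at_age(model, warm.final_state, i, ages, thermal_factors=fw)
                wb = size_at_age(model, base.final_state, i, ages, thermal_factors=fb)
                ratios.append(ww / wb)
            out[name] = np.array(ratios)
        return out


def run_warming_projection(
    model: Model,
    scenario: ScenarioSpec,
    thermal: ThermalConfig,
    solver: SolverConfig | None = None,
    draws: list[ActivationDraw] | None = None,
) -> WarmingResult:
    """Ensemble warming projection with a matched no-warming baseline.

    Each draw runs the identical protocol twice: burn-in at the first
    forcing values, historical F and T, then future F to the horizon --
    with the baseline temperature frozen after the freeze year.
    """
    solver = solver or SolverConfig()
    species = [sp.name for sp in model.species]
    warm_forcing, base_forcing, horizon = _build_forcings(scenario, species, thermal.Tref)
    if draws is None:
        if scenario.n_draws <= 1:
            draws = [thermal.mean_draw]
        else:
            draws = sample_activation_energies(thermal, scenario.n_draws, scenario.seed)
    run_solver = SolverConfig(
        dt=solver.dt, t_max=horizon, steady_tol=solver.steady_tol
    )
    warming, baseline = [], []
    for draw in draws:
        st0 = model.initial_state(T=warm_forcing.T[0])
        warming.append(
            project(st0, model, run_solver, warm_forcing, thermal=thermal, draw=draw)
        )
        baseline.append(
            project(st0, model, run_solver, base_forcing, thermal=thermal, draw=draw)
        )
    return WarmingResult(warming=warming, baseline=baseline, draws=list(draws), species=species)


# ---------------------------------------------------------------------------
# Constant T x F grid
# ---------------------------------------------------------------------------


def run_constant_grid(
    model: Model,
    gridspec: GridSpec,
    fmsy_ref: dict[str, float],
    thermal: ThermalConfig,
    draw: ActivationDraw | None = None,
    solver: SolverConfig | None = None,
    focal: str | None = None,
    Tref: float = 283.15,
    prop_scale: str = "celsius",
) -> pd.DataFrame:
    """Steady-state yield and SSB over the full factorial T x F grid.

    F proportions scale the focal species' reference FMSY (others held at
    their own FMSY); with ``focal=None`` the proportion scales every
    species.  Temperature proportions are applied on the Celsius scale by
    default (prop * 10 degC for the default reference) -- applying them in
    Kelvin would span -61 to +81 degC and extinguish the community; pass
    ``prop_scale='kelvin'`` to force the literal reading.  Cells where the
    solver fails (e.g. recruits starve at the egg weight) are recorded
    with NaN yields rather than aborting the sweep.
    """
    solver = solver or SolverConfig()
    if prop_scale not in ("celsius", "kelvin"):
        raise ValueError("prop_scale must be 'celsius' or 'kelvin'")
    names = [sp.name for sp in model.species]
    base_F = np.array([fmsy_ref[n] for n in names])
    rows = []
    for T_prop in gridspec.T_props:
        if prop_scale == "celsius":
            T = 273.15 + float(T_prop) * (Tref - 273.15)
        else:
            T = float(T_prop * Tref)
        state = model.initial_state(T=T)  # warm-start along the F axis only
        for F_prop in gridspec.F_props:
            F = base_F.copy()
            if focal is None:
                F = base_F * F_prop
            else:
                F[names.index(focal)] = fmsy_ref[focal] * F_prop
            try:
                state, conv = run_to_steady(
                    state, model, solver, F=F, T=T, thermal=thermal, draw=draw
                )
                ylds = yield_of(state, model)
                ssbs = ssb_of(state, model)
            except (ZeroDivisionError, FloatingPointError):
                state = model.initial_state(T=T)
                conv = False
                ylds = np.full(len(names), np.nan)
                ssbs = np.full(len(names), np.nan)
            for i, n in enumerate(names):
                rows.append(
                    {
                        "species": n,
                        "T_prop": float(T_prop),
                        "F_prop": float(F_prop),
                        "T": T,
                        "F": float(F[i]),
                        "yield": float(ylds[i]),
                        "ssb": float(ssbs[i]),
                        "converged": bool(conv),
                    }
                )
    return pd.DataFrame(rows)
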