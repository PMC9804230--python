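"""Synthetic stand-ins for assessment and climate forcing inputs.

Everything needed to exercise calibration and projection offline:
a three-species archetype community (small and medium forage fish plus a
large piscivore -- illustrative values, NOT any real stock's parameters),
annual temperature and fishing-mortality series, noisy SSB calibration
targets generated from a known model, and von Bertalanffy weight-at-age
growth targets.  All generators are pure functions of their arguments
and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import Model, ResourceParams, SpeciesParams
from .dynamics_engine import SolverConfig, run_to_steady, ssb_of
from .calibration import CalibrationTargets

__all__ = [
    "SyntheticSpec",
    "default_species",
    "default_resources",
    "default_model",
    "generate_temperature_series",
    "generate_fishing_history",
    "generate_ssb_targets",
    "generate_growth_targets",
]


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_species: int = 3
    ssb_noise_cv: float = 0.05
    warming_delta_2050: float = 2.0
    # piecewise F levels: {species: [(year_from, level), ...]}
    f_history_shape: dict[str, list[tuple[int, float]]] | None = None
    f_noise_sd: float = 0.0
    t_noise_sd: float = 0.15
    t_ar1: float = 0.6
    year_start: int = 1970
    year_end: int = 2050
    calib_window: tuple[int, int] = (1992, 2002)
    Tref: float = 283.15

    def __post_init__(self) -> None:
        if self.ssb_noise_cv < 0:
            raise ValueError("ssb_noise_cv must be >= 0")
        if not np.isfinite(self.warming_delta_2050):
            raise ValueError("warming_delta_2050 must be finite")


# ---------------------------------------------------------------------------
# Archetype community (illustrative parameters only)
# ---------------------------------------------------------------------------


def default_species() -> list[SpeciesParams]:
    """Three archetypes: small forage fish, medium forage fish, large
    piscivore.  theta_R is (pelagic, benthic)."""
    return [
        SpeciesParams(
            name="forage_small",
            w0=1e-3,
            Wi=30.0,
            wmat=6.0,
            h=35.0,
            ks=4.0,
            mu0=0.8,
            Rmax=1e11,
            beta=200.0,
            sigma=1.5,
            theta_R=(1.0, 0.0),
        ),
        SpeciesParams(
            name="forage_medium",
            w0=2e-3,
            Wi=250.0,
            wmat=35.0,
            h=32.0,
            ks=4.0,
            mu0=0.7,
            Rmax=3e10,
            beta=800.0,
            sigma=1.5,
            theta_R=(0.85, 0.15),
        ),
        SpeciesParams(
            name="piscivore",
            w0=2e-3,
            Wi=15000.0,
            wmat=1000.0,
            h=30.0,
            ks=3.5,
            mu0=0.6,
            Rmax=3e7,
            beta=100.0,
            sigma=1.5,
            theta_R=(0.3, 0.7),
        ),
    ]


def default_resources() -> list[ResourceParams]:
    lam = 2.0 - 0.75 + 0.8
    return [
        ResourceParams(name="pelagic", r0=0.2, kappa=5e11, lambda_=lam, w_min=1e-7, w_max=1.0),
        ResourceParams(name="benthic", r0=4.0, kappa=1e11, lambda_=lam, w_min=1e-4, w_max=20.0),
    ]


def default_model(bins_per_decade: int = 15, **overrides) -> Model:
    species = default_species()
    for sp in species:
        for key, val in overrides.items():
            if hasattr(sp, key):
                setattr(sp, key, val)
    return Model(species, default_resources(), bins_per_decade=bins_per_decade)


# ---------------------------------------------------------------------------
# Forcing generators
# ---------------------------------------------------------------------------


def generate_temperature_series(spec: SyntheticSpec, years: np.ndarray | None = None) -> pd.DataFrame:
    """Smooth warming trend with AR(1) interannual noise, re-centered so the
    calibration-window mean equals Tref and reaching
    Tref + warming_delta by the final year."""
    if years is None:
        years = np.arange(spec.year_start, spec.year_end + 1)
    years = np.asarray(years)
    rng = np.random.default_rng(spec.seed)
    # quadratic ramp from 0 at the start to 1 at the end of the horizon
    frac = (years - years[0]) / max(1, years[-1] - years[0])
    trend = spec.warming_delta_2050 * frac**2
    noise = np.zeros(years.size)
    if spec.t_noise_sd > 0:
        eps = rng.normal(0.0, spec.t_noise_sd, size=years.size)
        for k in range(1, years.size):
            noise[k] = spec.t_ar1 * noise[k - 1] + eps[k]
    raw = trend + noise
    w0, w1 = spec.calib_window
    mask = (years >= w0) & (years <= w1)
    if not mask.any():
        raise ValueError("calibration window outside year range")
    series = raw - raw[mask].mean() + spec.Tref
    # pin the endpoint so the configured 2050 delta is honored exactly on
    # the trend (noise-free) scale
    if spec.t_noise_sd == 0 and spec.warming_delta_2050 != 0:
        target_end = spec.Tref + spec.warming_delta_2050
        lo = series[mask].mean()
        scale = (target_end - lo) / (series[-1] - lo) if series[-1] != lo else 1.0
        series = lo + (series - lo) * scale
    return pd.DataFrame({"year": years, "T": series})


def generate_fishing_history(spec: SyntheticSpec, years: np.ndarray | None = None) -> pd.DataFrame:
    """Piecewise-constant per-species F with optional multiplicative noise."""
    if years is None:
        years = np.arange(spec.year_start, spec.year_end + 1)
    years = np.asarray(years)
    rng = np.random.default_rng(spec.seed + 1)
    shapes = spec.f_history_shape or {
        "forage_small": [(spec.year_start, 0.3), (1985, 0.45), (2005, 0.35)],
        "forage_medium": [(spec.year_start, 0.25), (1990, 0.35), (2005, 0.25)],
        "piscivore": [(spec.year_start, 0.4), (1988, 0.9), (2008, 0.55)],
    }
    out = {"year": years}
    for name, pieces in shapes.items():
        pieces = sorted(pieces)
        f = np.zeros(years.size)
        for year_from, level in pieces:
            f[years >= year_from] = level
        if spec.f_noise_sd > 0:
            f = f * np.exp(rng.normal(0.0, spec.f_noise_sd, size=years.size))
        out[name] = np.maximum(f, 0.0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Calibration target generators
# ---------------------------------------------------------------------------


def generate_ssb_targets(
    model_truth: Model,
    window: tuple[int, int] = (1992, 2002),
    cv: float = 0.05,
    seed: int = 0,
    f_bar: dict[str, float] | None = None,
    solver: SolverConfig | None = None,
) -> CalibrationTargets:
    """Run the truth model to steady state and emit noisy SSB targets.

    Each year in the window gets an independent multiplicative lognormal
    perturbation with the given CV (mean-one); the targets are the
    window averages of the annual series.
    """
    solver = solver or SolverConfig()
    rng = np.random.default_rng(seed)
    names = [sp.name for sp in model_truth.species]
    if f_bar is None:
        f_bar = {sp.name: sp.F for sp in model_truth.species}
    F = np.array([f_bar[n] for n in names])
    state, _ = run_to_steady(model_truth.initial_state(), model_truth, solver, F=F)
    ssb_true = ssb_of(state, model_truth)
    sigma = np.sqrt(np.log(1.0 + cv**2)) if cv > 0 else 0.0
    noisy = {}
    rows = []
    years = np.arange(window[0], window[1] + 1)
    for i, name in enumerate(names):
        yearly = (
            np.exp(rng.normal(-0.5 * sigma**2, sigma, size=years.size))
            if cv > 0
            else np.ones(years.size)
        )
        series = ssb_true[i] * yearly
        noisy[name] = float(series.mean())
        for y, s in zip(years, series):
            rows.append({"species": name, "year": int(y), "ssb": float(s), "f": f_bar[name]})
    return CalibrationTargets(ssb=noisy, f_bar=dict(f_bar), ssb_series=pd.DataFrame(rows))


def generate_growth_targets(
    vb_params: dict[str, tuple[float, float]], ages: np.ndarray
) -> pd.DataFrame:
    """Weight-at-age from a von Bertalanffy weight curve
    w(a) = W_inf * (1 - exp(-K a))**3 per species."""
    ages = np.asarray(ages, dtype=float)
    rows = []
    for name, (w_inf, K) in vb_params.items():
        w = w_inf * (1.0 - np.exp(-K * ages)) ** 3
        for a, wt in zip(ages, w):
            rows.append({"species": name, "age": a, "weight": wt})
    return pd.DataFrame(rows)
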