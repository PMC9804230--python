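"""Arrhenius temperature scaling of physiological and resource rates.

Rate coefficients are rescaled from their reference values once per time
step with an exponential (Arrhenius) correction factor that equals 1 at
the reference temperature.  Activation-energy uncertainty is propagated
by sampling ensembles of independent normal draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BOLTZMANN_EV = 8.617e-5  # eV / K

SCENARIOS = ("none", "physiology", "resources", "both")


@dataclass
class ThermalConfig:
    """Activation-energy distributions (eV) and scenario switches.

    Search volume scales like maximum consumption and background
    mortality like metabolism by default; all six energies are sampled
    independently in ensembles regardless of tied means.
    """

    Tref: float = 283.15
    k_B: float = BOLTZMANN_EV
    E_met: tuple[float, float] = (0.59, 0.08)
    E_cons: tuple[float, float] = (0.69, 0.10)
    E_search: tuple[float, float] | None = None  # defaults to E_cons
    E_mort: tuple[float, float] | None = None  # defaults to E_met
    E_r0: tuple[float, float] = (0.63, 0.10)
    E_kappa: tuple[float, float] = (0.63, 0.10)
    scenario: str = "both"

    def __post_init__(self) -> None:
        if self.Tref <= 0:
            raise ValueError("Tref must be positive (Kelvin)")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.E_search is None:
            self.E_search = self.E_cons
        if self.E_mort is None:
            self.E_mort = self.E_met
        for name in ("E_met", "E_cons", "E_search", "E_mort", "E_r0", "E_kappa"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")

    @property
    def mean_draw(self) -> "ActivationDraw":
        return ActivationDraw(
            E_met=self.E_met[0],
            E_cons=self.E_cons[0],
            E_search=self.E_search[0],
            E_mort=self.E_mort[0],
            E_r0=self.E_r0[0],
            E_kappa=self.E_kappa[0],
            index=-1,
            seed=None,
        )


@dataclass(frozen=True)
class ActivationDraw:
    """One sampled set of the six activation energies (eV)."""

    E_met: float
    E_cons: float
    E_search: float
    E_mort: float
    E_r0: float
    E_kappa: float
    index: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("E_met", "E_cons", "E_search", "E_mort", "E_r0", "E_kappa"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def arrhenius_factor(E: float, T: float, thermal: ThermalConfig) -> float:
    """Exponential temperature correction; exactly 1 at T = Tref."""
    return math.exp(E * (T - thermal.Tref) / (thermal.k_B * T * thermal.Tref))


def scale_physiology(
    T: float,
    thermal: ThermalConfig,
    draw: ActivationDraw | None = None,
    n_species: int = 1,
) -> dict[str, np.ndarray]:
    """Multipliers for the physiological rate coefficients h, gamma, ks, mu0.

    Growth is never scaled directly; its temperature response emerges
    from consumption and metabolism.  Identity outside the physiology
    scenarios.
    """
    draw = draw or thermal.mean_draw
    ones = np.ones(n_species)
    if thermal.scenario not in ("physiology", "both"):
        return {"h": ones, "gamma": ones, "ks": ones, "mu0": ones}
    return {
        "h": ones * arrhenius_factor(draw.E_cons, T, thermal),
        "gamma": ones * arrhenius_factor(draw.E_search, T, thermal),
        "ks": ones * arrhenius_factor(draw.E_met, T, thermal),
        "mu0": ones * arrhenius_factor(draw.E_mort, T, thermal),
    }


def scale_resource(
    T: float,
    thermal: ThermalConfig,
    draw: ActivationDraw | None = None,
) -> tuple[float, float]:
    """Multipliers (r0, kappa): regeneration speeds up while the carrying
    capacity declines at the corresponding rate; the spectrum slope is
    untouched.  Identity outside the resource scenarios."""
    draw = draw or thermal.mean_draw
    if thermal.scenario not in ("resources", "both"):
        return 1.0, 1.0
    return (
        arrhenius_factor(draw.E_r0, T, thermal),
        arrhenius_factor(-draw.E_kappa, T, thermal),
    )


def sample_activation_energies(
    thermal: ThermalConfig, n_draws: int = 200, seed: int | None = None
) -> list[ActivationDraw]:
    """Independent normal draws of the six activation energies."""
    rng = np.random.default_rng(seed)
    draws = []
    for k in range(n_draws):
        vals = {}
        for name in ("E_met", "E_cons", "E_search", "E_mort", "E_r0", "E_kappa"):
            mean, sd = getattr(thermal, name)
            vals[name] = float(rng.normal(mean, sd)) if sd > 0 else mean
        draws.append(ActivationDraw(index=k, seed=seed, **vals))
    return draws


def sd_from_ci(ci_low: float, ci_high: float, mean: float) -> float:
    """Standard deviation for which mean +/- 1.959964*sd spans the 95% CI.

    Asymmetric intervals use the average half-width.
    """
    half = ((mean - ci_low) + (ci_high - mean)) / 2.0
    if half < 0:
        raise ValueError("confidence interval does not bracket the mean")
    return half / 1.959964
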